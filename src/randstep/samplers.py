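"""Stimulus-placement procedures: Random Step, constant stimuli, staircase.

All three share one stateful contract: ``propose()`` returns the grid index
to present next, ``update(level_index, response)`` ingests the outcome.
Every random draw comes from the ``numpy.random.Generator`` injected at
construction, so a single seed fixes an entire session.
"""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np

from .core import DOWN, UP, LevelGrid

__all__ = [
    "Sampler",
    "RandomStepSampler",
    "ConstantStimuliSampler",
    "StaircaseSampler",
    "cs_schedule",
    "make_sampler",
    "METHODS",
]

METHODS = ("RS", "CS", "SC")


class Sampler(ABC):
    """Stateful stimulus-placement procedure over a level grid."""

    method: str

    def __init__(self, grid: LevelGrid, rng: np.random.Generator):
        self.grid = grid
        self.rng = rng
        self.last_index: int | None = None
        self.last_response: str | None = None

    @abstractmethod
    def propose(self) -> int:
        """Grid index of the next level to present."""

    def update(self, level_index: int, response: str) -> None:
        """Record the presented level and the observer's response."""
        if not 0 <= level_index < self.grid.n_levels:
            raise ValueError(f"level index {level_index} outside the grid")
        if response not in (UP, DOWN):
            raise ValueError(f"unknown response {response!r}")
        self.last_index = level_index
        self.last_response = response


class RandomStepSampler(Sampler):
    """One-up-one-down rule with a random step size.

    The first level is uniform over the whole grid.  After a response at
    index ``k``: "up" draws the next index uniformly from the strict lower
    range ``{0..k-1}``, "down" uniformly from the strict upper range
    ``{k+1..K-1}``.  The admissible range is never narrowed across trials,
    so every level keeps a nonzero proposal probability throughout a
    session.  When the admissible side is empty ("up" at the lowest level
    or "down" at the highest) the boundary level is repeated.
    """

    method = "RS"

    def propose(self) -> int:
        k = self.last_index
        if k is None:
            return int(self.rng.integers(self.grid.n_levels))
        if self.last_response == UP:
            if k == 0:
                return 0  # empty lower range: repeat the boundary level
            return int(self.rng.integers(0, k))
        if k == self.grid.n_levels - 1:
            return k  # empty upper range
        return int(self.rng.integers(k + 1, self.grid.n_levels))


def cs_schedule(grid: LevelGrid, n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """Constant-stimuli presentation schedule as an index sequence.

    Each level is scheduled floor(n/K) or ceil(n/K) times — remainder
    repetitions go to distinct levels chosen uniformly at random — and the
    whole schedule is presented in uniformly random order.
    """
    k = grid.n_levels
    if n_trials < k:
        raise ValueError(
            f"constant stimuli needs at least one trial per level: n={n_trials} < K={k}"
        )
    reps = np.full(k, n_trials // k, dtype=int)
    remainder = n_trials % k
    if remainder:
        reps[rng.choice(k, size=remainder, replace=False)] += 1
    schedule = np.repeat(np.arange(k), reps)
    return rng.permutation(schedule)


class ConstantStimuliSampler(Sampler):
    """Pre-shuffled schedule giving every level a (near-)equal repetition count."""

    method = "CS"

    def __init__(self, grid: LevelGrid, rng: np.random.Generator, n_trials: int):
        super().__init__(grid, rng)
        self.schedule = cs_schedule(grid, n_trials, rng)
        self._pos = 0

    def propose(self) -> int:
        if self._pos >= len(self.schedule):
            raise RuntimeError("constant-stimuli schedule exhausted")
        return int(self.schedule[self._pos])

    def update(self, level_index: int, response: str) -> None:
        super().update(level_index, response)
        self._pos += 1


class StaircaseSampler(Sampler):
    """One-up-one-down staircase with a fixed step of one grid index.

    The starting level is uniform over the grid; thereafter "up" steps one
    index down and "down" one index up, clipped at the grid boundaries.
    """

    method = "SC"

    def __init__(self, grid: LevelGrid, rng: np.random.Generator, step: int = 1):
        super().__init__(grid, rng)
        if step < 1:
            raise ValueError(f"step must be >= 1, got {step}")
        self.step = step

    def propose(self) -> int:
        k = self.last_index
        if k is None:
            return int(self.rng.integers(self.grid.n_levels))
        if self.last_response == UP:
            return max(k - self.step, 0)
        return min(k + self.step, self.grid.n_levels - 1)


def make_sampler(
    method: str, grid: LevelGrid, rng: np.random.Generator, n_trials: int | None = None
) -> Sampler:
    """Build a sampler by method tag ("RS" | "CS" | "SC")."""
    if method == "RS":
        return RandomStepSampler(grid, rng)
    if method == "CS":
        if n_trials is None:
            raise ValueError("constant stimuli requires n_trials for its schedule")
        return ConstantStimuliSampler(grid, rng, n_trials)
    if method == "SC":
        return StaircaseSampler(grid, rng)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
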