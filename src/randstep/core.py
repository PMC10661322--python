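"""Shared domain types and the psychometric model.

A 2AFC session presents one stimulus level per trial and records a binary
"up"/"down" judgment.  The observer's behaviour is summarized by a
psychometric function — here a logistic forced between 0 and 1 whose
midpoint is the point of subjective equality (PSE) and whose steepness
parameter is the slope.  The simulated observer is a classical
signal-detection model: an internal value is drawn from a normal
distribution centered on the presented level and compared against a fixed
pivot (the observer's true PSE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.special import expit, ndtr

__all__ = [
    "UP",
    "DOWN",
    "RESPONSES",
    "LevelGrid",
    "TrialRecord",
    "ResponseTally",
    "SimulatedObserver",
    "PsychometricFit",
    "GaussianOffsetModel",
    "logistic_probability",
    "observer_probability_up",
    "default_simulation_grid",
]

UP = "up"
DOWN = "down"
RESPONSES = (UP, DOWN)


@dataclass(frozen=True)
class LevelGrid:
    """An ordered set of candidate stimulus levels.

    Parameters
    ----------
    values
        Strictly increasing stimulus levels (at least 3) in stimulus units —
        degrees of interocular phase shift, abstract integer levels, etc.
    labels
        Optional display labels, one per level (e.g. -7..7 for a symmetric
        phase grid).
    """

    values: tuple[float, ...]
    labels: tuple[int, ...] | None = None

    def __init__(self, values: Sequence[float], labels: Sequence[int] | None = None):
        vals = tuple(float(v) for v in values)
        if len(vals) < 3:
            raise ValueError(f"a level grid needs at least 3 levels, got {len(vals)}")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("grid values must be strictly increasing")
        labs = None
        if labels is not None:
            labs = tuple(int(l) for l in labels)
            if len(labs) != len(vals):
                raise ValueError(
                    f"{len(labs)} labels for {len(vals)} levels"
                )
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", labs)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_levels(self) -> int:
        """Number of levels K."""
        return len(self.values)

    @property
    def span(self) -> float:
        """Distance between the extreme levels."""
        return self.values[-1] - self.values[0]

    def value(self, index: int) -> float:
        if not 0 <= index < len(self.values):
            raise IndexError(f"level index {index} outside 0..{len(self.values) - 1}")
        return self.values[index]

    def index_of(self, value: float) -> int:
        """Grid index of an exact level value."""
        try:
            return self.values.index(float(value))
        except ValueError:
            raise ValueError(f"{value!r} is not a grid level") from None

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def default_simulation_grid() -> LevelGrid:
    """The 20-level integer grid 1..20 used throughout the simulations."""
    return LevelGrid(tuple(range(1, 21)))


class TrialRecord(NamedTuple):
    """One stimulus presentation and its binary response."""

    trial_index: int  # 1-based position within the session
    level_index: int  # index into the grid
    level_value: float  # stimulus units
    response: str  # "up" | "down"


@dataclass(frozen=True)
class SimulatedObserver:
    """Normal-draw-versus-pivot observer.

    On each trial an internal value ``v ~ Normal(level, sigma)`` is compared
    to ``pivot`` (the true PSE): the response is "up" iff ``v > pivot``.
    With probability ``lapse_rate`` the observer instead guesses at random
    (a fair coin flip), modelling finger errors / attention lapses.
    """

    pivot: float
    sigma: float
    lapse_rate: float = 0.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not 0.0 <= self.lapse_rate < 0.5:
            raise ValueError(f"lapse_rate must lie in [0, 0.5), got {self.lapse_rate}")


def logistic_probability(x, pse: float, slope: float):
    """Logistic psychometric function forced between 0 and 1.

    ``P(up | x) = 1 / (1 + exp(-slope * (x - pse)))``

    with no guess or lapse floor/ceiling.  ``slope`` is the steepness
    parameter beta (1/stimulus-units); the derivative at the midpoint is
    ``slope / 4``.
    """
    if slope <= 0:
        raise ValueError(f"slope must be positive, got {slope}")
    x = np.asarray(x, dtype=float)
    out = expit(slope * (x - pse))
    return float(out) if out.ndim == 0 else out


def observer_probability_up(level, observer: SimulatedObserver):
    """Analytic probability that the simulated observer responds "up".

    Equals ``lapse/2 + (1 - lapse) * Phi((level - pivot) / sigma)``; at
    ``sigma = 0`` the normal tail degenerates to a 0 / 0.5 / 1 step.
    """
    level = np.asarray(level, dtype=float)
    if observer.sigma == 0:
        base = np.where(
            level > observer.pivot, 1.0, np.where(level == observer.pivot, 0.5, 0.0)
        )
    else:
        # tiny sigma overflows to +/-inf, for which ndtr gives the correct limit
        with np.errstate(over="ignore"):
            base = ndtr((level - observer.pivot) / observer.sigma)
    out = observer.lapse_rate / 2.0 + (1.0 - observer.lapse_rate) * base
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ResponseTally:
    """Per-level aggregation of trials: presentations and "up" counts."""

    level_values: tuple[float, ...]
    n_presented: tuple[int, ...]
    n_up: tuple[int, ...]

    def __post_init__(self):
        if not (len(self.level_values) == len(self.n_presented) == len(self.n_up)):
            raise ValueError("tally fields must have equal length")
        for n, u in zip(self.n_presented, self.n_up):
            if n < 0 or not 0 <= u <= n:
                raise ValueError(f"need 0 <= n_up <= n_presented, got up={u}, n={n}")

    @classmethod
    def from_trials(cls, trials: Sequence[TrialRecord], grid: LevelGrid) -> "ResponseTally":
        k = grid.n_levels
        n = np.zeros(k, dtype=int)
        up = np.zeros(k, dtype=int)
        for t in trials:
            if not 0 <= t.level_index < k:
                raise ValueError(f"trial level index {t.level_index} outside grid")
            n[t.level_index] += 1
            if t.response == UP:
                up[t.level_index] += 1
            elif t.response != DOWN:
                raise ValueError(f"unknown response {t.response!r}")
        return cls(grid.values, tuple(n.tolist()), tuple(up.tolist()))

    @property
    def total_trials(self) -> int:
        return int(sum(self.n_presented))

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(levels, n_presented, n_up) as float/int arrays."""
        return (
            np.asarray(self.level_values, dtype=float),
            np.asarray(self.n_presented, dtype=int),
            np.asarray(self.n_up, dtype=int),
        )


_SD_UNSET = None


@dataclass
class PsychometricFit:
    """Result of the maximum-likelihood logistic fit.

    ``sd_pse`` / ``sd_slope`` are populated by bootstrapping; they are NaN
    with the matching validity flag False when the bootstrap deemed the
    estimate unusable, and None before any bootstrap ran.
    """

    pse: float
    slope: float
    converged: bool
    loglik: float = math.nan
    sd_pse: float | None = None
    sd_slope: float | None = None
    sd_pse_valid: bool | None = None
    sd_slope_valid: bool | None = None

    @property
    def midpoint_derivative(self) -> float:
        """Slope of the probability curve at the midpoint, beta/4."""
        return self.slope / 4.0


@dataclass
class GaussianOffsetModel:
    """Gaussian bump plus vertical offset, fit to trial-count histograms.

    ``count(level) ~ amplitude * exp(-(level - center)^2 / (2 width^2)) + offset``

    ``center_identifiable`` is False for degenerate (flat) histograms where
    the bump amplitude vanishes and the center is arbitrary.
    """

    amplitude: float
    center: float
    width: float
    offset: float
    center_identifiable: bool = True

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.amplitude * np.exp(-((x - self.center) ** 2) / (2 * self.width**2)) + self.offset

    def offset_fraction(self, n_levels: int, total: float) -> float:
        """Fraction of all trials accounted for by the flat offset term."""
        return self.offset * n_levels / total
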