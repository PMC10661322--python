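"""Stochastic simulated observer and session runner.

``respond`` realizes one noisy judgment; ``run_block`` drives any sampler
against the observer for a fixed number of trials, producing a trial log.
Sampler and observer consume the same RNG stream in interleaved order
(proposal draw, then response draw), so one seed fixes the whole block.
"""

from __future__ import annotations

import numpy as np

from .core import DOWN, UP, SimulatedObserver, TrialRecord
from .samplers import Sampler

__all__ = ["respond", "run_block"]


def respond(level: float, observer: SimulatedObserver, rng: np.random.Generator) -> str:
    """One 2AFC judgment of ``level`` against the observer's pivot.

    Draws ``v ~ Normal(level, sigma)`` and answers "up" iff ``v > pivot``
    (the measure-zero tie ``v == pivot`` resolves to "down").  With
    probability ``lapse_rate`` the draw is ignored and the answer is a fair
    coin flip.
    """
    if observer.lapse_rate > 0 and rng.random() < observer.lapse_rate:
        return UP if rng.random() < 0.5 else DOWN
    v = level if observer.sigma == 0 else level + observer.sigma * rng.standard_normal()
    return UP if v > observer.pivot else DOWN


def run_block(
    sampler: Sampler,
    observer: SimulatedObserver,
    n_trials: int,
    rng: np.random.Generator,
) -> list[TrialRecord]:
    """Run ``n_trials`` propose/present/respond cycles and return the log.

    For full single-seed reproducibility the sampler should have been
    constructed with the same ``rng`` passed here.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    values = sampler.grid.values
    records: list[TrialRecord] = []
    for t in range(1, n_trials + 1):
        idx = sampler.propose()
        resp = respond(values[idx], observer, rng)
        sampler.update(idx, resp)
        records.append(TrialRecord(t, idx, values[idx], resp))
    return records
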