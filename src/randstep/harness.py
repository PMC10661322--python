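"""Monte-Carlo method-comparison harness and agreement analyses.

Runs repeated simulated 2AFC blocks for every cell of
(method x noise level x trial count), fits each block, bootstraps each fit,
and aggregates distributions of estimates, mean SDs, failure rates and
pooled level-occupancy histograms.  Per-repetition seeds are derived from
the master seed through ``numpy.random.SeedSequence([master, method_index,
sigma_index, repetition])``, so any cell (or single repetition) can be
recomputed independently of the rest of the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import LevelGrid, SimulatedObserver, TrialRecord, default_simulation_grid
from .fitting import (
    DEFAULT_VALIDITY_RULE,
    ValidityRule,
    bootstrap_sds,
    failure_rate,
    fit_trials,
)
from .observer import run_block
from .samplers import METHODS, make_sampler

__all__ = [
    "HarnessConfig",
    "CellResult",
    "ComparisonSummary",
    "run_comparison",
    "run_cell",
    "occupancy_histogram",
    "bland_altman",
    "agreement_regression",
    "compare_sd_distributions",
]


@dataclass(frozen=True)
class HarnessConfig:
    """Full description of one simulation study.

    Defaults mirror the simulation regime used for method comparison:
    20 integer levels, pivot 13, noise levels sigma in {2, 3.75, 5},
    100-trial blocks.  ``repetitions`` defaults to 1,000 desk-scale blocks
    per cell; the full 10,000 is a config change.
    """

    grid: LevelGrid = field(default_factory=default_simulation_grid)
    pivot: float = 13.0
    sigmas: tuple[float, ...] = (2.0, 3.75, 5.0)
    methods: tuple[str, ...] = ("RS", "CS", "SC")
    n_trials: int = 100
    repetitions: int = 1000
    n_boot: int = 500
    seed: int = 0
    lapse_rate: float = 0.0
    validity_rule: ValidityRule = DEFAULT_VALIDITY_RULE

    def __post_init__(self):
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if any(s < 0 for s in self.sigmas):
            raise ValueError("all sigmas must be >= 0")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}; choose from {METHODS}")


def _rep_rng(master: int, method_idx: int, sigma_idx: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(master), method_idx, sigma_idx, rep])
    )


@dataclass
class CellResult:
    """Aggregated results of one (method, sigma, n_trials) cell."""

    method: str
    sigma: float
    n_trials: int
    pse: np.ndarray  # per repetition; NaN where the base fit failed
    slope: np.ndarray
    converged: np.ndarray
    sd_pse: np.ndarray  # NaN where invalid
    sd_slope: np.ndarray
    valid_pse: np.ndarray
    valid_slope: np.ndarray
    occupancy: np.ndarray  # pooled per-level trial counts across repetitions

    @property
    def repetitions(self) -> int:
        return len(self.pse)

    @property
    def mean_pse(self) -> float:
        return float(np.nanmean(self.pse))

    @property
    def mean_slope(self) -> float:
        return float(np.nanmean(self.slope))

    @property
    def mean_sd_pse(self) -> float:
        return float(np.nanmean(self.sd_pse))

    @property
    def mean_sd_slope(self) -> float:
        return float(np.nanmean(self.sd_slope))

    @property
    def failure_rate_pse(self) -> float:
        return failure_rate(self.valid_pse.tolist())

    @property
    def failure_rate_slope(self) -> float:
        return failure_rate(self.valid_slope.tolist())


class ComparisonSummary:
    """Results of a full harness run, keyed by (method, sigma, n_trials)."""

    def __init__(self, config: HarnessConfig, cells: dict[tuple[str, float, int], CellResult]):
        self.config = config
        self.cells = cells

    def cell(self, method: str, sigma: float, n_trials: int | None = None) -> CellResult:
        n = self.config.n_trials if n_trials is None else n_trials
        return self.cells[(method, float(sigma), n)]

    def to_long_frame(self) -> pd.DataFrame:
        """One row per repetition: estimates, SDs and validity flags."""
        rows = []
        for (method, sigma, n), cell in self.cells.items():
            for rep in range(cell.repetitions):
                rows.append(
                    {
                        "method": method,
                        "sigma": sigma,
                        "n_trials": n,
                        "rep": rep,
                        "seed": self.config.seed,
                        "pse": cell.pse[rep],
                        "slope": cell.slope[rep],
                        "converged": bool(cell.converged[rep]),
                        "sd_pse": cell.sd_pse[rep],
                        "sd_slope": cell.sd_slope[rep],
                        "valid_pse": bool(cell.valid_pse[rep]),
                        "valid_slope": bool(cell.valid_slope[rep]),
                    }
                )
        return pd.DataFrame(rows)

    def to_summary_frame(self) -> pd.DataFrame:
        """One row per cell: means, SD means and failure rates."""
        rows = []
        for (method, sigma, n), cell in self.cells.items():
            rows.append(
                {
                    "method": method,
                    "sigma": sigma,
                    "n_trials": n,
                    "repetitions": cell.repetitions,
                    "mean_pse": cell.mean_pse,
                    "mean_slope": cell.mean_slope,
                    "mean_sd_pse": cell.mean_sd_pse,
                    "mean_sd_slope": cell.mean_sd_slope,
                    "failure_rate_pse": cell.failure_rate_pse,
                    "failure_rate_slope": cell.failure_rate_slope,
                }
            )
        return pd.DataFrame(rows)

    def occupancy_frame(self) -> pd.DataFrame:
        """Pooled per-level trial counts, one row per (cell, level)."""
        grid = self.config.grid
        rows = []
        for (method, sigma, n), cell in self.cells.items():
            for i, count in enumerate(cell.occupancy):
                rows.append(
                    {
                        "method": method,
                        "sigma": sigma,
                        "n_trials": n,
                        "level_index": i,
                        "level_value": grid.values[i],
                        "count": int(count),
                    }
                )
        return pd.DataFrame(rows)

    def save(self, out_dir) -> None:
        """Write the per-repetition, summary and occupancy CSV tables."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_long_frame().to_csv(out / "repetitions.csv", index=False)
        self.to_summary_frame().to_csv(out / "summary.csv", index=False)
        self.occupancy_frame().to_csv(out / "occupancy.csv", index=False)


def run_cell(
    config: HarnessConfig, method: str, sigma: float, method_idx: int, sigma_idx: int
) -> CellResult:
    """Run all repetitions of one (method, sigma) cell."""
    grid = config.grid
    observer = SimulatedObserver(config.pivot, sigma, config.lapse_rate)
    reps = config.repetitions
    pse = np.full(reps, np.nan)
    slope = np.full(reps, np.nan)
    converged = np.zeros(reps, dtype=bool)
    sd_pse = np.full(reps, np.nan)
    sd_slope = np.full(reps, np.nan)
    valid_pse = np.zeros(reps, dtype=bool)
    valid_slope = np.zeros(reps, dtype=bool)
    occupancy = np.zeros(grid.n_levels, dtype=np.int64)

    for rep in range(reps):
        rng = _rep_rng(config.seed, method_idx, sigma_idx, rep)
        sampler = make_sampler(method, grid, rng, n_trials=config.n_trials)
        trials = run_block(sampler, observer, config.n_trials, rng)
        for t in trials:
            occupancy[t.level_index] += 1
        try:
            fit = fit_trials(trials, grid)
        except ValueError:  # fewer than two occupied levels (recorded, never fatal)
            continue
        converged[rep] = fit.converged
        if fit.converged:
            pse[rep] = fit.pse
            slope[rep] = fit.slope
        if config.n_boot > 0:
            sds = bootstrap_sds(
                trials,
                grid,
                n_boot=config.n_boot,
                rng=rng,
                base_fit=fit,
                rule=config.validity_rule,
            )
            sd_pse[rep] = sds.sd_pse
            sd_slope[rep] = sds.sd_slope
            valid_pse[rep] = sds.pse_valid
            valid_slope[rep] = sds.slope_valid

    return CellResult(
        method=method,
        sigma=float(sigma),
        n_trials=config.n_trials,
        pse=pse,
        slope=slope,
        converged=converged,
        sd_pse=sd_pse,
        sd_slope=sd_slope,
        valid_pse=valid_pse,
        valid_slope=valid_slope,
        occupancy=occupancy,
    )


def run_comparison(config: HarnessConfig, progress: bool = False) -> ComparisonSummary:
    """Run every (method, sigma) cell of the study; deterministic in the seed."""
    cells: dict[tuple[str, float, int], CellResult] = {}
    for mi, method in enumerate(config.methods):
        for si, sigma in enumerate(config.sigmas):
            if progress:
                print(f"  running {method} at sigma={sigma} ...", flush=True)
            cells[(method, float(sigma), config.n_trials)] = run_cell(
                config, method, sigma, mi, si
            )
    return ComparisonSummary(config, cells)


def occupancy_histogram(trials: Iterable, n_levels: int) -> np.ndarray:
    """Pooled per-level trial counts from records or nested record lists."""
    counts = np.zeros(n_levels, dtype=np.int64)
    stack = list(trials)
    if not stack:
        raise ValueError("no trials to histogram")
    for item in stack:
        if isinstance(item, TrialRecord):
            counts[item.level_index] += 1
        else:
            for t in item:
                counts[t.level_index] += 1
    return counts


class BlandAltman(NamedTuple):
    mean_diff: float
    loa_low: float
    loa_high: float


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltman:
    """Mean difference and 95% limits of agreement of paired estimates.

    ``mean_diff = mean(x - y)``; limits are ``mean_diff +/- 1.96 * SD(x - y)``
    with the sample (n-1) standard deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired vectors differ in length: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(mean, mean - 1.96 * sd, mean + 1.96 * sd)


class AgreementRegression(NamedTuple):
    r_squared: float
    slope: float
    intercept: float


def agreement_regression(x: Sequence[float], y: Sequence[float]) -> AgreementRegression:
    """OLS of y on x plus the coefficient of determination."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired vectors differ in length: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; regression undefined")
    res = stats.linregress(x, y)
    return AgreementRegression(float(res.rvalue**2), float(res.slope), float(res.intercept))


def compare_sd_distributions(sd_a: Sequence[float], sd_b: Sequence[float]):
    """Two-sample Student's t-test between SD distributions (NaNs dropped).

    Plumbing for significance reporting; the scientific comparisons rest on
    the orderings of the means, not on p-values.
    """
    a = np.asarray(sd_a, dtype=float)
    b = np.asarray(sd_b, dtype=float)
    return stats.ttest_ind(a[~np.isnan(a)], b[~np.isnan(b)])
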