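"""Maximum-likelihood psychometric fitting and bootstrap dispersion.

The logistic fit maximizes the binomial log-likelihood of the per-level
tallies with guess and lapse rates fixed at zero (the function is forced
between 0 and 1).  Internally the model is parameterized as
``eta = b0 + b1 * x`` with ``pse = -b0/b1`` and ``slope = b1``; the
log-likelihood is globally concave in ``(b0, b1)``, so a coarse multi-start
grid (PSE candidates at the grid levels crossed with log-spaced slopes)
followed by damped Newton ascent reaches the global optimum.  The Newton
stage is vectorized across tallies, which is what makes bootstrapping
hundreds of resamples per block cheap.

Bootstrap standard deviations come from nonparametric resampling of the
trial list with replacement; a resample estimate is *usable* iff its refit
converges with the PSE inside the grid span extended by one span on each
side and the slope within wide plausibility bounds.  The SD itself is
*invalid* when too few resamples are usable or the SD exceeds its
plausibility bound — failure rates aggregate exactly these flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit

from .core import (
    UP,
    GaussianOffsetModel,
    LevelGrid,
    PsychometricFit,
    ResponseTally,
    TrialRecord,
)

__all__ = [
    "ValidityRule",
    "DEFAULT_VALIDITY_RULE",
    "BootstrapSDs",
    "fit_logistic",
    "fit_trials",
    "bootstrap_sds",
    "attach_bootstrap",
    "failure_rate",
    "fit_gaussian_offset",
]

_REL_LL_TOL = 1e-8  # relative log-likelihood change declaring convergence
_MAX_NEWTON_ITER = 200
_SLOPE_CANDIDATES = np.logspace(-2, 2, 17)


@dataclass(frozen=True)
class ValidityRule:
    """Thresholds deciding when a bootstrap SD estimate is usable/valid.

    A resample is usable iff its refit converged, its PSE lies within the
    grid span extended by ``pse_margin_spans`` full spans on each side, and
    its slope lies in ``(slope_min, slope_max)``.  The SD is invalid iff
    fewer than ``min_usable_fraction`` of resamples are usable, or the PSE
    SD exceeds the grid span, or the slope SD exceeds ``slope_max``.
    """

    min_usable_fraction: float = 0.5
    pse_margin_spans: float = 1.0
    slope_min: float = 1e-4
    slope_max: float = 1e3


DEFAULT_VALIDITY_RULE = ValidityRule()


@dataclass(frozen=True)
class BootstrapSDs:
    """Bootstrap SDs of PSE and slope with per-parameter validity."""

    sd_pse: float
    sd_slope: float
    pse_valid: bool
    slope_valid: bool
    n_usable: int
    n_boot: int


def _loglik(n_up: np.ndarray, n_tot: np.ndarray, eta: np.ndarray) -> np.ndarray:
    # sum_k [ n_up * log p + (n_tot - n_up) * log(1-p) ] in a stable form:
    # log p = eta - softplus(eta), log(1-p) = -softplus(eta)
    return (n_up * eta - n_tot * np.logaddexp(0.0, eta)).sum(axis=-1)


@lru_cache(maxsize=32)
def _candidate_tables(levels: tuple[float, ...]):
    """Multi-start candidates for a given level set: (b0, b1, eta, softplus)."""
    x = np.asarray(levels, dtype=float)
    pse_c, slope_c = np.meshgrid(x, _SLOPE_CANDIDATES, indexing="ij")
    b1 = slope_c.ravel()
    b0 = -(b1 * pse_c.ravel())
    eta = b0[:, None] + b1[:, None] * x[None, :]
    return x, b0, b1, eta, np.logaddexp(0.0, eta)


def _fit_counts_batch(
    n_up: np.ndarray, n_tot: np.ndarray, levels: tuple[float, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit many tallies over a common level set at once.

    Returns (pse, slope, converged, loglik) arrays of length B.  Rows whose
    responses are degenerate (all "up", all "down", fewer than two occupied
    levels) or whose likelihood has no interior maximum come back with
    ``converged = False``.
    """
    x, b0c, b1c, eta_c, sp_c = _candidate_tables(tuple(levels))
    n_up = np.asarray(n_up, dtype=float)
    n_tot = np.asarray(n_tot, dtype=float)
    if n_up.ndim == 1:
        n_up = n_up[None, :]
        n_tot = n_tot[None, :]
    b = n_up.shape[0]

    # multi-start: best coarse candidate per tally
    ll_grid = n_up @ eta_c.T - n_tot @ sp_c.T
    best = np.argmax(ll_grid, axis=1)
    b0 = b0c[best].copy()
    b1 = b1c[best].copy()
    ll = ll_grid[np.arange(b), best]

    fittable = (
        ((n_tot > 0).sum(axis=1) >= 2)
        & (n_up.sum(axis=1) > 0)
        & (n_up.sum(axis=1) < n_tot.sum(axis=1))
    )
    active = fittable.copy()
    converged = np.zeros(b, dtype=bool)

    for _ in range(_MAX_NEWTON_ITER):
        if not active.any():
            break
        eta = b0[:, None] + b1[:, None] * x[None, :]
        p = expit(eta)
        resid = n_up - n_tot * p
        g0 = resid.sum(axis=1)
        g1 = (resid * x).sum(axis=1)
        w = n_tot * p * (1.0 - p)
        h00 = w.sum(axis=1)
        h01 = (w * x).sum(axis=1)
        h11 = (w * x * x).sum(axis=1)
        det = h00 * h11 - h01 * h01
        singular = active & ~(det > 1e-12 * (h00 * h11 + 1e-300))
        active &= ~singular  # flat likelihood direction: no interior optimum
        with np.errstate(divide="ignore", invalid="ignore"):
            d0 = np.where(active, (h11 * g0 - h01 * g1) / det, 0.0)
            d1 = np.where(active, (h00 * g1 - h01 * g0) / det, 0.0)

        # damped step: halve until the log-likelihood does not decrease
        step = np.ones(b)
        nb0, nb1 = b0 + d0, b1 + d1
        nll = _loglik(n_up, n_tot, nb0[:, None] + nb1[:, None] * x[None, :])
        for _ in range(40):
            worse = active & (nll < ll - 1e-12)
            if not worse.any():
                break
            step[worse] *= 0.5
            nb0 = np.where(worse, b0 + step * d0, nb0)
            nb1 = np.where(worse, b1 + step * d1, nb1)
            nll = np.where(
                worse,
                _loglik(n_up, n_tot, nb0[:, None] + nb1[:, None] * x[None, :]),
                nll,
            )

        delta = np.abs(nll - ll)
        b0 = np.where(active, nb0, b0)
        b1 = np.where(active, nb1, b1)
        ll = np.where(active, nll, ll)
        just_conv = active & (delta < _REL_LL_TOL * (np.abs(ll) + 1.0))
        converged |= just_conv
        runaway = active & ((np.abs(b1) > 1e6) | (np.abs(b0) > 1e8))
        active &= ~just_conv & ~runaway

    slope = b1
    with np.errstate(divide="ignore", invalid="ignore"):
        pse = np.where(b1 != 0, -b0 / b1, np.nan)
    ok = converged & (slope > 0) & np.isfinite(pse)
    return pse, slope, ok, ll


def fit_logistic(tally: ResponseTally) -> PsychometricFit:
    """Maximum-likelihood logistic fit of a per-level response tally.

    Raises ``ValueError`` if fewer than two levels carry trials.  Returns
    ``converged = False`` (with the boundary parameters reached) when the
    likelihood has no interior maximum — all responses identical, or
    responses perfectly separable by level so the slope diverges.
    """
    levels, n_tot, n_up = tally.arrays()
    if int((n_tot > 0).sum()) < 2:
        raise ValueError("need trials at no fewer than 2 levels to fit")
    pse, slope, ok, ll = _fit_counts_batch(n_up, n_tot, tuple(levels.tolist()))
    return PsychometricFit(
        pse=float(pse[0]), slope=float(slope[0]), converged=bool(ok[0]), loglik=float(ll[0])
    )


def fit_trials(trials: Sequence[TrialRecord], grid: LevelGrid) -> PsychometricFit:
    """Convenience: tally a trial log on its grid, then fit."""
    return fit_logistic(ResponseTally.from_trials(trials, grid))


def bootstrap_sds(
    trials: Sequence[TrialRecord],
    grid: LevelGrid,
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
    base_fit: PsychometricFit | None = None,
    rule: ValidityRule = DEFAULT_VALIDITY_RULE,
) -> BootstrapSDs:
    """Nonparametric bootstrap SDs of the fitted PSE and slope.

    Resamples the trial list with replacement (resample size = original
    size), refits every resample, and takes the sample SD of the usable
    estimates.  Both SDs are invalid when the base fit did not converge.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = len(trials)
    if base_fit is None and n > 0:
        base_fit = fit_trials(trials, grid)
    if n == 0 or base_fit is None or not base_fit.converged:
        return BootstrapSDs(math.nan, math.nan, False, False, 0, n_boot)

    k = grid.n_levels
    lev_idx = np.fromiter((t.level_index for t in trials), dtype=np.intp, count=n)
    is_up = np.fromiter((t.response == UP for t in trials), dtype=float, count=n)

    draw = rng.integers(0, n, size=(n_boot, n))
    flat = lev_idx[draw] + k * np.arange(n_boot)[:, None]
    n_tot = np.bincount(flat.ravel(), minlength=n_boot * k).reshape(n_boot, k)
    n_up = np.bincount(
        flat.ravel(), weights=is_up[draw].ravel(), minlength=n_boot * k
    ).reshape(n_boot, k)

    pse, slope, ok, _ = _fit_counts_batch(n_up, n_tot, grid.values)
    lo, hi = grid.values[0], grid.values[-1]
    span = grid.span
    margin = rule.pse_margin_spans * span
    usable = (
        ok
        & (pse >= lo - margin)
        & (pse <= hi + margin)
        & (slope > rule.slope_min)
        & (slope < rule.slope_max)
    )
    n_usable = int(usable.sum())

    if n_usable < max(2, math.ceil(rule.min_usable_fraction * n_boot)):
        return BootstrapSDs(math.nan, math.nan, False, False, n_usable, n_boot)

    sd_pse = float(np.std(pse[usable], ddof=1))
    sd_slope = float(np.std(slope[usable], ddof=1))
    pse_valid = sd_pse <= span
    slope_valid = sd_slope <= rule.slope_max
    return BootstrapSDs(
        sd_pse if pse_valid else math.nan,
        sd_slope if slope_valid else math.nan,
        pse_valid,
        slope_valid,
        n_usable,
        n_boot,
    )


def attach_bootstrap(fit: PsychometricFit, sds: BootstrapSDs) -> PsychometricFit:
    """Copy bootstrap SDs and validity flags onto a fit (in place)."""
    fit.sd_pse = sds.sd_pse
    fit.sd_slope = sds.sd_slope
    fit.sd_pse_valid = sds.pse_valid
    fit.sd_slope_valid = sds.slope_valid
    return fit


def failure_rate(validity_flags: Sequence[bool]) -> float:
    """Percentage of invalid SD estimations among ``validity_flags``."""
    flags = list(validity_flags)
    if not flags:
        raise ValueError("failure rate of an empty result list is undefined")
    invalid = sum(1 for f in flags if not f)
    return 100.0 * invalid / len(flags)


def fit_gaussian_offset(tally, counts=None) -> GaussianOffsetModel:
    """Least-squares Gaussian-plus-vertical-offset fit of a trial histogram.

    Accepts a ``ResponseTally`` (fits its presentation counts) or a pair of
    arrays ``(levels, counts)``.  A flat histogram is degenerate: the bump
    amplitude is ~0, the center is unidentifiable (flagged) and the offset
    is still returned.
    """
    if isinstance(tally, ResponseTally):
        levels, n_tot, _ = tally.arrays()
        counts = n_tot.astype(float)
    else:
        levels = np.asarray(tally, dtype=float)
        counts = np.asarray(counts, dtype=float)
    occupied = int((counts > 0).sum())
    if occupied < 4:
        raise ValueError(
            f"Gaussian+offset has 4 free parameters; need >= 4 occupied levels, got {occupied}"
        )
    span = levels[-1] - levels[0]

    if np.ptp(counts) == 0:  # exactly flat: amplitude 0, center arbitrary
        return GaussianOffsetModel(
            amplitude=0.0,
            center=float(levels.mean()),
            width=span / 4.0,
            offset=float(counts[0]),
            center_identifiable=False,
        )

    def model(x, amplitude, center, width, offset):
        return amplitude * np.exp(-((x - center) ** 2) / (2.0 * width**2)) + offset

    p0 = (
        float(counts.max() - counts.min()),
        float(levels[int(np.argmax(counts))]),
        span / 4.0,
        float(counts.min()),
    )
    bounds = (
        [0.0, levels[0] - span, 1e-6 * span, 0.0],
        [np.inf, levels[-1] + span, 10.0 * span, np.inf],
    )
    popt, _ = curve_fit(model, levels, counts, p0=p0, bounds=bounds, maxfev=20000)
    amplitude, center, width, offset = (float(v) for v in popt)
    identifiable = amplitude > 1e-6 * max(counts.max(), 1.0)
    return GaussianOffsetModel(
        amplitude=amplitude,
        center=center,
        width=width,
        offset=offset,
        center_identifiable=identifiable,
    )
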