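# Methods

## The measurement problem

A 2AFC session probes the point of subjective equality: the stimulus level
at which the observer's two responses are equiprobable. Constant stimuli
estimates it robustly but spends trials uniformly over the range; a fixed-
step staircase concentrates trials near the PSE but yields poor slope
estimates because it rarely samples the flanks. The Random Step procedure
is a compromise: it follows the one-up-one-down logic (a response "up" at
level *k* sends the next trial below *k*, "down" sends it above) but draws
the next level uniformly from the entire admissible side of the grid, so
trials pile up near the PSE while every level — boundaries included — keeps
a fixed, nonzero probability of being probed on any trial.

## Observer model

Responses are simulated by a signal-detection observer: on a trial at level
*x* an internal value v ~ Normal(x, σ) is compared with a fixed pivot (the
true PSE); the response is "up" iff v > pivot. Its analytic response curve
is Φ((x − pivot)/σ) — a probit, deliberately not the logistic used for
fitting, so the fit is a (very good) approximation rather than a tautology.
With σ = 0 the curve degenerates to a 0/0.5/1 step, and the measure-zero
tie v = pivot resolves to "down" (documented for exactness; at σ = 0 and
x = pivot exactly, the simulator therefore answers "down" always while the
analytic curve reports 0.5 — an isolated point with no effect at σ > 0).
A lapse rate λ ∈ [0, 0.5) replaces the judgment with a fair coin flip with
probability λ (a uniform-guess lapse, the symmetric standard choice), giving
the analytic curve λ/2 + (1 − λ)Φ((x − pivot)/σ).

## Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| grid | integers 1..20 | stimulus levels | 20-level simulation grid with the pivot on-grid; the 15-level interocular phase-shift grid (±1.5° … 0°, labels −7..7) is provided for experimental data |
| pivot | 13 | grid levels | off-center on purpose: places the PSE asymmetrically in the range |
| σ | 2, 3.75, 5 | grid levels | low / medium / high observer noise regimes |
| n_trials | 100 | trials/block | a practical session length |
| repetitions | 1,000 | blocks/cell | desk-scale Monte-Carlo; 10,000 reproduces study scale by config |
| n_boot | 500 | resamples | bootstrap SD stabilizes well below this (two independent 2,000-resample runs agree within 10%) |
| lapse | 0 | probability | lapses are opt-in; 5% models finger errors |
| SC step | 1 | grid index | finest step on a discrete grid |

Samplers, observer and bootstrap all consume one seeded
`numpy.random.Generator` per block, interleaved proposal-then-response, so
one integer reproduces a whole session. Harness repetition seeds derive
from `SeedSequence([master, method_index, sigma_index, repetition])`,
making every cell independently recomputable.

## Fitting

The logistic ML fit is computed in the natural-parameter form
η = b₀ + b₁x (PSE = −b₀/b₁, slope = b₁), in which the binomial
log-likelihood is globally concave. A coarse multi-start grid (PSE
candidates at the grid levels × 17 log-spaced slopes in [10⁻², 10²]) picks
the best starting point, then damped Newton ascent (step-halving keeps the
likelihood non-decreasing) runs to a relative log-likelihood change below
10⁻⁸. Concavity makes the optimum global, which the test suite verifies
against a brute-force 200 × 200 parameter-grid oracle. The Newton stage is
vectorized across tallies so that hundreds of bootstrap refits per block
cost about a millisecond. Degenerate data — all responses identical, or
perfectly separable by level, where the slope diverges — terminate via a
singular-Hessian or runaway-parameter guard and are reported as
`converged = False`. No guess or lapse parameters enter the fit: the curve
is forced between 0 and 1.

Bootstrap SDs use nonparametric resampling of the trial list with
replacement (resample size = original size), chosen because it applies
identically to RS, CS and SC logs and assumes no model. A resample estimate
is *usable* iff its refit converges, the PSE lies within the grid span
extended by one full span on each side, and the slope lies in (10⁻⁴, 10³);
an SD is *invalid* iff fewer than 50% of resamples are usable, or the PSE
SD exceeds the grid span (slope SD: the 10³ bound). Failure rates are the
percentage of repetitions with an invalid SD, per parameter. All thresholds
sit in a `ValidityRule` and are configurable. Two caveats follow from this
design: because the optimizer is globally convergent, refits essentially
never fail where a local simplex search would, so failure rates here run
far below what fragile-optimizer pipelines report; and because only
SDs above the full grid span are censored, heavy upper tails of an SD
distribution (notably SC at high noise) remain in the means.

The Gaussian-plus-offset histogram characterization
(count ≈ A·exp(−(x−c)²/2w²) + o) is least squares via
`scipy.optimize.curve_fit` with nonnegativity bounds on A and o; an exactly
flat histogram short-circuits to A = 0 with the center flagged
unidentifiable.

## What the simulations do and do not show

The generator reproduces the study conditions (grid 1..20, pivot 13,
σ ∈ {2, 3.75, 5}, 100-trial blocks) with a stationary, memoryless observer.
It deliberately omits adaptation, habituation, fatigue and sequential
response dependencies, and models lapses as symmetric guesses; passing
tests therefore validate the placement and estimation machinery, not
robustness to those human effects.

Two structural properties of the RS chain are worth stating because they
are exact, not sampling accidents (both follow from power iteration of the
explicit K × K transition matrix — probit response probabilities times the
two uniform half-range rules):

- With the pivot at 13 on 1..20, the stationary occupancy is right-skewed:
  the 7 levels above the pivot receive proposals concentrated from a narrow
  upper range while the 12 below dilute theirs, so the upper boundary
  collects ~1.7× the trials of the lower one, and the least-squares
  Gaussian+offset center lands near 14.5 rather than 13 even though the
  histogram *peak* sits at level 13–14.
- The pooled placement ratio "mean count over the three levels nearest the
  pivot over the mean count at the two extremes" is ≈1.56 at σ = 2
  (≈1.54 in 100-trial blocks); against the *far* boundary alone the peak
  ratio is ≈2.2. The offset term of the long-run fit accounts for ≈0.55 of
  all trials — about half the session keeps probing the full range.

## Numerical and design choices

- Response coding: "up" ⇔ judged above the PSE, coded 1 when tallying.
- RS "below the tested stimulus" is read strictly (the current level is
  excluded); a response whose admissible side is empty ("up" at the lowest
  level) repeats the boundary level — the minimal-assumption rule for a
  case that near-never occurs at realistic σ.
- SC starts at a uniformly random level (symmetric with RS) and its PSE is
  estimated by the same logistic fit as the other methods; no
  reversal-averaging rule is used.
- CS remainder trials (n not divisible by K) go to uniformly chosen
  distinct levels, so counts differ by at most one.
- Between-method significance on SD distributions is a two-sample Student's
  t-test, provided as plumbing; the scientific claims rest on orderings of
  means, not p-values.
- Slope is reported as the logistic steepness β (with β/4, the derivative
  at the midpoint, as a convenience accessor); absolute slope values are
  parameterization-specific and comparisons across toolboxes should be
  qualitative.

## Known limitations

- Probit/Weibull psychometric shapes, non-zero guess rates, transformed or
  interleaved staircases and Bayesian placement (QUEST/Psi-style) are out
  of scope.
- Failure-rate magnitudes depend strongly on the invalidity rule and the
  optimizer's robustness; with the defaults above they are near zero in all
  simulated cells, and only orderings across conditions are meaningful.
- Human-subject agreement numbers cannot be reproduced without human data;
  the agreement utilities (`agreement_regression`, `bland_altman`) are
  exercised on simulated paired sessions instead.
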