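"""Simulate one Random Step session and fit its psychometric function.

A 300-trial 2AFC session is run against a noisy simulated observer whose
true PSE (pivot) is 13 on the integer grid 1..20.  The logistic MLE then
recovers the PSE and slope, and a nonparametric bootstrap attaches standard
deviations to both.
"""

import numpy as np

from randstep import (
    RandomStepSampler,
    SimulatedObserver,
    attach_bootstrap,
    bootstrap_sds,
    default_simulation_grid,
    fit_trials,
    run_block,
)

grid = default_simulation_grid()
observer = SimulatedObserver(pivot=13.0, sigma=2.0)
rng = np.random.default_rng(7)

sampler = RandomStepSampler(grid, rng)
trials = run_block(sampler, observer, n_trials=300, rng=rng)
fit = fit_trials(trials, grid)
attach_bootstrap(fit, bootstrap_sds(trials, grid, n_boot=500, rng=rng, base_fit=fit))

print(f"trials:   {len(trials)}  (levels {grid.values[0]:.0f}..{grid.values[-1]:.0f})")
print(f"PSE:      {fit.pse:.3f} +/- {fit.sd_pse:.3f}   (true pivot 13)")
print(f"slope:    {fit.slope:.3f} +/- {fit.sd_slope:.3f}  (steepness beta; beta/4 = {fit.midpoint_derivative:.3f} at midpoint)")
print(f"converged: {fit.converged}, SDs valid: pse={fit.sd_pse_valid} slope={fit.sd_slope_valid}")
# The PSE should land within a few tenths of the pivot; the slope reflects
# the observer noise (larger sigma -> shallower psychometric function).
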