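import numpy as np
import pytest

from randstep import LevelGrid, SimulatedObserver, default_simulation_grid


@pytest.fixture
def unit_grid() -> LevelGrid:
    """Integer levels 1..20, the simulation-study grid."""
    return default_simulation_grid()


@pytest.fixture
def standard_observer() -> SimulatedObserver:
    """Pivot 13, sigma 2: the reference simulated observer."""
    return SimulatedObserver(pivot=13.0, sigma=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def brute_force_loglik_max(levels, n_tot, n_up, pse_grid, slope_grid):
    """Independent oracle: binomial log-likelihood maximized over a parameter grid.

    Evaluates sum_k [n_up log p + (n_tot - n_up) log(1-p)] with the logistic
    p = 1/(1+exp(-slope (x - pse))) at every (pse, slope) node, directly and
    without any code path shared with the fitting module.
    """
    levels = np.asarray(levels, float)
    n_tot = np.asarray(n_tot, float)
    n_up = np.asarray(n_up, float)
    best = -np.inf
    for pse in pse_grid:
        eta = np.multiply.outer(np.asarray(slope_grid, float), levels - pse)
        logp = -np.logaddexp(0.0, -eta)
        log1mp = -np.logaddexp(0.0, eta)
        ll = (n_up * logp + (n_tot - n_up) * log1mp).sum(axis=1)
        best = max(best, float(ll.max()))
    return best


def rs_markov_stationary(levels, pivot, sigma):
    """Independent oracle: stationary occupancy of the Random Step chain.

    Builds the K x K transition matrix by hand from the two uniform
    half-range rules and the observer's analytic response probabilities,
    then power-iterates to convergence.
    """
    from scipy.stats import norm

    levels = np.asarray(levels, float)
    k = len(levels)
    if sigma == 0:
        p_up = np.where(levels > pivot, 1.0, 0.0)  # tie at the pivot -> "down"
    else:
        p_up = norm.cdf((levels - pivot) / sigma)
    t = np.zeros((k, k))
    for i in range(k):
        if i == 0:
            t[i, 0] += p_up[i]  # empty lower range: repeat boundary
        else:
            t[i, :i] += p_up[i] / i
        if i == k - 1:
            t[i, k - 1] += 1.0 - p_up[i]
        else:
            t[i, i + 1 :] += (1.0 - p_up[i]) / (k - 1 - i)
    v = np.full(k, 1.0 / k)
    for _ in range(200000):
        nxt = v @ t
        if np.abs(nxt - v).sum() < 1e-14:
            v = nxt
            break
        v = nxt
    return v
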