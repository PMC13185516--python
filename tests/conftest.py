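import numpy as np
import pytest

from pcsm.simulator import SimulationConfig, simulate_cohort
from pcsm.state_model import GmmHmmParams, fit_global


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Six low/medium-noise subjects at reduced spatial scale for fast fits."""
    base = SimulationConfig(n_nodes=40, n_trials=40)
    configs, tabs, truths, firs = simulate_cohort(
        3, seed=7, base_config=base, regimes=("medium",),
        noise_levels=("low", "medium"))
    return configs, tabs, truths, firs


@pytest.fixture(scope="session")
def small_global_fit(small_cohort):
    _, _, _, firs = small_cohort
    return fit_global(firs, C=3, M=2, n_init=2, max_iter=40, seed=5)


def make_params(C=3, M=2, N=4, seed=0, spread=3.0, var=0.04,
                spatial_cov=None) -> GmmHmmParams:
    """Well-separated synthetic GMM-HMM parameters for oracle tests."""
    r = np.random.default_rng(seed)
    start = r.dirichlet(np.ones(C) * 5)
    trans = r.dirichlet(np.ones(C) * 2, size=C)
    weights = r.dirichlet(np.ones(M) * 5, size=C)
    centres = np.linspace(-spread, spread, C)
    means = np.empty((C, M, N))
    for c in range(C):
        for m in range(M):
            means[c, m] = centres[c] + (m - (M - 1) / 2) * 1.0 + r.normal(0, 0.1, N)
    variances = np.full((C, M, N), var)
    return GmmHmmParams(startprob=start, transmat=trans, weights=weights,
                        means=means, variances=variances,
                        spatial_cov=spatial_cov)
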