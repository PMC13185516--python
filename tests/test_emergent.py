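import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcsm import emergent
from pcsm.emergent import (CohortScaler, classify_mode, cognitive_demand,
                           node_response_posterior, poisson_binomial_pmf,
                           resource_level, robust_scale, serial_bottleneck,
                           serial_parallel_deviation, tanh_squash)
from pcsm.fir import FirSeries
from pcsm.state_model import PosteriorTrajectory

from conftest import make_params


def _traj(pi):
    pi = np.asarray(pi, dtype=float)
    return PosteriorTrajectory(pi=pi, viterbi=np.argmax(pi, axis=1),
                               loglik=0.0, seq_lengths=[len(pi)])


# ---------------------------------------------------------------------------
# node response posterior


def test_node_response_degenerate_mixture_sums_posteriors(rng):
    """With all weight on the responding mixture, B_t,n = sum_c pi_t,c = 1."""
    params = make_params(C=3, M=2, N=4, seed=0)
    params.weights[:] = [0.0, 1.0]
    pi = rng.dirichlet(np.ones(3), size=10)
    fir = FirSeries(values=rng.normal(size=(10, 4)),
                    trials=np.repeat(np.arange(2), 5),
                    delays=np.tile(np.arange(5), 2))
    B = node_response_posterior(fir, params, _traj(pi))
    assert np.allclose(B, 1.0, atol=1e-12)


def test_node_response_equal_densities_reduce_to_weights(rng):
    """Identical component densities give gamma = weights, B = sum pi * a."""
    params = make_params(C=3, M=2, N=4, seed=1)
    params.means[:, 1, :] = params.means[:, 0, :]
    params.variances[:, 1, :] = params.variances[:, 0, :]
    pi = rng.dirichlet(np.ones(3), size=8)
    fir = FirSeries(values=rng.normal(size=(8, 4)),
                    trials=np.repeat(np.arange(2), 4),
                    delays=np.tile(np.arange(4), 2))
    B = node_response_posterior(fir, params, _traj(pi))
    expected = (pi @ params.weights[:, 1])[:, None] * np.ones(4)
    assert np.allclose(B, expected, atol=1e-10)


def test_node_response_matches_bayes_rule_oracle(rng):
    params = make_params(C=3, M=2, N=3, seed=2)
    pi = rng.dirichlet(np.ones(3), size=6)
    X = rng.normal(size=(6, 3))
    fir = FirSeries(values=X, trials=np.repeat(np.arange(2), 3),
                    delays=np.tile(np.arange(3), 2))
    B = node_response_posterior(fir, params, _traj(pi))
    for t in range(6):
        for n in range(3):
            expected = 0.0
            for c in range(3):
                dens = [params.weights[c, m]
                        * math.exp(-0.5 * (X[t, n] - params.means[c, m, n]) ** 2
                                   / params.variances[c, m, n])
                        / math.sqrt(2 * math.pi * params.variances[c, m, n])
                        for m in range(2)]
                expected += pi[t, c] * dens[1] / (dens[0] + dens[1])
            assert B[t, n] == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# Poisson binomial and serial-parallel deviation


def test_pmf_binomial_and_degenerate_cases():
    assert np.allclose(poisson_binomial_pmf([0.5, 0.5]), [0.25, 0.5, 0.25])
    pmf = poisson_binomial_pmf([1.0] * 4)
    assert np.allclose(pmf, [0, 0, 0, 0, 1])
    with pytest.raises(ValueError):
        poisson_binomial_pmf([0.5, 1.2])


def test_pmf_matches_subset_enumeration(rng):
    """DP convolution equals the exponential sum over all 2^N outcomes."""
    q = rng.uniform(size=10)
    pmf = poisson_binomial_pmf(q)
    oracle = np.zeros(11)
    for bits in itertools.product([0, 1], repeat=10):
        p = 1.0
        for n, b in enumerate(bits):
            p *= q[n] if b else 1 - q[n]
        oracle[sum(bits)] += p
    assert np.allclose(pmf, oracle, atol=1e-12)
    assert pmf.sum() == pytest.approx(1.0, abs=1e-10)


def test_dsp_trivial_cases():
    assert serial_parallel_deviation(np.ones((1, 4)))[0] == pytest.approx(1.0)
    assert serial_parallel_deviation(np.asarray([[0.5, 0.5]]))[0] == \
        pytest.approx(0.5)
    with pytest.raises(ValueError):
        serial_parallel_deviation(np.empty((1, 0)))


def test_dsp_matches_enumeration_expectation(rng):
    q = rng.uniform(size=12)
    d = serial_parallel_deviation(q[None, :])[0]
    expect = 0.0
    for bits in itertools.product([0, 1], repeat=12):
        p = 1.0
        for n, b in enumerate(bits):
            p *= q[n] if b else 1 - q[n]
        expect += abs(sum(bits) - 6.0) * p
    assert d == pytest.approx(2.0 / 12.0 * expect, abs=1e-9)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
def test_dsp_bounds_and_reflection_symmetry(q):
    q = np.asarray(q)
    d = serial_parallel_deviation(q[None, :])[0]
    assert -1e-12 <= d <= 1.0 + 1e-12
    d_ref = serial_parallel_deviation((1.0 - q)[None, :])[0]
    assert d == pytest.approx(d_ref, abs=1e-10)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
def test_pmf_conserves_probability(q):
    pmf = poisson_binomial_pmf(np.asarray(q))
    assert pmf.sum() == pytest.approx(1.0, abs=1e-10)
    assert np.all(pmf >= -1e-12)


def test_classify_mode_boundaries():
    labels = classify_mode(np.asarray([0.50, 0.55, 0.70]), 0.522, 0.612)
    assert labels.tolist() == ["parallel", "mixed", "serial"]
    with pytest.raises(ValueError):
        classify_mode(np.asarray([0.5]), 0.7, 0.6)


# ---------------------------------------------------------------------------
# demand


def test_demand_static_trajectory_is_zero():
    pi = np.tile([0.2, 0.5, 0.3], (6, 1))
    d_sp = np.full(6, 0.4)
    with pytest.warns(UserWarning, match="zero MAD"):
        dem = cognitive_demand(d_sp, _traj(pi))
    assert np.allclose(dem.raw, 0.0)
    assert np.allclose(dem.squashed, 0.0)


def test_demand_squashed_always_bounded(rng):
    pi = rng.dirichlet(np.ones(3), size=50)
    d_sp = rng.uniform(size=50)
    dem = cognitive_demand(d_sp, _traj(pi))
    assert np.all(np.abs(dem.squashed) <= 1.0)
    assert np.all(np.isfinite(dem.raw))


def test_demand_matches_hand_computed_three_frame_example():
    """Step-by-step scalar evaluation of the demand recipe on 3 frames."""
    pi = np.asarray([[1, 0, 0], [0.5, 0.5, 0], [0.25, 0.25, 0.5]], dtype=float)
    d_sp = np.asarray([0.2, 0.6, 0.4])
    dem = cognitive_demand(d_sp, _traj(pi))
    ln, log2, log3 = math.log, math.log(2.0), math.log(3.0)
    # U = min-max of d_sp; deltas with t=0 fixed at 0
    U = [0.0, 1.0, 0.5]
    dU = [0.0, 1.0, -0.5]
    H = [0.0, (-2 * 0.5 * ln(0.5)) / log3,
         (-(2 * 0.25 * ln(0.25) + 0.5 * ln(0.5))) / log3]
    dH = [0.0, H[1] - H[0], H[2] - H[1]]
    # JS divergences (natural log, / ln 2)
    m1 = [0.75, 0.25]
    js1 = 0.5 * (1.0 * ln(1.0 / m1[0])) \
        + 0.5 * (0.5 * ln(0.5 / m1[0]) + 0.5 * ln(0.5 / m1[1]))
    m2 = [0.375, 0.375, 0.25]
    js2 = 0.5 * (0.5 * ln(0.5 / m2[0]) + 0.5 * ln(0.5 / m2[1])) \
        + 0.5 * (0.25 * ln(0.25 / m2[0]) + 0.25 * ln(0.25 / m2[1])
                 + 0.5 * ln(0.5 / m2[2]))
    J = [0.0, js1 / log2, js2 / log2]
    medJ = sorted(J)[1]
    dJ = [0.0, J[1] - medJ, J[2] - medJ]
    prod = [abs(a) * abs(b) for a, b in zip(dU, dJ)]
    medP = sorted(prod)[1]
    S = [p - medP for p in prod]
    base = [-(a + b + c) / 3.0 for a, b, c in zip(dU, dH, dJ)]
    omega = sum(abs(x) for x in base) / 3.0
    raw = [b - omega * s for b, s in zip(base, S)]
    assert np.allclose(dem.raw, raw, atol=1e-12)
    assert dem.components["omega_syn"] == pytest.approx(omega, abs=1e-12)


# ---------------------------------------------------------------------------
# resource level


def test_resource_zero_input_zero_output():
    mode = np.asarray(["mixed"] * 10)
    with pytest.warns(UserWarning):
        res = resource_level(np.zeros(10), mode)
    assert np.allclose(res.raw, 0.0)
    assert res.alpha == 0.0


def test_resource_halflife_closed_form():
    mode = np.asarray(["serial"] * 3 + ["mixed"] * 3 + ["serial"] * 3)
    res = resource_level(np.random.default_rng(0).normal(size=9), mode)
    assert res.dwell_med == 3
    assert res.h == 6
    assert res.lam == pytest.approx(1 - 2 ** (-1 / 6))


def test_resource_stationary_variance_matches_unit_demand(rng):
    """White-noise unit-variance demand yields unit stationary variance."""
    K = 19998
    L = rng.normal(size=K)
    mode = np.asarray(["serial", "serial", "serial", "mixed", "mixed",
                       "mixed"] * (K // 6))
    res = resource_level(L, mode)
    assert np.var(res.raw[200:]) == pytest.approx(1.0, rel=0.08)


def test_resource_impulse_decays_geometrically():
    mode = np.asarray(["mixed"] * 50)
    L = np.zeros(50)
    L[0] = 1.0
    res = resource_level(L, mode)
    lam, alpha = res.lam, res.alpha
    expected = alpha * (1 - lam) ** np.arange(50)
    assert np.allclose(res.raw, expected, atol=1e-12)


# ---------------------------------------------------------------------------
# serial bottleneck


def test_bottleneck_no_serial_episodes_is_zero_and_flagged():
    res = serial_bottleneck(np.asarray(["mixed"] * 8), np.zeros(8))
    assert res.raw == 0.0 and res.no_serial_episodes


def test_bottleneck_hand_example_raw_two():
    """One length-4 episode with post-exit demand -0.5 gives 4 x 0.5 = 2."""
    mode = np.asarray(["serial"] * 4 + ["mixed"] * 4)
    L = np.zeros(8)
    L[4:7] = -0.5
    res = serial_bottleneck(mode, L, pe_delta=3)
    assert res.persistence == 4.0
    assert res.exit_cost == pytest.approx(0.5)
    assert res.raw == pytest.approx(2.0)


def test_bottleneck_excludes_episodes_without_post_exit_window():
    mode = np.asarray(["mixed"] * 3 + ["serial"] * 2)
    res = serial_bottleneck(mode, np.full(5, -1.0), pe_delta=3)
    assert res.n_episodes == 1 and res.n_exit_episodes == 0
    assert res.raw == 0.0 and res.no_exit_data
    # a valid and an invalid episode: exit averages over the valid one only
    mode = np.asarray(["serial"] * 2 + ["mixed"] * 4 + ["serial"] * 2)
    L = np.zeros(8)
    L[2:5] = -0.9
    res = serial_bottleneck(mode, L, pe_delta=3)
    assert res.n_episodes == 2 and res.n_exit_episodes == 1
    assert res.exit_cost == pytest.approx(0.9)
    assert res.raw == pytest.approx(2.0 * 0.9)


def test_bottleneck_rectifies_positive_post_exit_demand():
    mode = np.asarray(["serial"] * 2 + ["mixed"] * 5)
    L = np.full(7, 1.0)  # recovery, not cost
    res = serial_bottleneck(mode, L, pe_delta=3)
    assert res.exit_cost == 0.0 and res.raw == 0.0


# ---------------------------------------------------------------------------
# robust scaling


def test_robust_scale_examples():
    z = robust_scale(np.asarray([-1.0, 0.0, 1.0]))
    assert np.allclose(z, [-0.6745, 0.0, 0.6745], atol=1e-3)
    with pytest.warns(UserWarning, match="zero MAD"):
        z = robust_scale(np.full(5, 3.0))
    assert np.allclose(z, 0.0)
    out = tanh_squash(np.asarray([-50.0, 0.0, 50.0]))
    assert np.all(np.abs(out) <= 1.0)
    assert abs(tanh_squash(np.asarray([3.0]))[0]) < 1.0


def test_cohort_scaler_matches_robust_scale(rng):
    x = rng.normal(2.0, 3.0, size=500)
    scaler = CohortScaler.fit(x)
    assert np.allclose(scaler.transform(x), robust_scale(x), atol=1e-12)
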