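import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from pcsm import _hmm
from pcsm.fir import FirSeries
from pcsm.simulator import SimulationConfig, simulate_cohort
from pcsm.state_model import (align_to_template, fit_global, fit_subject,
                              infer_posteriors, sample_from_params, score,
                              select_model_order)

from conftest import make_params


def _series(X, seg):
    R = X.shape[0] // seg
    return FirSeries(values=X, trials=np.repeat(np.arange(R), seg),
                     delays=np.tile(np.arange(seg), R))


# ---------------------------------------------------------------------------
# emission density and inference oracles


def test_emission_density_matches_weighted_gaussian_oracle(rng):
    """Mixture emission log density equals a direct sum of full Gaussians."""
    params = make_params(C=3, M=2, N=3, seed=1)
    X = rng.normal(size=(20, 3))
    logB, _ = _hmm.state_loglik(X, params.weights, params.means, params.variances)
    for t in range(20):
        for c in range(3):
            direct = sum(
                params.weights[c, m] * multivariate_normal.pdf(
                    X[t], params.means[c, m], np.diag(params.variances[c, m]))
                for m in range(2))
            assert logB[t, c] == pytest.approx(np.log(direct), abs=1e-10)


def test_posterior_rows_sum_to_one(rng):
    params = make_params(C=3, M=2, N=4, seed=2)
    fir, _ = sample_from_params(params, n_trials=30, seg_len=5, rng=rng)
    for smoothing in ("filtered", "smoothed"):
        traj = infer_posteriors(params, fir, smoothing=smoothing)
        assert np.allclose(traj.pi.sum(axis=1), 1.0, atol=1e-8)
        assert traj.viterbi.min() >= 0 and traj.viterbi.max() < 3


def test_viterbi_beats_exhaustive_path_enumeration(rng):
    """The Viterbi joint log probability tops all 3^K enumerated paths."""
    params = make_params(C=3, M=2, N=2, seed=3, spread=1.0, var=0.5)
    for trial in range(3):
        X = rng.normal(size=(6, 2))
        fir = _series(X, 6)
        logB, _ = _hmm.state_loglik(X, params.weights, params.means,
                                    params.variances)
        path, logp = _hmm.viterbi(logB, np.log(params.startprob),
                                  np.log(params.transmat), 6)
        best = -np.inf
        best_path = None
        for cand in itertools.product(range(3), repeat=6):
            lp = np.log(params.startprob[cand[0]]) + logB[0, cand[0]]
            for t in range(1, 6):
                lp += np.log(params.transmat[cand[t - 1], cand[t]]) + logB[t, cand[t]]
            if lp > best:
                best, best_path = lp, cand
        assert logp[0] == pytest.approx(best, abs=1e-9)
        assert tuple(path) == best_path


def test_zero_probability_frames_stay_normalised():
    """Far-outlying observations renormalise instead of producing NaN."""
    params = make_params(C=3, M=2, N=3, seed=4, var=1e-4)
    X = np.full((5, 3), 1e4)
    traj = infer_posteriors(params, _series(X, 5))
    assert np.all(np.isfinite(traj.pi))
    assert np.allclose(traj.pi.sum(axis=1), 1.0, atol=1e-8)


# ---------------------------------------------------------------------------
# cross-checks against hmmlearn on identical parameters


def _to_hmmlearn(params):
    from hmmlearn.hmm import GMMHMM
    m = GMMHMM(n_components=params.C, n_mix=params.M, covariance_type="diag",
               init_params="", params="")
    m.startprob_ = params.startprob
    m.transmat_ = params.transmat
    m.weights_ = params.weights
    m.means_ = params.means
    m.covars_ = params.variances
    return m


def test_loglik_and_viterbi_agree_with_hmmlearn(rng):
    params = make_params(C=3, M=2, N=4, seed=5, spread=1.5, var=0.3)
    fir, _ = sample_from_params(params, n_trials=12, seg_len=5, rng=rng)
    ref = _to_hmmlearn(params)
    lengths = [5] * 12
    assert score(params, fir) == pytest.approx(ref.score(fir.values, lengths),
                                               abs=1e-8)
    ref_lp, ref_path = ref.decode(fir.values, lengths)
    traj = infer_posteriors(params, fir)
    assert np.array_equal(traj.viterbi, ref_path)
    smoothed = infer_posteriors(params, fir, smoothing="smoothed")
    assert np.allclose(smoothed.pi, ref.predict_proba(fir.values, lengths),
                       atol=1e-8)


# ---------------------------------------------------------------------------
# fitting


def test_em_loglik_is_monotone(rng):
    params = make_params(C=3, M=2, N=4, seed=6, spread=1.0, var=0.4)
    fir, _ = sample_from_params(params, n_trials=40, seg_len=5, rng=rng)
    res = _hmm.em(fir.values, 5, params.startprob, params.transmat,
                  params.weights, params.means, params.variances,
                  update="stmwc", max_iter=15, tol=0)
    hist = res["history"]
    assert np.all(np.diff(hist) >= -1e-6 * np.abs(hist[:-1]))


def test_subject_fit_freezes_variances_and_improves_loglik(small_cohort,
                                                           small_global_fit):
    _, _, _, firs = small_cohort
    gp = small_global_fit
    sp = fit_subject(firs[0], gp)
    assert sp.variances is gp.variances or np.array_equal(sp.variances,
                                                          gp.variances)
    assert score(sp, firs[0]) >= score(gp, firs[0]) - 1e-6


def test_subject_transitions_recover_global_at_low_noise(rng):
    """Data sampled from the global model refits to nearby transitions."""
    params = make_params(C=3, M=2, N=6, seed=7, spread=2.5, var=0.05)
    fir, _ = sample_from_params(params, n_trials=120, seg_len=5, rng=rng)
    sp = fit_subject(fir, params, max_iter=50)
    assert np.max(np.abs(sp.transmat - params.transmat)) < 0.1


def test_global_fit_recovers_generative_means(rng):
    """Parameter recovery: fitted state/mixture means near truth at low noise."""
    from pcsm.state_model import canonicalize
    truth = canonicalize(make_params(C=3, M=2, N=5, seed=8, spread=3.0, var=0.05))
    firs = [sample_from_params(truth, n_trials=80, seg_len=5,
                               rng=np.random.default_rng(100 + i))[0]
            for i in range(4)]
    fitted = fit_global(firs, C=3, M=2, n_init=3, max_iter=100, seed=9)
    aligned = align_to_template(fitted, truth).aligned
    err = np.abs(aligned.means - truth.means).mean()
    assert err < 0.05


# ---------------------------------------------------------------------------
# alignment


def test_alignment_is_identity_on_the_template(small_global_fit):
    res = align_to_template(small_global_fit, small_global_fit)
    assert np.array_equal(res.state_perm, np.arange(3))
    assert np.array_equal(res.aligned.means, small_global_fit.means)


@pytest.mark.parametrize("perm", list(itertools.permutations(range(3))))
def test_alignment_round_trip_recovers_state_permutation(small_global_fit, perm,
                                                         small_cohort):
    """Every state shuffle of the template aligns back and keeps likelihood."""
    _, _, _, firs = small_cohort
    template = small_global_fit
    shuffled = template.permute(np.asarray(perm))
    res = align_to_template(shuffled, template)
    assert np.allclose(res.aligned.means, template.means)
    assert np.allclose(res.aligned.transmat, template.transmat)
    ll_before = score(shuffled, firs[0])
    ll_after = score(res.aligned, firs[0])
    assert ll_after == pytest.approx(ll_before, abs=1e-8)


def test_alignment_permutes_all_blocks_consistently():
    params = make_params(C=3, M=2, N=4, seed=10)
    p = params.permute(np.asarray([2, 0, 1]))
    assert np.allclose(p.startprob, params.startprob[[2, 0, 1]])
    assert p.transmat[0, 1] == params.transmat[2, 0]
    assert np.allclose(p.means[0], params.means[2])
    rows = p.transmat.sum(axis=1)
    assert np.allclose(rows, 1.0)


def test_alignment_rejects_dimension_mismatch(small_global_fit):
    other = make_params(C=3, M=2, N=small_global_fit.N + 1, seed=11)
    with pytest.raises(ValueError):
        align_to_template(other, small_global_fit)


# ---------------------------------------------------------------------------
# model-order selection


def test_model_order_selection_recovers_three_states(rng):
    truth = make_params(C=3, M=1, N=5, seed=12, spread=2.5, var=0.1)
    firs = [sample_from_params(truth, n_trials=40, seg_len=5,
                               rng=np.random.default_rng(200 + i))[0]
            for i in range(6)]
    report = select_model_order(firs, C_range=range(2, 5), M_range=(1, 2),
                                k_folds=3, seed=13, n_init=1, max_iter=40)
    assert report["selected"][0] == 3


def test_model_order_selection_keeps_minimal_order_for_single_gaussian(rng):
    truth = make_params(C=1, M=1, N=4, seed=14, var=0.3)
    firs = [sample_from_params(truth, n_trials=40, seg_len=5,
                               rng=np.random.default_rng(300 + i))[0]
            for i in range(6)]
    report = select_model_order(firs, C_range=range(2, 4), M_range=(1,),
                                k_folds=3, seed=15, n_init=1, max_iter=30)
    assert report["selected"] == (2, 1)
    assert not report["state_steps"][0]["accepted"]
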