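"""Constrained Gaussian-mixture HMM over trial-segmented FIR amplitudes.

The model has C latent brain states (default 3) whose emission density is a
two-component diagonal-covariance Gaussian mixture per state — a
"responding" and a "non-responding" component per node pattern.  Three
adaptations tailor it to trial-aligned fMRI:

1. *Trial segmentation*: each trial's D delay bins form an independent
   sequence re-initialised from the start distribution, so transitions
   never bridge inter-trial gaps.
2. *Template alignment*: state labels are arbitrary under EM, so each
   subject's states are permuted to match a global template by a salience
   score combining mean BOLD intensity with the responding-mixture weight.
3. *Frozen covariances*: subject-level fits keep the mixture variances
   fixed at the global estimates for numerical stability; only start,
   transition, weight and mean parameters adapt per subject.

A separate full N x N spatial covariance (Ledoit-Wolf shrinkage) is
estimated from the concatenated data for Mahalanobis model-discrepancy
scoring downstream.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.covariance import LedoitWolf
from sklearn.model_selection import KFold

from . import _hmm
from .fir import FirSeries

__all__ = [
    "GmmHmmParams",
    "PosteriorTrajectory",
    "AlignmentResult",
    "fit_global",
    "fit_subject",
    "align_to_template",
    "infer_posteriors",
    "score",
    "select_model_order",
    "sample_from_params",
]

VAR_FLOOR = 1e-6


@dataclass
class GmmHmmParams:
    """Parameters of the C-state, M-mixture diagonal GMM-HMM.

    ``weights[c, m]`` is P(mixture m | state c); mixture index
    ``responding_mixture_index`` (canonically 1) denotes the responding
    component.  ``spatial_cov`` is the full node covariance used only for
    discrepancy scoring, not for emission likelihoods.
    """

    startprob: np.ndarray          # (C,)
    transmat: np.ndarray           # (C, C)
    weights: np.ndarray            # (C, M)
    means: np.ndarray              # (C, M, N)
    variances: np.ndarray          # (C, M, N)
    spatial_cov: np.ndarray | None = None
    responding_mixture_index: int = 1

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if self.responding_mixture_index >= self.means.shape[1]:
            self.responding_mixture_index = self.means.shape[1] - 1
        self.validate()

    def validate(self) -> None:
        C, M, N = self.means.shape
        if self.startprob.shape != (C,) or self.transmat.shape != (C, C):
            raise ValueError("startprob/transmat shape mismatch")
        if self.weights.shape != (C, M) or self.variances.shape != (C, M, N):
            raise ValueError("weights/variances shape mismatch")
        if not (np.isclose(self.startprob.sum(), 1.0)
                and np.allclose(self.transmat.sum(axis=1), 1.0)
                and np.allclose(self.weights.sum(axis=1), 1.0)):
            raise ValueError("probability vectors must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    @property
    def C(self) -> int:
        return self.means.shape[0]

    @property
    def M(self) -> int:
        return self.means.shape[1]

    @property
    def N(self) -> int:
        return self.means.shape[2]

    @property
    def responding_weights(self) -> np.ndarray:
        """a_c = P(responding mixture | state c), shape (C,)."""
        return self.weights[:, self.responding_mixture_index]

    def state_means(self) -> np.ndarray:
        """Mixture-weighted mean pattern per state, shape (C, N)."""
        return np.einsum("cm,cmn->cn", self.weights, self.means)

    def copy(self) -> "GmmHmmParams":
        return GmmHmmParams(
            startprob=self.startprob.copy(), transmat=self.transmat.copy(),
            weights=self.weights.copy(), means=self.means.copy(),
            variances=self.variances.copy(),
            spatial_cov=None if self.spatial_cov is None else self.spatial_cov.copy(),
            responding_mixture_index=self.responding_mixture_index)

    def permute(self, state_perm: np.ndarray,
                mixture_perms: np.ndarray | None = None) -> "GmmHmmParams":
        """Relabel states (and optionally, mixtures within each state).

        ``state_perm[i]`` is the old state placed at new position ``i``;
        ``mixture_perms[i]`` likewise permutes mixtures of new state ``i``.
        Relabeling leaves the likelihood of any data unchanged.
        """
        p = np.asarray(state_perm, dtype=int)
        if sorted(p.tolist()) != list(range(self.C)):
            raise ValueError("state_perm must be a permutation of the states")
        w = self.weights[p].copy()
        mu = self.means[p].copy()
        var = self.variances[p].copy()
        if mixture_perms is not None:
            mp = np.asarray(mixture_perms, dtype=int)
            for i in range(self.C):
                w[i] = w[i, mp[i]]
                mu[i] = mu[i, mp[i]]
                var[i] = var[i, mp[i]]
        return GmmHmmParams(
            startprob=self.startprob[p].copy(),
            transmat=self.transmat[np.ix_(p, p)].copy(),
            weights=w, means=mu, variances=var,
            spatial_cov=None if self.spatial_cov is None else self.spatial_cov.copy(),
            responding_mixture_index=self.responding_mixture_index)


@dataclass
class PosteriorTrajectory:
    """Decoded per-frame posteriors and the Viterbi path for one subject."""

    pi: np.ndarray                       # (K, C) state posteriors
    viterbi: np.ndarray                  # (K,) MAP state path (per trial segment)
    loglik: float
    seq_lengths: list[int]
    smoothing: str = "filtered"
    node_resp: np.ndarray | None = None  # (K, N) B_{t,n}, filled downstream

    @property
    def K(self) -> int:
        return self.pi.shape[0]

    @property
    def C(self) -> int:
        return self.pi.shape[1]


@dataclass
class AlignmentResult:
    state_perm: np.ndarray
    mixture_perms: np.ndarray
    salience_scores: np.ndarray          # subject salience, template state order
    aligned: GmmHmmParams


# ---------------------------------------------------------------------------
# helpers


def _stack(fir_stack: list[FirSeries]) -> tuple[np.ndarray, int]:
    if not fir_stack:
        raise ValueError("empty FIR stack")
    seg = fir_stack[0].seg_len
    N = fir_stack[0].n_nodes
    for f in fir_stack:
        if f.seg_len != seg or f.n_nodes != N:
            raise ValueError("all FIR series must share segment length and node count")
    return np.vstack([f.values for f in fir_stack]), seg


def _zscore_states(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _canonical_mixture_perms(params: GmmHmmParams) -> np.ndarray:
    """Order mixtures so the larger-|mean| (responding) component is index 1.

    Ties in mean |mu| are broken toward the larger mixture weight.
    """
    C, M = params.C, params.M
    perms = np.tile(np.arange(M), (C, 1))
    if M < 2:
        return perms
    mag = np.abs(params.means).mean(axis=2)  # (C, M)
    for c in range(C):
        order = np.lexsort((params.weights[c], mag[c]))  # ascending, weight tiebreak
        perms[c] = order
    return perms


def _salience(params: GmmHmmParams, effective_weights: np.ndarray | None = None) -> np.ndarray:
    """Salience score per state: mean BOLD intensity + responding weight.

    The two components are combined on their native scales (z-scored
    amplitude units and a probability).  Standardising each across the C
    states before summing is unstable: when a state's true emission is
    nearly unimodal its responding weight degenerates toward 0, and a
    z-score over only C values then amplifies that noise enough to scramble
    the ranking.
    """
    intensity = params.means.mean(axis=(1, 2))     # (C,)
    resp = (params.responding_weights if effective_weights is None
            else np.asarray(effective_weights, dtype=float))
    return intensity + resp


def canonicalize(params: GmmHmmParams) -> GmmHmmParams:
    """Deterministic internal ordering: responding mixture last, states by
    descending salience."""
    mix = _canonical_mixture_perms(params)
    p = params.permute(np.arange(params.C), mix)
    order = np.argsort(-_salience(p), kind="stable")
    return p.permute(order)


def _init_from_data(X: np.ndarray, C: int, M: int,
                    rng: np.random.Generator) -> GmmHmmParams:
    """K-means state centres with jittered mixture splits as an EM start."""
    n = X.shape[1]
    sub = X[rng.choice(X.shape[0], size=min(X.shape[0], 5000), replace=False)]
    km = KMeans(n_clusters=C, n_init=3, random_state=int(rng.integers(2 ** 31)))
    labels = km.fit_predict(sub)
    var = np.maximum(sub.var(axis=0), VAR_FLOOR)
    means = np.empty((C, M, n))
    variances = np.empty((C, M, n))
    for c in range(C):
        centre = km.cluster_centers_[c]
        cl_var = sub[labels == c].var(axis=0) if np.sum(labels == c) > 1 else var
        for m in range(M):
            means[c, m] = centre + rng.normal(0, 0.1, n) * np.sqrt(var)
            variances[c, m] = np.maximum(cl_var, VAR_FLOOR)
    startprob = np.full(C, 1.0 / C)
    transmat = np.full((C, C), 0.1 / max(C - 1, 1)) + np.eye(C) * (0.9 - 0.1 / max(C - 1, 1))
    transmat /= transmat.sum(axis=1, keepdims=True)
    weights = np.full((C, M), 1.0 / M)
    return GmmHmmParams(startprob=startprob, transmat=transmat, weights=weights,
                        means=means, variances=variances)


def _run_em(X: np.ndarray, seg: int, params: GmmHmmParams, update: str,
            max_iter: int, tol: float) -> tuple[GmmHmmParams, np.ndarray, bool]:
    res = _hmm.em(X, seg, params.startprob, params.transmat, params.weights,
                  params.means, params.variances, update=update,
                  max_iter=max_iter, tol=tol, var_floor=VAR_FLOOR)
    out = GmmHmmParams(
        startprob=res["startprob"], transmat=res["transmat"], weights=res["weights"],
        means=res["means"],
        variances=res["variances"] if "c" in update else params.variances,
        spatial_cov=params.spatial_cov,
        responding_mixture_index=params.responding_mixture_index)
    return out, res["history"], res["converged"]


# ---------------------------------------------------------------------------
# public operations


def fit_global(fir_stack: list[FirSeries], C: int = 3, M: int = 2,
               n_init: int = 5, max_iter: int = 100, tol: float = 1e-4,
               seed: int | None = None) -> GmmHmmParams:
    """Fit the global template model on the concatenated cohort.

    Baum-Welch over all subjects' trial segments, best of ``n_init`` random
    initialisations by final log likelihood.  The result is canonically
    ordered (states by descending salience, responding mixture at index 1)
    and carries the Ledoit-Wolf spatial covariance of the concatenated data.
    """
    if len(fir_stack) < 2:
        raise ValueError("global fit requires at least 2 subjects")
    X, seg = _stack(fir_stack)
    rng = np.random.default_rng(seed)
    best: tuple[float, GmmHmmParams] | None = None
    any_converged = False
    for _ in range(n_init):
        init = _init_from_data(X, C, M, rng)
        fitted, history, converged = _run_em(X, seg, init, "stmwc", max_iter, tol)
        any_converged = any_converged or converged
        ll = float(history[-1])
        if best is None or ll > best[0]:
            best = (ll, fitted)
    assert best is not None
    if not any_converged:
        warnings.warn("EM did not converge within max_iter for any initialisation; "
                      "returning the best iterate", stacklevel=2)
    params = best[1]
    params.spatial_cov = LedoitWolf().fit(X).covariance_
    return canonicalize(params)


def fit_subject(fir: FirSeries, global_params: GmmHmmParams,
                max_iter: int = 50, tol: float = 1e-4) -> GmmHmmParams:
    """Subject-level fit with covariances frozen at the global estimates.

    EM updates start, transition, mixture-weight and mean parameters,
    initialised at the global template; the returned ``variances`` array is
    bit-identical to the global one.
    """
    if fir.n_nodes != global_params.N:
        raise ValueError("node count mismatch with global parameters")
    fitted, _, converged = _run_em(fir.values, fir.seg_len, global_params,
                                   "stmw", max_iter, tol)
    if not converged:
        warnings.warn("subject EM did not converge within max_iter", stacklevel=2)
    fitted.variances = global_params.variances  # exact, shared
    return fitted


def _effective_responding_weights(params: GmmHmmParams, fir: FirSeries,
                                  chunk: int = 512) -> np.ndarray:
    """Empirical responding-responsibility mass per state.

    Posterior-weighted mean (over frames and nodes) of the node-wise
    responding-mixture responsibility, used as the subject-adjusted
    replacement for a_{c,1} in the salience score.
    """
    traj = infer_posteriors(params, fir)
    C, M = params.C, params.M
    ridx = params.responding_mixture_index
    num = np.zeros(C)
    den = np.zeros(C)
    X = fir.values
    for lo in range(0, X.shape[0], chunk):
        x = X[lo:lo + chunk]
        pi = traj.pi[lo:lo + chunk]
        for c in range(C):
            lp = (-0.5 * ((x[:, None, :] - params.means[c][None]) ** 2
                          / params.variances[c][None]
                          + np.log(2 * np.pi * params.variances[c][None]))
                  + np.log(np.maximum(params.weights[c], 1e-300))[None, :, None])
            g = np.exp(lp - logsumexp(lp, axis=1, keepdims=True))  # (chunk, M, N)
            num[c] += float(np.sum(pi[:, c, None] * g[:, ridx, :]))
            den[c] += float(np.sum(pi[:, c]) * x.shape[1])
    return num / np.maximum(den, 1e-300)


def align_to_template(subject: GmmHmmParams, template: GmmHmmParams,
                      use_effective_weights: bool = False,
                      fir: FirSeries | None = None) -> AlignmentResult:
    """Permute a subject's states (and mixtures) to match the template.

    Within each state the larger-|mean| mixture is labelled responding;
    states are then matched to template states by salience rank, with ties
    broken by the correlation between state-mean patterns.  Relabeling is
    likelihood-preserving by construction.
    """
    if subject.C != template.C or subject.M != template.M or subject.N != template.N:
        raise ValueError("subject/template dimensions do not match")
    mix_perms = _canonical_mixture_perms(subject)
    canon = subject.permute(np.arange(subject.C), mix_perms)
    if use_effective_weights:
        if fir is None:
            raise ValueError("effective weights require the subject's FIR data")
        eff = _effective_responding_weights(canon, fir)
        sal_subj = _salience(canon, eff)
    else:
        sal_subj = _salience(canon)
    sal_temp = _salience(template)
    subj_order = np.argsort(-sal_subj, kind="stable")
    temp_order = np.argsort(-sal_temp, kind="stable")
    perm = np.empty(subject.C, dtype=int)
    perm[temp_order] = subj_order
    # Ambiguous salience margins (e.g. near-degenerate responding weights)
    # can swap close states; the distance between full state signatures
    # (state means plus sd profiles, which subject fits inherit frozen
    # from the template) is decisive there, so prefer whichever candidate
    # pairing sits closer to the template.
    dist = _signature_distance(canon, template)
    rows, cols = linear_sum_assignment(dist)
    sig_perm = np.empty(subject.C, dtype=int)
    sig_perm[rows] = cols
    if not np.array_equal(sig_perm, perm):
        if dist[np.arange(subject.C), sig_perm].sum() < \
                dist[np.arange(subject.C), perm].sum() - 1e-12:
            perm = sig_perm
    aligned = canon.permute(perm)
    return AlignmentResult(state_perm=perm, mixture_perms=mix_perms[perm],
                           salience_scores=sal_subj[perm], aligned=aligned)


def _signature_distance(subject: GmmHmmParams, template: GmmHmmParams) -> np.ndarray:
    """dist[i, j]: Euclidean distance between template state i's and subject
    state j's parameter signature.

    The signature stacks the mixture-weighted state mean with the
    mixture-averaged sd profile, so it is invariant to the mixture
    ordering within a state (whose components can be near-degenerate) and
    keeps the level information a Pearson correlation would centre away.
    """
    ts = np.concatenate([template.state_means(),
                         np.sqrt(template.variances.mean(axis=1))], axis=1)
    ss = np.concatenate([subject.state_means(),
                         np.sqrt(subject.variances.mean(axis=1))], axis=1)
    diff = ts[:, None, :] - ss[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


def infer_posteriors(params: GmmHmmParams, fir: FirSeries,
                     smoothing: str = "filtered") -> PosteriorTrajectory:
    """Decode state posteriors and the per-trial Viterbi path.

    ``filtered`` (default) returns P(C_t = c | y_{0:t}) from the forward
    pass; ``smoothed`` conditions on the whole segment.  All recursions run
    in log space, so zero-probability frames renormalise rather than NaN.
    """
    if fir.n_nodes != params.N:
        raise ValueError("node count mismatch")
    seg = fir.seg_len
    logB, _ = _hmm.state_loglik(fir.values, params.weights, params.means,
                                params.variances)
    log_start = _hmm._safe_log(params.startprob)
    log_trans = _hmm._safe_log(params.transmat)
    if smoothing == "filtered":
        log_alpha, ll_seg = _hmm.forward(logB, log_start, log_trans, seg)
        pi = _hmm.filtered_posteriors(log_alpha)
        ll = float(ll_seg.sum())
    elif smoothing == "smoothed":
        pi, _, ll, _, _ = _hmm.forward_backward(logB, log_start, log_trans, seg)
    else:
        raise ValueError("smoothing must be 'filtered' or 'smoothed'")
    path, _ = _hmm.viterbi(logB, log_start, log_trans, seg)
    R = fir.K // seg
    return PosteriorTrajectory(pi=pi, viterbi=path, loglik=ll,
                               seq_lengths=[seg] * R, smoothing=smoothing)


def score(params: GmmHmmParams, fir: FirSeries) -> float:
    """Total log likelihood of a subject's data under the parameters."""
    logB, _ = _hmm.state_loglik(fir.values, params.weights, params.means,
                                params.variances)
    _, ll_seg = _hmm.forward(logB, _hmm._safe_log(params.startprob),
                             _hmm._safe_log(params.transmat), fir.seg_len)
    return float(ll_seg.sum())


def sample_from_params(params: GmmHmmParams, n_trials: int, seg_len: int,
                       rng: np.random.Generator) -> tuple[FirSeries, np.ndarray]:
    """Sample trial-segmented observations from the generative GMM-HMM.

    Test/recovery utility; returns the (unscored) FIR series and the true
    state sequence.
    """
    C, M, N = params.C, params.M, params.N
    K = n_trials * seg_len
    states = np.empty(K, dtype=np.intp)
    X = np.empty((K, N))
    for r in range(n_trials):
        s = rng.choice(C, p=params.startprob)
        for d in range(seg_len):
            if d > 0:
                s = rng.choice(C, p=params.transmat[s])
            m = rng.choice(M, p=params.weights[s])
            t = r * seg_len + d
            states[t] = s
            X[t] = rng.normal(params.means[s, m], np.sqrt(params.variances[s, m]))
    fir = FirSeries(values=X, trials=np.repeat(np.arange(n_trials), seg_len),
                    delays=np.tile(np.arange(seg_len), n_trials))
    return fir, states


# ---------------------------------------------------------------------------
# model-order selection


def select_model_order(fir_stack: list[FirSeries],
                       C_range=range(2, 6), M_range=range(1, 4),
                       k_folds: int = 5, seed: int | None = None,
                       n_init: int = 2, max_iter: int = 50,
                       tol: float = 1e-4) -> dict:
    """Subject-level cross-validated selection of (C, M).

    For every candidate order, k-fold CV over subjects yields the held-out
    log likelihood per observation.  States are accepted in ascending order
    while the information gain exceeds 2 per observation and 2 fold
    standard errors, the higher order wins at least 70% of folds, and (from
    the second step on) the gain is at least 10% of the previous gain.
    Mixtures are then accepted at the chosen C while the gain is at least
    max(5, 2 SE) per observation and wins at least 70% of folds.
    """
    C_range = list(C_range)
    M_range = list(M_range)
    if len(fir_stack) < k_folds:
        raise ValueError("need at least as many subjects as folds")
    rng = np.random.default_rng(seed)
    kf = KFold(n_splits=k_folds, shuffle=True,
               random_state=int(rng.integers(2 ** 31)))
    n_obs = {i: f.K for i, f in enumerate(fir_stack)}
    ll = {}  # (C, M) -> (k_folds,) held-out LL per observation
    for C in C_range:
        for M in M_range:
            fold_ll = []
            for train, test in kf.split(fir_stack):
                gp = fit_global([fir_stack[i] for i in train], C=C, M=M,
                                n_init=n_init, max_iter=max_iter, tol=tol,
                                seed=int(rng.integers(2 ** 31)))
                tot = sum(score(gp, fir_stack[i]) for i in test)
                fold_ll.append(tot / sum(n_obs[i] for i in test))
            ll[(C, M)] = np.asarray(fold_ll)

    def _gain(hi: np.ndarray, lo: np.ndarray) -> tuple[float, float, float]:
        d = hi - lo
        se = d.std(ddof=1) / np.sqrt(len(d)) if len(d) > 1 else 0.0
        return float(d.mean()), float(se), float(np.mean(d > 0))

    M0 = M_range[0]
    chosen_C = C_range[0]
    prev_gain = None
    state_steps = []
    for C_next in C_range[1:]:
        g, se, frac = _gain(ll[(C_next, M0)], ll[(chosen_C, M0)])
        ok = g > 2.0 and g > 2.0 * se and frac >= 0.70
        if ok and prev_gain is not None:
            ok = g > 0.10 * prev_gain
        state_steps.append({"from": chosen_C, "to": C_next, "gain": g, "se": se,
                            "fold_win_fraction": frac, "accepted": bool(ok)})
        if not ok:
            break
        prev_gain = g
        chosen_C = C_next

    chosen_M = M_range[0]
    mixture_steps = []
    for M_next in M_range[1:]:
        g, se, frac = _gain(ll[(chosen_C, M_next)], ll[(chosen_C, chosen_M)])
        ok = g >= max(5.0, 2.0 * se) and frac >= 0.70
        mixture_steps.append({"from": chosen_M, "to": M_next, "gain": g, "se": se,
                              "fold_win_fraction": frac, "accepted": bool(ok)})
        if not ok:
            break
        chosen_M = M_next

    return {
        "selected": (chosen_C, chosen_M),
        "loglik_per_obs": {f"C{C}_M{M}": v.tolist() for (C, M), v in ll.items()},
        "state_steps": state_steps,
        "mixture_steps": mixture_steps,
    }
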