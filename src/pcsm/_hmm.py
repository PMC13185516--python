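"""Core numerics for the trial-segmented Gaussian-mixture HMM.

Everything here operates on a stack of equal-length observation segments
(one segment per task trial, ``D`` FIR delay bins each).  Because every
segment has the same length, the forward, backward and Viterbi recursions
are vectorised across segments instead of looping over them, which is what
makes whole-cohort fits tractable: a cohort-level fit touches tens of
thousands of 5-frame sequences per EM iteration.

All recursions run in log space.  Shapes use the conventions:

``F``  total frames (= S * D), ``S`` segments, ``D`` frames per segment,
``C`` latent states, ``M`` mixture components per state, ``N`` nodes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

LOG_EPS = -1e30  # stand-in for log(0) that stays finite in arithmetic

__all__ = [
    "component_logpdf",
    "state_loglik",
    "forward",
    "forward_backward",
    "viterbi",
    "em",
]


def _safe_log(x: np.ndarray) -> np.ndarray:
    out = np.full(np.shape(x), LOG_EPS, dtype=float)
    pos = np.asarray(x) > 0
    out[pos] = np.log(np.asarray(x)[pos])
    return out


def component_logpdf(X: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Log density of each frame under each (state, mixture) diagonal Gaussian.

    Parameters
    ----------
    X : (F, N) observations
    means, variances : (C, M, N)

    Returns
    -------
    (F, C, M) array of log densities.
    """
    F = X.shape[0]
    C, M, N = means.shape
    out = np.empty((F, C, M))
    # constant term per component
    const = -0.5 * (N * np.log(2.0 * np.pi) + np.log(variances).sum(axis=-1))  # (C, M)
    for c in range(C):
        for m in range(M):
            diff = X - means[c, m]
            out[:, c, m] = const[c, m] - 0.5 * np.sum(diff * diff / variances[c, m], axis=1)
    return out


def state_loglik(X: np.ndarray, weights: np.ndarray, means: np.ndarray,
                 variances: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame per-state mixture log likelihood and component log densities.

    Returns ``(logB, comp)`` with shapes ``(F, C)`` and ``(F, C, M)``; ``comp``
    already includes the mixture-weight term.
    """
    comp = component_logpdf(X, means, variances) + _safe_log(weights)[None, :, :]
    logB = logsumexp(comp, axis=2)
    return logB, comp


def _segment(logB: np.ndarray, seg_len: int) -> np.ndarray:
    F, C = logB.shape
    if F % seg_len:
        raise ValueError(f"frame count {F} not divisible by segment length {seg_len}")
    return logB.reshape(F // seg_len, seg_len, C)


def forward(logB: np.ndarray, log_start: np.ndarray, log_trans: np.ndarray,
            seg_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised forward pass.

    Returns ``(log_alpha, ll_seg)``: ``log_alpha`` with shape (S, D, C) and the
    per-segment log likelihoods (S,).
    """
    B = _segment(logB, seg_len)
    S, D, C = B.shape
    log_alpha = np.empty((S, D, C))
    log_alpha[:, 0] = log_start[None, :] + B[:, 0]
    for d in range(1, D):
        # (S, C_prev, 1) + (C_prev, C_next) -> logsumexp over C_prev
        log_alpha[:, d] = logsumexp(log_alpha[:, d - 1, :, None] + log_trans[None, :, :],
                                    axis=1) + B[:, d]
    ll_seg = logsumexp(log_alpha[:, -1], axis=1)
    return log_alpha, ll_seg


def forward_backward(logB: np.ndarray, log_start: np.ndarray, log_trans: np.ndarray,
                     seg_len: int):
    """Full forward-backward pass.

    Returns
    -------
    gamma : (F, C) smoothed state posteriors
    xi_sum : (C, C) expected transition counts summed over all segment steps
    ll : float, total log likelihood
    log_alpha : (S, D, C)
    start_post : (S, C) posterior over the initial state of each segment
    """
    B = _segment(logB, seg_len)
    S, D, C = B.shape
    log_alpha, ll_seg = forward(logB, log_start, log_trans, seg_len)
    log_beta = np.zeros((S, D, C))
    for d in range(D - 2, -1, -1):
        log_beta[:, d] = logsumexp(log_trans[None, :, :] + (B[:, d + 1] + log_beta[:, d + 1])[:, None, :],
                                   axis=2)
    log_gamma = log_alpha + log_beta - ll_seg[:, None, None]
    gamma = np.exp(log_gamma)
    # transition counts
    xi_sum = np.zeros((C, C))
    for d in range(1, D):
        log_xi = (log_alpha[:, d - 1, :, None] + log_trans[None, :, :]
                  + (B[:, d] + log_beta[:, d])[:, None, :] - ll_seg[:, None, None])
        xi_sum += np.exp(logsumexp(log_xi, axis=0))
    return gamma.reshape(S * D, C), xi_sum, float(ll_seg.sum()), log_alpha, gamma[:, 0, :].reshape(S, C)


def filtered_posteriors(log_alpha: np.ndarray) -> np.ndarray:
    """Normalise forward messages into filtered posteriors P(C_t | y_{0:t})."""
    S, D, C = log_alpha.shape
    norm = log_alpha - logsumexp(log_alpha, axis=2, keepdims=True)
    return np.exp(norm).reshape(S * D, C)


def viterbi(logB: np.ndarray, log_start: np.ndarray, log_trans: np.ndarray,
            seg_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-segment Viterbi decoding.

    Returns ``(paths, logp)``: the MAP state paths flattened to (F,) and the
    per-segment joint log probability (S,).
    """
    B = _segment(logB, seg_len)
    S, D, C = B.shape
    delta = log_start[None, :] + B[:, 0]
    psi = np.zeros((S, D, C), dtype=np.intp)
    for d in range(1, D):
        cand = delta[:, :, None] + log_trans[None, :, :]  # (S, prev, next)
        psi[:, d] = np.argmax(cand, axis=1)
        delta = np.take_along_axis(cand, psi[:, d][:, None, :], axis=1)[:, 0, :] + B[:, d]
    paths = np.empty((S, D), dtype=np.intp)
    paths[:, -1] = np.argmax(delta, axis=1)
    logp = np.max(delta, axis=1)
    for d in range(D - 1, 0, -1):
        paths[:, d - 1] = np.take_along_axis(psi[:, d], paths[:, d][:, None], axis=1)[:, 0]
    return paths.reshape(S * D), logp


def em(X: np.ndarray, seg_len: int, startprob: np.ndarray, transmat: np.ndarray,
       weights: np.ndarray, means: np.ndarray, variances: np.ndarray,
       update: str = "stmwc", max_iter: int = 100, tol: float = 1e-4,
       var_floor: float = 1e-6):
    """Baum-Welch EM for the segmented GMM-HMM.

    ``update`` selects which parameter blocks the M-step touches
    (s=startprob, t=transmat, m=means, w=weights, c=variances); anything
    excluded is returned bit-identical to its input.  Convergence is judged
    on the change in per-frame log likelihood.

    Returns a dict with the final parameter arrays, the log-likelihood
    history (one entry per iteration, computed at the *current* parameters
    before the update), and a convergence flag.
    """
    X = np.ascontiguousarray(X, dtype=float)
    F = X.shape[0]
    startprob = startprob.copy()
    transmat = transmat.copy()
    weights = weights.copy()
    means = means.copy()
    variances = variances.copy()
    history: list[float] = []
    converged = False
    for _ in range(max_iter):
        logB, comp = state_loglik(X, weights, means, variances)
        gamma, xi_sum, ll, _, start_post = forward_backward(
            logB, _safe_log(startprob), _safe_log(transmat), seg_len)
        history.append(ll)
        if len(history) > 1 and abs(history[-1] - history[-2]) / F < tol:
            converged = True
            break
        # mixture responsibilities r[f, c, m] = gamma[f, c] * p(m | y_f, c)
        post_m = np.exp(comp - logsumexp(comp, axis=2, keepdims=True))
        r = gamma[:, :, None] * post_m
        occ = r.sum(axis=0)  # (C, M)
        occ_safe = np.maximum(occ, 1e-300)
        if "s" in update:
            startprob = start_post.sum(axis=0)
            startprob /= startprob.sum()
        if "t" in update:
            rows = xi_sum.sum(axis=1, keepdims=True)
            transmat = np.where(rows > 0, xi_sum / np.maximum(rows, 1e-300),
                                1.0 / transmat.shape[0])
        if "w" in update:
            weights = occ / np.maximum(occ.sum(axis=1, keepdims=True), 1e-300)
        if "m" in update:
            means = np.einsum("fcm,fn->cmn", r, X) / occ_safe[:, :, None]
        if "c" in update:
            ex2 = np.einsum("fcm,fn->cmn", r, X * X) / occ_safe[:, :, None]
            variances = np.maximum(ex2 - means ** 2, var_floor)
    return {
        "startprob": startprob,
        "transmat": transmat,
        "weights": weights,
        "means": means,
        "variances": variances,
        "history": np.asarray(history),
        "converged": converged,
    }
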