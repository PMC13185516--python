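"""Emergent cognitive-processing metrics derived from posterior structure.

From the decoded state posteriors and the per-node responding-mixture
responsibilities, this module derives:

* ``B_{t,n}`` — state-marginalised posterior that node n is responding at
  time t (Bayes rule over the two mixture components, weighted by the
  state posterior).
* ``D_t^SP`` — serial-parallel deviation: the normalised expected absolute
  deviation of the responding-node count (a Poisson-binomial variable with
  success probabilities B_{t,:}) from half the nodes.  High values mean
  polarised/serial processing, low values distributed/parallel processing.
* ``L_t^demand`` — signed instantaneous cognitive demand combining changes
  in processing-mode potential, posterior entropy and Jensen-Shannon
  divergence, with a synergy penalty; negative values mean rising demand.
* ``R_t^level`` — resource level: a discrete-time leaky integrator of
  demand whose forgetting half-life adapts to the median dwell time in
  processing modes and whose gain matches the integrator's stationary
  variance to the demand variance.
* ``S^bottleneck`` — a per-subject scalar multiplying mean serial-episode
  persistence by the mean post-exit recovery cost.

Unbounded series are robust-standardised (median / 1.4826*MAD) and squashed
through tanh into [-1, 1] for cross-subject comparability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.special import logsumexp, rel_entr

from .fir import FirSeries
from .state_model import GmmHmmParams, PosteriorTrajectory

__all__ = [
    "GCC",
    "node_response_posterior",
    "poisson_binomial_pmf",
    "serial_parallel_deviation",
    "classify_mode",
    "cognitive_demand",
    "resource_level",
    "serial_bottleneck",
    "robust_scale",
    "tanh_squash",
    "CohortScaler",
    "DemandResult",
    "ResourceResult",
    "BottleneckResult",
]

GCC = 1.4826  # Gaussian consistency constant for the MAD


# ---------------------------------------------------------------------------
# node response posterior


def node_response_posterior(fir: FirSeries, params: GmmHmmParams,
                            traj: PosteriorTrajectory,
                            chunk: int = 256) -> np.ndarray:
    """B_{t,n}: posterior probability that node n is responding at frame t.

    Per node, the responsibility of the responding mixture within each
    state follows from univariate Gaussian densities and the mixture
    weights; marginalising over states with the posterior pi gives B.
    Nodes where every component density underflows fall back to the
    mixture weights.
    """
    K, N = fir.values.shape
    C, M = params.C, params.M
    ridx = params.responding_mixture_index
    logw = np.log(np.maximum(params.weights, 1e-300))  # (C, M)
    B = np.zeros((K, N))
    for lo in range(0, K, chunk):
        x = fir.values[lo:lo + chunk]                   # (k, N)
        pi = traj.pi[lo:lo + chunk]                     # (k, C)
        for c in range(C):
            # (k, M, N) log component densities, weight term included
            lp = (-0.5 * ((x[:, None, :] - params.means[c][None]) ** 2
                          / params.variances[c][None]
                          + np.log(2 * np.pi * params.variances[c][None]))
                  + logw[c][None, :, None])
            tot = logsumexp(lp, axis=1)                 # (k, N)
            with np.errstate(invalid="ignore"):
                g = np.exp(lp[:, ridx, :] - tot)
            dead = ~np.isfinite(g)
            if np.any(dead):
                g = np.where(dead, params.weights[c, ridx], g)
            B[lo:lo + chunk] += pi[:, c, None] * g
    return np.clip(B, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Poisson-binomial serial-parallel index


def poisson_binomial_pmf(q: np.ndarray) -> np.ndarray:
    """Exact PMF of a sum of independent Bernoulli(q_i) variables.

    Dynamic-programming convolution, O(N^2); the result sums to 1 within
    1e-10.  Entries of ``q`` must lie in [0, 1].
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 1:
        raise ValueError("q must be a vector")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("success probabilities must lie in [0, 1]")
    return _pmf_batch(q[None, :])[0]


def _pmf_batch(Q: np.ndarray) -> np.ndarray:
    """Poisson-binomial PMFs for a batch of probability rows, (K, N) -> (K, N+1)."""
    K, N = Q.shape
    pmf = np.zeros((K, N + 1))
    pmf[:, 0] = 1.0
    for n in range(N):
        qn = Q[:, n][:, None]
        pmf[:, 1:n + 2] = pmf[:, 1:n + 2] * (1.0 - qn) + pmf[:, 0:n + 1] * qn
        pmf[:, 0] *= (1.0 - Q[:, n])
    return pmf


def serial_parallel_deviation(B: np.ndarray) -> np.ndarray:
    """D_t^SP = (2/N) E|K_t - N/2| under the Poisson-binomial count model."""
    B = np.atleast_2d(np.asarray(B, dtype=float))
    K, N = B.shape
    if N == 0:
        raise ValueError("need at least one node")
    pmf = _pmf_batch(B)
    dev = np.abs(np.arange(N + 1) - N / 2.0)
    return np.clip((2.0 / N) * (pmf @ dev), 0.0, 1.0)


def classify_mode(d_sp: np.ndarray, tau_low: float, tau_high: float) -> np.ndarray:
    """Label frames parallel (<= tau_low), serial (>= tau_high) or mixed."""
    if not tau_low < tau_high:
        raise ValueError("tau_low must be below tau_high")
    d = np.asarray(d_sp, dtype=float)
    out = np.full(d.shape, "mixed", dtype="<U8")
    out[d <= tau_low] = "parallel"
    out[d >= tau_high] = "serial"
    return out


# ---------------------------------------------------------------------------
# robust scaling


def robust_scale(x: np.ndarray) -> np.ndarray:
    """(x - median) / (1.4826 * MAD); a zero-MAD series maps to all zeros."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn("zero MAD; robust scale degenerate, returning zeros",
                      stacklevel=2)
        return np.zeros_like(x)
    return (x - med) / (GCC * mad)


def tanh_squash(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


@dataclass
class CohortScaler:
    """Median/MAD scaling factors shared across a cohort for comparability."""

    median: float
    mad: float

    @classmethod
    def fit(cls, values: np.ndarray) -> "CohortScaler":
        v = np.asarray(values, dtype=float)
        med = float(np.median(v))
        return cls(median=med, mad=float(np.median(np.abs(v - med))))

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.mad == 0:
            return np.zeros_like(np.asarray(x, dtype=float))
        return (np.asarray(x, dtype=float) - self.median) / (GCC * self.mad)


# ---------------------------------------------------------------------------
# demand, resource, bottleneck


@dataclass
class DemandResult:
    raw: np.ndarray          # demand series on its native scale, unstandardised
    standardized: np.ndarray
    squashed: np.ndarray     # tanh of the robust-standardised series
    components: dict = field(default_factory=dict)


def _entropy_norm(pi: np.ndarray) -> np.ndarray:
    C = pi.shape[1]
    h = -np.sum(rel_entr(pi, np.ones_like(pi)), axis=1)  # = -sum pi log pi
    return h / np.log(C)


def _js_divergence(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Jensen-Shannon divergence rows-wise, natural log, normalised by ln 2.

    Probabilities below 1e-300 are flushed to zero first: halving a
    subnormal entry underflows the mixture to 0 and would turn a
    vanishing contribution into rel_entr(p, 0) = inf.
    """
    p = np.where(p < 1e-300, 0.0, p)
    q = np.where(q < 1e-300, 0.0, q)
    m = 0.5 * (p + q)
    js = 0.5 * rel_entr(p, m).sum(axis=1) + 0.5 * rel_entr(q, m).sum(axis=1)
    return js / np.log(2.0)


def cognitive_demand(d_sp: np.ndarray, traj: PosteriorTrajectory) -> DemandResult:
    """Instantaneous cognitive demand from mode, entropy and transition flux.

    Components: U = per-subject min-max normalisation of D^SP; H = posterior
    entropy normalised by ln C; J = JS divergence between successive
    posteriors (normalised by ln 2) centred at its median; the synergy term
    S upweights frames with concurrent mode and state changes.  All
    first-difference terms are 0 at t = 0.  The demand series is
    L_t = -(dU + dH + dJ)/3 - omega * S_t with omega the mean absolute
    unweighted demand; it is returned raw, robust-standardised, and
    tanh-squashed.
    """
    d_sp = np.asarray(d_sp, dtype=float)
    K = len(d_sp)
    if K < 2:
        raise ValueError("need at least two frames")
    pi = traj.pi
    rng_ = d_sp.max() - d_sp.min()
    U = (d_sp - d_sp.min()) / rng_ if rng_ > 0 else np.zeros(K)
    dU = np.concatenate([[0.0], np.diff(U)])
    H = _entropy_norm(pi)
    dH = np.concatenate([[0.0], np.diff(H)])
    J = np.zeros(K)
    J[1:] = _js_divergence(pi[1:], pi[:-1])
    dJ = J - np.median(J)
    dJ[0] = 0.0
    prod = np.abs(dU) * np.abs(dJ)
    S = prod - np.median(prod)
    base = -(dU + dH + dJ) / 3.0
    omega = float(np.mean(np.abs(base)))
    raw = base - omega * S
    standardized = robust_scale(raw)
    return DemandResult(
        raw=raw, standardized=standardized, squashed=np.tanh(standardized),
        components={"U": U, "dU": dU, "H": H, "dH": dH, "J": J, "dJ": dJ,
                    "S": S, "omega_syn": omega})


@dataclass
class ResourceResult:
    raw: np.ndarray
    squashed: np.ndarray
    lam: float
    h: float
    dwell_med: float
    alpha: float


def _run_lengths(labels: np.ndarray) -> np.ndarray:
    if len(labels) == 0:
        return np.asarray([])
    change = np.nonzero(labels[1:] != labels[:-1])[0] + 1
    bounds = np.concatenate([[0], change, [len(labels)]])
    return np.diff(bounds)


def resource_level(l_demand: np.ndarray, mode: np.ndarray) -> ResourceResult:
    """Leaky integration of demand into a resource-availability series.

    The forgetting half-life is h = max(3, 2 * median mode dwell); the gain
    alpha = sqrt((1 - (1-lambda)^2) / Var(L)) makes the integrator's
    stationary variance match unit-scaled demand.  R_0 starts at 0.
    """
    L = np.asarray(l_demand, dtype=float)
    if len(L) != len(mode):
        raise ValueError("demand series and mode labels must align")
    dwell_med = float(np.median(_run_lengths(np.asarray(mode))))
    h = max(3.0, 2.0 * dwell_med)
    lam = 1.0 - 2.0 ** (-1.0 / h)
    var = float(np.var(L))
    if var == 0:
        warnings.warn("zero-variance demand; resource gain set to 0", stacklevel=2)
        alpha = 0.0
    else:
        alpha = float(np.sqrt((1.0 - (1.0 - lam) ** 2) / var))
    R = lfilter([alpha], [1.0, -(1.0 - lam)], L)
    return ResourceResult(raw=R, squashed=np.tanh(robust_scale(R)) if np.any(R != R[0])
                          else np.zeros_like(R),
                          lam=lam, h=h, dwell_med=dwell_med, alpha=alpha)


@dataclass
class BottleneckResult:
    raw: float
    squashed: float
    persistence: float
    exit_cost: float
    n_episodes: int
    n_exit_episodes: int
    no_serial_episodes: bool
    no_exit_data: bool


def serial_bottleneck(mode: np.ndarray, l_demand: np.ndarray, pe_delta: int = 3,
                      cohort_scaler: CohortScaler | None = None) -> BottleneckResult:
    """Serial-bottleneck scalar: episode persistence times post-exit cost.

    Serial episodes are maximal runs labelled ``serial``.  The persistence
    factor is the mean episode length; the exit factor averages, over
    episodes with at least ``pe_delta`` subsequent frames, the rectified
    post-exit demand cost max(0, -mean of the next ``pe_delta`` demand
    values).  With a cohort scaler the product is robust-standardised
    against the cohort before tanh; otherwise tanh is applied to the raw
    value.
    """
    mode = np.asarray(mode)
    L = np.asarray(l_demand, dtype=float)
    K = len(mode)
    if K != len(L):
        raise ValueError("mode labels and demand series must align")
    serial = mode == "serial"
    # episode boundaries
    starts = np.nonzero(serial & ~np.concatenate([[False], serial[:-1]]))[0]
    ends = np.nonzero(serial & ~np.concatenate([serial[1:], [False]]))[0]
    n_ep = len(starts)
    if n_ep == 0:
        return BottleneckResult(raw=0.0, squashed=_squash_bneck(0.0, cohort_scaler),
                                persistence=0.0, exit_cost=0.0, n_episodes=0,
                                n_exit_episodes=0, no_serial_episodes=True,
                                no_exit_data=True)
    persistence = float(np.mean(ends - starts + 1))
    exit_costs = []
    for te in ends:
        if te + pe_delta <= K - 1:
            window = L[te + 1: te + 1 + pe_delta]
            exit_costs.append(max(0.0, -float(np.mean(window))))
    n_exit = len(exit_costs)
    exit_cost = float(np.mean(exit_costs)) if n_exit else 0.0
    raw = persistence * exit_cost
    return BottleneckResult(raw=raw, squashed=_squash_bneck(raw, cohort_scaler),
                            persistence=persistence, exit_cost=exit_cost,
                            n_episodes=n_ep, n_exit_episodes=n_exit,
                            no_serial_episodes=False, no_exit_data=n_exit == 0)


def _squash_bneck(raw: float, scaler: CohortScaler | None) -> float:
    if scaler is None:
        return float(np.tanh(raw))
    return float(np.tanh(scaler.transform(np.asarray([raw]))[0]))
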