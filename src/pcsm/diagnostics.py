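"""Per-timepoint decoding-quality diagnostics and frame/trial flagging.

Three metrics gauge how trustworthy each decoded frame is:

* ``P_t`` — probability the brain is actively responding: the posterior-
  weighted responding-mixture weight, in [0, 1].
* ``rho_t`` — temporal reliability: one minus the total variation distance
  between consecutive state posteriors, in [0, 1].
* ``D_t^Maha`` — model-data discrepancy: the Mahalanobis distance between
  the observed FIR amplitudes and the posterior-predicted pattern under the
  global spatial covariance; reported raw (unbounded) and rank-normalised
  to [0, 1] within subject.

Frames where the discrepancy exceeds its threshold *and* both P_t and
rho_t are weak are flagged for removal; a trial with more than half of its
FIR bins flagged (3+ of 5) is recommended for removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .fir import FirSeries
from .state_model import GmmHmmParams, PosteriorTrajectory

__all__ = [
    "DiagnosticSeries",
    "response_probability",
    "temporal_reliability",
    "model_discrepancy",
    "flag_frames",
    "compute_diagnostics",
]


@dataclass
class DiagnosticSeries:
    """Per-frame diagnostics plus flagging state for one subject."""

    p_t: np.ndarray
    rho_t: np.ndarray
    d_maha_raw: np.ndarray
    d_maha_norm: np.ndarray
    trials: np.ndarray
    maha_flag: np.ndarray | None = None
    weak_p: np.ndarray | None = None
    weak_rho: np.ndarray | None = None
    removal_flag: np.ndarray | None = None
    trial_remove: np.ndarray | None = None      # per-trial bool
    trial_flag_counts: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "trial": self.trials,
            "p_t": self.p_t,
            "rho_t": self.rho_t,
            "d_maha_raw": self.d_maha_raw,
            "d_maha_norm": self.d_maha_norm,
        })
        for name in ("maha_flag", "weak_p", "weak_rho", "removal_flag"):
            v = getattr(self, name)
            if v is not None:
                df[name] = v
        return df


def response_probability(traj: PosteriorTrajectory, params: GmmHmmParams) -> np.ndarray:
    """P_t = sum_c pi_{t,c} a_{c,1}: posterior-weighted responding weight."""
    return traj.pi @ params.responding_weights


def temporal_reliability(traj: PosteriorTrajectory, smooth: bool = False,
                         halflife: float | None = None) -> np.ndarray:
    """rho_t = 1 - TV(pi_t, pi_{t-1}); rho_0 = 1 by convention.

    With ``smooth`` an exponential moving average (half-life tied to the
    per-trial bin count unless overridden) is applied to the rho series
    only — the definition of rho itself is unchanged.
    """
    pi = traj.pi
    rho = np.ones(pi.shape[0])
    if pi.shape[0] > 1:
        rho[1:] = 1.0 - 0.5 * np.abs(np.diff(pi, axis=0)).sum(axis=1)
    if smooth:
        hl = halflife if halflife is not None else float(traj.seq_lengths[0])
        rho = pd.Series(rho).ewm(halflife=hl).mean().to_numpy()
    return rho


def _stable_solve(cov: np.ndarray, resid: np.ndarray) -> np.ndarray:
    """Solve cov @ z = resid' via Cholesky with escalating jitter."""
    scale = float(np.trace(cov)) / cov.shape[0]
    jitter = 0.0
    for _ in range(8):
        try:
            chol = np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10 * scale)
    else:
        raise np.linalg.LinAlgError("covariance not positive definite even with jitter")
    if jitter:
        warnings.warn(f"singular spatial covariance; jitter {jitter:.2e} added",
                      stacklevel=3)
    z = np.linalg.solve(chol, resid.T)
    return np.linalg.solve(chol.T, z).T


def model_discrepancy(fir: FirSeries, params: GmmHmmParams,
                      traj: PosteriorTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Mahalanobis discrepancy between observed and posterior-predicted BOLD.

    The prediction is yhat_t = sum_c pi_{t,c} mu_bar_c with mu_bar_c the
    mixture-weighted state mean.  Returns ``(raw, normalised)`` where the
    normalised series is the within-subject empirical-CDF (mid-rank)
    transform of the raw quadratic form, supported on (0, 1).
    """
    if params.spatial_cov is None:
        raise ValueError("params.spatial_cov is required for discrepancy scoring")
    resid = fir.values - traj.pi @ params.state_means()
    sol = _stable_solve(params.spatial_cov, resid)
    raw = np.einsum("kn,kn->k", resid, sol)
    raw = np.maximum(raw, 0.0)
    norm = (rankdata(raw, method="average") - 0.5) / len(raw)
    return raw, norm


def flag_frames(diag: DiagnosticSeries, tau_maha: float, tau_p: float,
                tau_rho: float, n_delays: int | None = None) -> DiagnosticSeries:
    """Apply the frame and trial flagging rules.

    A frame is removal-flagged when its normalised discrepancy is at or
    above ``tau_maha`` *and* P_t < ``tau_p`` *and* rho_t < ``tau_rho``.  A
    trial is recommended for removal when more than half of its bins are
    flagged (>= 3 of 5 by default).
    """
    for tau in (tau_maha, tau_p, tau_rho):
        if tau is None or not np.isfinite(tau):
            raise ValueError("all three thresholds must be supplied and finite")
    diag.maha_flag = diag.d_maha_norm >= tau_maha
    diag.weak_p = diag.p_t < tau_p
    diag.weak_rho = diag.rho_t < tau_rho
    diag.removal_flag = diag.maha_flag & diag.weak_p & diag.weak_rho
    n_trials = int(diag.trials.max()) + 1
    counts = np.bincount(diag.trials[diag.removal_flag], minlength=n_trials)
    if n_delays is None:
        n_delays = int(np.bincount(diag.trials).max())
    diag.trial_flag_counts = counts
    diag.trial_remove = counts >= (n_delays // 2 + 1)
    return diag


def compute_diagnostics(fir: FirSeries, params: GmmHmmParams,
                        traj: PosteriorTrajectory,
                        smooth_rho: bool = False) -> DiagnosticSeries:
    """Convenience wrapper computing all three diagnostic series."""
    raw, norm = model_discrepancy(fir, params, traj)
    return DiagnosticSeries(
        p_t=response_probability(traj, params),
        rho_t=temporal_reliability(traj, smooth=smooth_rho),
        d_maha_raw=raw,
        d_maha_norm=norm,
        trials=fir.trials.copy(),
    )
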