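"""Finite-impulse-response (FIR) deconvolution of trial-aligned BOLD.

The FIR model estimates the evoked response at discrete post-stimulus
delays (here 0-8 s in TR steps, i.e. 5 bins at TR = 2 s) without assuming
any haemodynamic response shape.  Each trial ``r`` and delay ``d`` gets its
own stick regressor; ordinary least squares on the full design recovers a
trial- and delay-specific amplitude tensor of shape (R, D, N) which is
flattened trial-major into the K x N observation matrix fed to the state
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FirDesign", "FirSeries", "build_fir_design", "estimate_fir"]

RANK_RCOND = 1e-10  # relative singular-value cutoff for the pseudo-inverse


@dataclass
class FirDesign:
    """FIR design matrix with trial/delay column bookkeeping."""

    X: np.ndarray                 # (T, K) 0/1 stick regressors, trial-major
    trials: np.ndarray            # (K,) trial index per column
    delays: np.ndarray            # (K,) delay index per column
    tr_s: float
    n_trials: int
    n_delays: int

    @property
    def T(self) -> int:
        return self.X.shape[0]

    @property
    def K(self) -> int:
        return self.X.shape[1]

    @property
    def empty_columns(self) -> np.ndarray:
        """Mask of all-zero columns (delayed sticks falling outside the run)."""
        return ~self.X.any(axis=0)


@dataclass
class FirSeries:
    """K x N matrix of FIR amplitudes, one row per (trial, delay) bin.

    This is the observation sequence y_t of the state model; ``trials`` and
    ``delays`` map each row back to its (trial, delay) pair.
    """

    values: np.ndarray            # (K, N)
    trials: np.ndarray            # (K,)
    delays: np.ndarray            # (K,)
    node_labels: list[str] = field(default_factory=list)
    zscored: bool = False
    empty_rows: np.ndarray | None = None   # rows from all-zero design columns

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.trials = np.asarray(self.trials, dtype=int)
        self.delays = np.asarray(self.delays, dtype=int)
        if self.values.ndim != 2 or len(self.trials) != self.values.shape[0]:
            raise ValueError("values must be K x N with matching row index")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FIR amplitudes must be finite")
        if not self.node_labels:
            self.node_labels = [f"node_{i}" for i in range(self.values.shape[1])]

    @property
    def K(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    @property
    def n_trials(self) -> int:
        return int(self.trials.max()) + 1 if self.K else 0

    @property
    def n_delays(self) -> int:
        return int(self.delays.max()) + 1 if self.K else 0

    @property
    def seg_len(self) -> int:
        """Frames per trial segment; requires every trial to have the same count."""
        counts = np.bincount(self.trials)
        if counts.size and not np.all(counts == counts[0]):
            raise ValueError("trials have unequal numbers of delay bins")
        return int(counts[0]) if counts.size else 0

    def tensor(self) -> np.ndarray:
        """View as the (R, D, N) trial x delay x node tensor."""
        return self.values.reshape(self.n_trials, self.seg_len, self.n_nodes)

    def zscore(self) -> "FirSeries":
        """Return a copy with each node column standardised across all K rows."""
        v = self.values
        sd = v.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return FirSeries(values=(v - v.mean(axis=0)) / sd, trials=self.trials.copy(),
                         delays=self.delays.copy(), node_labels=list(self.node_labels),
                         zscored=True, empty_rows=self.empty_rows)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.node_labels)
        df.insert(0, "delay", self.delays)
        df.insert(0, "trial", self.trials)
        return df


def build_fir_design(trials: pd.DataFrame, T: int, tr_s: float = 2.0,
                     n_delays: int = 5) -> FirDesign:
    """Build the T x K FIR stick design from a trial table.

    Trial onsets are mapped to their nearest volume; the stick for delay
    ``d`` of trial ``r`` sits at row ``nearest(onset / TR) + d`` when that
    row exists, otherwise the column is left all-zero (with a warning).
    Columns are ordered trial-major then delay.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    onsets = np.asarray(trials["onset_s"] if "onset_s" in trials else trials["onset"],
                        dtype=float)
    if np.any(onsets < 0):
        raise ValueError("onsets must be non-negative")
    R = len(onsets)
    K = R * n_delays
    X = np.zeros((T, K))
    col_trials = np.repeat(np.arange(R), n_delays)
    col_delays = np.tile(np.arange(n_delays), R)
    vols = np.rint(onsets / tr_s).astype(int)
    n_lost = 0
    for r in range(R):
        for d in range(n_delays):
            row = vols[r] + d
            if 0 <= row < T:
                X[row, r * n_delays + d] = 1.0
            else:
                n_lost += 1
    if n_lost:
        warnings.warn(f"{n_lost} FIR regressors fall outside the run and are all-zero",
                      stacklevel=2)
    return FirDesign(X=X, trials=col_trials, delays=col_delays, tr_s=tr_s,
                     n_trials=R, n_delays=n_delays)


def estimate_fir(design: FirDesign, bold: np.ndarray,
                 node_labels: list[str] | None = None) -> FirSeries:
    """Estimate FIR amplitudes by rank-tolerant ordinary least squares.

    Solves beta = (X'X)^-1 X'Y jointly for all trials and delays with an
    SVD-based pseudo-inverse (singular values below ``1e-10`` of the largest
    treated as zero), after augmenting the design with a run intercept that
    is discarded from the returned series.  All-zero design columns yield
    amplitude 0 and are flagged in ``empty_rows``.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 2 or bold.shape[0] != design.T:
        raise ValueError(f"BOLD must be (T={design.T}) x N, got {bold.shape}")
    X = np.column_stack([design.X, np.ones(design.T)])
    rank_full = min(X.shape)
    beta, _, rank, _ = np.linalg.lstsq(X, bold, rcond=RANK_RCOND)
    if rank < rank_full:
        warnings.warn(f"rank-deficient FIR design (rank {rank} < {rank_full}); "
                      "pseudo-inverse solution returned", stacklevel=2)
    beta = beta[:-1]  # drop intercept
    empty = design.empty_columns
    beta[empty] = 0.0
    return FirSeries(values=beta, trials=design.trials.copy(),
                     delays=design.delays.copy(),
                     node_labels=list(node_labels) if node_labels is not None else [],
                     zscored=False, empty_rows=empty.copy())
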