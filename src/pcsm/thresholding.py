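"""Data-driven decision boundaries for the PCSM metrics.

Three estimators cover the metric families:

* **Gaussian-mixture intersection** — for clearly bimodal metrics, fit a
  two-component univariate Gaussian mixture and place the boundary where
  the weighted component densities are equal (the root of a quadratic in
  the log densities, kept between the component means).  The split is
  accepted only when both component weights exceed 20% and the Cohen's-d
  style separation is at least 1; otherwise the estimator falls back to a
  KDE valley.
* **Boundary-corrected KDE valley** — smooth a high-resolution histogram
  with a Gaussian kernel after reflecting mass at the support boundaries,
  and take the local density minimum inside a pre-specified window.  A
  sensitivity sweep over bandwidth (x0.5, x1, x2) and bin count (256, 512,
  1024) reports the maximum threshold drift.
* **Quartile bootstrap** — for unimodal metrics, robust-standardise the
  pooled values and use the 25th/75th percentiles as cut points with
  subject-level bootstrap confidence intervals.

Node selection on the response posterior B uses an adaptive
posterior-error rule: keep the largest descending-B prefix whose mean
posterior error (mean of 1-B) stays at or below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.mixture import GaussianMixture

__all__ = [
    "ThresholdSet",
    "ThresholdNotFoundError",
    "separation_d",
    "gaussian_intersections",
    "gmm_intersection_threshold",
    "kde_valley_threshold",
    "quartile_bootstrap_thresholds",
    "adaptive_fdr_select",
    "adaptive_fdr_batch",
]


class ThresholdNotFoundError(RuntimeError):
    """Raised when no valley/intersection exists in the requested window."""

    def __init__(self, message: str, density: np.ndarray | None = None,
                 grid: np.ndarray | None = None):
        super().__init__(message)
        self.density = density
        self.grid = grid


@dataclass
class ThresholdSet:
    """A metric's decision boundary(ies) plus how they were obtained."""

    metric: str
    taus: dict                      # {"single": x} or {"low": x, "high": y}
    method: str                     # gmm_intersection | kde_valley | quartile_bootstrap
    separation_d: float | dict | None = None
    mixture_summary: dict | None = None
    ci: dict | None = None
    sensitivity: dict | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "taus": self.taus,
            "method": self.method,
            "separation_d": self.separation_d,
            "mixture_summary": self.mixture_summary,
            "ci": self.ci,
            "sensitivity": self.sensitivity,
            "extras": self.extras,
        }


def separation_d(m1: float, s1: float, m2: float, s2: float) -> float:
    """Cohen's-d style separation |m2 - m1| / sqrt((s1^2 + s2^2) / 2)."""
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    return abs(m2 - m1) / np.sqrt((s1 ** 2 + s2 ** 2) / 2.0)


def gaussian_intersections(w1: float, m1: float, s1: float,
                           w2: float, m2: float, s2: float) -> np.ndarray:
    """Real solutions of w1 N(x|m1,s1) = w2 N(x|m2,s2), sorted ascending.

    Equating log densities yields a quadratic (linear when s1 == s2).
    """
    a = 0.5 / s1 ** 2 - 0.5 / s2 ** 2
    b = m2 / s2 ** 2 - m1 / s1 ** 2
    c = (m1 ** 2 / (2 * s1 ** 2) - m2 ** 2 / (2 * s2 ** 2)
         - np.log((w1 * s2) / (w2 * s1)))
    if abs(a) < 1e-300:
        if b == 0:
            return np.asarray([])
        return np.asarray([-c / b])
    disc = b ** 2 - 4 * a * c
    if disc < 0:
        return np.asarray([])
    r = np.sqrt(disc)
    return np.sort(np.asarray([(-b - r) / (2 * a), (-b + r) / (2 * a)]))


def _fit_two_gaussians(samples: np.ndarray, seed: int | None):
    gm = GaussianMixture(n_components=2, covariance_type="full",
                         n_init=3, random_state=seed)
    gm.fit(samples.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(means)
    return gm.weights_[order], means[order], sds[order]


def gmm_intersection_threshold(samples: np.ndarray,
                               support: tuple[float, float] | None = None,
                               metric: str = "", seed: int | None = 0,
                               weight_gate: float = 0.20, d_gate: float = 1.0,
                               on_gate_failure: str = "kde_valley",
                               kde_windows=None) -> ThresholdSet:
    """Two-component Gaussian-mixture intersection threshold with gating.

    Keeps the density-equality root between the component means.  When a
    component weight falls at or below ``weight_gate``, the separation is
    below ``d_gate``, or no between-means root exists, the estimator either
    falls back to a KDE valley (default) or, with
    ``on_gate_failure="keep"``, reports the intersection anyway with the
    gate diagnostics attached.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 100:
        raise ValueError("need at least 100 samples for a mixture threshold")
    if support is None:
        support = (float(samples.min()), float(samples.max()))
    (w1, w2), (m1, m2), (s1, s2) = _fit_two_gaussians(samples, seed)
    d = separation_d(m1, s1, m2, s2)
    roots = gaussian_intersections(w1, m1, s1, w2, m2, s2)
    between = roots[(roots > m1) & (roots < m2)]
    summary = {"weights": (float(w1), float(w2)), "means": (float(m1), float(m2)),
               "sds": (float(s1), float(s2))}
    gates_ok = (w1 > weight_gate and w2 > weight_gate and d >= d_gate
                and between.size > 0)
    if gates_ok or (on_gate_failure == "keep" and between.size > 0):
        return ThresholdSet(metric=metric, taus={"single": float(between[-1])},
                            method="gmm_intersection", separation_d=float(d),
                            mixture_summary=summary,
                            extras={"gates_passed": bool(gates_ok),
                                    "all_intersections": roots.tolist()})
    ts = kde_valley_threshold(samples, support=support, windows=kde_windows,
                              metric=metric)
    ts.mixture_summary = summary
    ts.separation_d = float(d)
    ts.extras["gates_passed"] = False
    ts.extras["gmm_intersections"] = roots.tolist()
    return ts


def _silverman_bw(x: np.ndarray) -> float:
    sd = x.std()
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale == 0:
        scale = max(sd, 1e-3)
    return 0.9 * scale * len(x) ** (-0.2)


def _smoothed_density(samples: np.ndarray, support: tuple[float, float],
                      n_bins: int, bandwidth: float) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = support
    counts, edges = np.histogram(samples, bins=n_bins, range=(lo, hi))
    counts = counts.astype(float)
    bin_w = (hi - lo) / n_bins
    sigma_bins = max(bandwidth / bin_w, 1e-6)
    # reflect mass at both boundaries before smoothing
    padded = np.concatenate([counts[::-1], counts, counts[::-1]])
    sm = gaussian_filter1d(padded, sigma_bins)[n_bins:2 * n_bins]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, sm


def _find_valleys(centers: np.ndarray, density: np.ndarray,
                  window: tuple[float, float]) -> list[float]:
    """Local density minima inside the window, deepest separating dip first.

    Valleys are peaks of the negated density ranked by topographic
    prominence, which ignores spurious near-zero minima in empty tails.
    """
    from scipy.signal import find_peaks
    idx, props = find_peaks(-density, prominence=0.0)
    cand = [(int(i), float(props["prominences"][j])) for j, i in enumerate(idx)
            if window[0] <= centers[i] <= window[1]]
    cand.sort(key=lambda t: -t[1])
    return [float(centers[i]) for i, _ in cand]


def kde_valley_threshold(samples: np.ndarray, support: tuple[float, float],
                         windows=None, bandwidth: float | None = None,
                         n_bins: int = 512, metric: str = "") -> ThresholdSet:
    """Boundary-corrected KDE valley threshold(s).

    One threshold is returned per window (default: the whole support),
    taken as the lowest-density local minimum of the reflected-and-smoothed
    histogram inside the window.  The sensitivity sweep varies the
    bandwidth over {0.5x, 1x, 2x} and the bin count over {256, 512, 1024}
    and reports the maximum drift per window.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    lo, hi = support
    tol = 1e-9 * max(1.0, abs(hi - lo))
    if np.any((samples < lo - tol) | (samples > hi + tol)):
        raise ValueError("samples must lie within the stated support")
    samples = np.clip(samples, lo, hi)
    if bandwidth is None:
        bandwidth = _silverman_bw(samples)
    if windows is None:
        windows = [(lo, hi)]
    single = len(windows) == 1

    def _one(bw: float, nb: int) -> list[float | None]:
        centers, dens = _smoothed_density(samples, support, nb, bw)
        out = []
        for w in windows:
            valleys = _find_valleys(centers, dens, w)
            out.append(valleys[0] if valleys else None)
        return out

    base = _one(bandwidth, n_bins)
    for i, v in enumerate(base):
        if v is None:
            centers, dens = _smoothed_density(samples, support, n_bins, bandwidth)
            raise ThresholdNotFoundError(
                f"no local density minimum in window {windows[i]}",
                density=dens, grid=centers)
    drift = [0.0] * len(windows)
    for bw_mult in (0.5, 1.0, 2.0):
        for nb in (256, 512, 1024):
            alt = _one(bandwidth * bw_mult, nb)
            for i, v in enumerate(alt):
                if v is not None:
                    drift[i] = max(drift[i], abs(v - base[i]))
    if single:
        taus = {"single": base[0]}
        sens = {"max_drift": drift[0]}
    else:
        keys = ["low", "high"] if len(windows) == 2 else [f"w{i}" for i in range(len(windows))]
        taus = dict(zip(keys, base))
        sens = {"max_drift": dict(zip(keys, drift))}
    return ThresholdSet(metric=metric, taus=taus, method="kde_valley",
                        sensitivity=sens,
                        extras={"bandwidth": float(bandwidth), "n_bins": n_bins,
                                "windows": [list(w) for w in windows]})


def quartile_bootstrap_thresholds(subject_values: list[np.ndarray],
                                  n_boot: int = 2000, seed: int | None = None,
                                  metric: str = "") -> ThresholdSet:
    """Robust-standardised quartile cut points with subject-level bootstrap.

    Pools all subjects, robust-standardises (median / 1.4826*MAD), and uses
    the 25th/75th percentiles as low/high thresholds.  Bootstrapping whole
    subjects (2000 resamples) yields percentile 95% CIs; acceptance
    requires the CI of the high-low difference to exclude 0 and a
    separation d > 1 between the below-low and above-high subsets.
    """
    from .emergent import robust_scale

    if len(subject_values) < 10:
        raise ValueError("need at least 10 subjects for the bootstrap")
    rng = np.random.default_rng(seed)
    pooled = robust_scale(np.concatenate([np.asarray(v, float).ravel()
                                          for v in subject_values]))
    q_low, q_high = np.percentile(pooled, [25, 75])
    n_subj = len(subject_values)
    boots = np.empty((n_boot, 2))
    for b in range(n_boot):
        take = rng.integers(0, n_subj, size=n_subj)
        sample = robust_scale(np.concatenate(
            [np.asarray(subject_values[i], float).ravel() for i in take]))
        boots[b] = np.percentile(sample, [25, 75])
    ci_low = np.percentile(boots[:, 0], [2.5, 97.5])
    ci_high = np.percentile(boots[:, 1], [2.5, 97.5])
    diff = boots[:, 1] - boots[:, 0]
    ci_diff = np.percentile(diff, [2.5, 97.5])
    below = pooled[pooled < q_low]
    above = pooled[pooled > q_high]
    d = None
    if below.size > 1 and above.size > 1 and below.std() > 0 and above.std() > 0:
        d = separation_d(float(below.mean()), float(below.std()),
                         float(above.mean()), float(above.std()))
    accepted = bool(ci_diff[0] > 0 and d is not None and d > 1.0)
    return ThresholdSet(
        metric=metric, taus={"low": float(q_low), "high": float(q_high)},
        method="quartile_bootstrap", separation_d=d,
        ci={"low": ci_low.tolist(), "high": ci_high.tolist(),
            "difference": ci_diff.tolist()},
        extras={"n_boot": n_boot, "accepted": accepted})


# ---------------------------------------------------------------------------
# adaptive posterior-FDR node selection


def adaptive_fdr_select(b_row: np.ndarray, alpha: float,
                        method: str = "prefix"):
    """Select responding nodes from a posterior row at error level alpha.

    ``prefix`` (default): sort nodes by descending B and retain the largest
    prefix whose mean posterior error (mean of 1-B) stays at or below
    alpha — the realized error estimate is conservative by construction.
    ``bh``: Benjamini-Hochberg on p = 1 - B as an alternate reading.

    Returns ``(selected_indices, realized_tau, fdr_estimate)``; an empty
    selection yields ``(empty, nan, 0.0)``.
    """
    b = np.asarray(b_row, dtype=float)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    order = np.argsort(-b, kind="stable")
    if method == "prefix":
        err = np.cumsum(1.0 - b[order]) / np.arange(1, b.size + 1)
        k = int(np.searchsorted(err, alpha, side="right"))
    elif method == "bh":
        p = 1.0 - b[order]
        crit = alpha * np.arange(1, b.size + 1) / b.size
        hits = np.nonzero(p <= crit)[0]
        k = int(hits[-1] + 1) if hits.size else 0
    else:
        raise ValueError("method must be 'prefix' or 'bh'")
    sel = np.sort(order[:k])
    if k == 0:
        return sel, float("nan"), 0.0
    realized_tau = float(b[order[k - 1]])
    fdr = float(np.mean(1.0 - b[order[:k]]))
    return sel, realized_tau, fdr


def adaptive_fdr_batch(B: np.ndarray, alpha: float):
    """Vectorised prefix-rule selection over many posterior rows.

    Returns ``(counts, realized_taus, fdr_estimates)`` each of length K;
    rows with empty selections get tau = nan and fdr = nan.
    """
    B = np.atleast_2d(np.asarray(B, dtype=float))
    K, N = B.shape
    srt = -np.sort(-B, axis=1)
    err = np.cumsum(1.0 - srt, axis=1) / np.arange(1, N + 1)
    counts = (err <= alpha).sum(axis=1)
    # mean error is non-decreasing along the sorted prefix, so the count is
    # the largest admissible prefix
    taus = np.full(K, np.nan)
    fdrs = np.full(K, np.nan)
    nz = counts > 0
    idx = counts[nz] - 1
    taus[nz] = srt[nz, idx]
    fdrs[nz] = err[nz, idx]
    return counts, taus, fdrs
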