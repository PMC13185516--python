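"""End-to-end orchestration of the simulation study and empirical runs.

``run_simulation_study`` executes the whole validation chain on synthetic
data with known ground truth: simulate a cohort balanced over transition
regimes and noise levels, fit the global GMM-HMM template, fit and align
every subject with frozen covariances, decode, compute diagnostics and
emergent metrics, estimate all data-driven thresholds from the pooled
cohort, and evaluate latent-state/transition recovery.  All randomness
flows from the single ``seed``.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import diagnostics as diag_mod
from . import emergent, thresholding
from .recovery_eval import (RecoveryReport, evaluate_state_recovery,
                            evaluate_transition_recovery)
from .simulator import NOISE_LEVELS, REGIMES, SimulationConfig, simulate_cohort
from .state_model import (GmmHmmParams, align_to_template, fit_global,
                          fit_subject, infer_posteriors)
from .thresholding import ThresholdSet, gaussian_intersections, separation_d

logger = logging.getLogger("pcsm")

__all__ = ["StudyResult", "run_simulation_study", "dsp_thresholds"]

DSP_LOW_WINDOW = (0.45, 0.58)  # expected parallel/mixed density dip
ALPHA_GRID = (0.10, 0.15, 0.20, 0.25, 0.30)
FDR_ALPHA_DEFAULT = 0.25


@dataclass
class SubjectMetrics:
    """Small per-subject summary retained by the study driver."""

    regime: str
    noise_level: str
    p_t: np.ndarray
    rho_t: np.ndarray
    d_maha_norm: np.ndarray
    d_sp: np.ndarray
    demand_raw: np.ndarray
    demand_squashed: np.ndarray
    fdr_counts: dict            # alpha -> mean retained nodes
    fdr_realized: dict          # alpha -> mean realized error (selected frames)
    mode: np.ndarray | None = None
    resource: "emergent.ResourceResult | None" = None
    bottleneck: "emergent.BottleneckResult | None" = None


@dataclass
class StudyResult:
    global_params: GmmHmmParams
    subjects: list[SubjectMetrics]
    state_recovery: RecoveryReport
    transition_recovery: RecoveryReport
    thresholds: dict[str, ThresholdSet] = field(default_factory=dict)
    fdr: dict = field(default_factory=dict)
    bottleneck_stats: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def pooled(self, attr: str) -> np.ndarray:
        return np.concatenate([getattr(s, attr) for s in self.subjects])


def dsp_thresholds(pooled_dsp: np.ndarray, seed: int | None = 0,
                   low_window: tuple[float, float] = DSP_LOW_WINDOW) -> ThresholdSet:
    """Composite serial-parallel boundaries.

    Fits the two-component mixture and keeps the separation-passing upper
    (between-means) intersection as the mixed/serial boundary; the lower
    parallel/mixed boundary is refined by a boundary-corrected KDE valley
    within ``low_window`` because the lower intersection typically fails
    the separation gate on this metric.
    """
    samples = np.asarray(pooled_dsp, dtype=float).ravel()
    (w1, w2), (m1, m2), (s1, s2) = thresholding._fit_two_gaussians(samples, seed)
    d = separation_d(m1, s1, m2, s2)
    roots = gaussian_intersections(w1, m1, s1, w2, m2, s2)
    between = roots[(roots > m1) & (roots < m2)]
    tau_high = float(between[-1]) if between.size else float(np.median([m1, m2]))
    kde = None
    tau_low = None
    low_method = "kde_valley"
    try:
        kde = thresholding.kde_valley_threshold(
            samples, support=(0.0, 1.0), windows=[low_window], metric="d_sp_low")
        tau_low = kde.taus["single"]
    except thresholding.ThresholdNotFoundError:
        # no density dip in the expected window; widen to everything below
        # the upper boundary, then fall back to the lower mixture root
        try:
            kde = thresholding.kde_valley_threshold(
                samples, support=(0.0, 1.0), windows=[(0.0, tau_high)],
                metric="d_sp_low")
            tau_low = kde.taus["single"]
            low_method = "kde_valley_widened"
        except thresholding.ThresholdNotFoundError:
            tau_low = float(roots[0]) if roots.size else float(m1)
            low_method = "gmm_lower_root"
    if tau_low >= tau_high:  # degenerate split; fall back to the raw lower root
        tau_low = float(roots[0]) if roots.size > 1 and roots[0] < tau_high \
            else tau_high - 0.05
        low_method += "+degenerate"
    lower = samples[samples <= tau_low]
    mid = samples[(samples > tau_low) & (samples < tau_high)]
    d_low = None
    if lower.size > 1 and mid.size > 1 and lower.std() > 0 and mid.std() > 0:
        d_low = separation_d(float(lower.mean()), float(lower.std()),
                             float(mid.mean()), float(mid.std()))
    return ThresholdSet(
        metric="d_sp", taus={"low": float(tau_low), "high": tau_high},
        method="gmm_intersection+kde_valley",
        separation_d={"high": float(d), "low": d_low},
        mixture_summary={"weights": (float(w1), float(w2)),
                         "means": (float(m1), float(m2)),
                         "sds": (float(s1), float(s2))},
        sensitivity=kde.sensitivity if kde is not None else None,
        extras={"all_intersections": roots.tolist(),
                "low_window": list(low_window), "low_method": low_method})


def run_simulation_study(n_subjects_per_cell: int = 9, seed: int | None = 0,
                         base_config: SimulationConfig | None = None,
                         C: int = 3, M: int = 2, n_init: int = 3,
                         max_iter: int = 50, tol: float = 1e-4,
                         subject_max_iter: int = 50,
                         n_boot: int = 2000,
                         alpha_grid=ALPHA_GRID,
                         fdr_alpha: float = FDR_ALPHA_DEFAULT,
                         regimes=REGIMES, noise_levels=NOISE_LEVELS,
                         progress: bool = False) -> StudyResult:
    """Run the full scaled simulation study.

    The cohort is balanced over ``regimes x noise_levels`` with
    ``n_subjects_per_cell`` subjects per cell (default 9 x 12 = 108).
    Returns recovery reports, all metric thresholds, adaptive-FDR
    statistics and per-subject metric series.
    """
    t0 = time.time()
    timings: dict[str, float] = {}
    root = np.random.SeedSequence(seed)
    sim_seed, fit_seed, thr_seed = (int(s.generate_state(1)[0] % (2 ** 31))
                                    for s in root.spawn(3))
    configs, _tabs, truths, firs = simulate_cohort(
        n_subjects_per_cell, seed=sim_seed, base_config=base_config,
        regimes=regimes, noise_levels=noise_levels)
    timings["simulate"] = time.time() - t0
    logger.info("simulated %d subjects in %.1fs", len(firs), timings["simulate"])

    t1 = time.time()
    gp = fit_global(firs, C=C, M=M, n_init=n_init, max_iter=max_iter, tol=tol,
                    seed=fit_seed)
    timings["fit_global"] = time.time() - t1
    logger.info("global fit in %.1fs", timings["fit_global"])

    t2 = time.time()
    subjects: list[SubjectMetrics] = []
    decoded: list[np.ndarray] = []
    for i, (cfg, fir) in enumerate(zip(configs, firs)):
        sp = fit_subject(fir, gp, max_iter=subject_max_iter, tol=tol)
        aligned = align_to_template(sp, gp).aligned
        traj = infer_posteriors(aligned, fir, smoothing="filtered")
        decoded.append(traj.viterbi)
        d = diag_mod.compute_diagnostics(fir, aligned, traj)
        B = emergent.node_response_posterior(fir, aligned, traj)
        d_sp = emergent.serial_parallel_deviation(B)
        fdr_counts, fdr_real = {}, {}
        for a in alpha_grid:
            counts, _taus, fdrs = thresholding.adaptive_fdr_batch(B, a)
            sel = counts > 0
            fdr_counts[a] = float(counts.mean())
            fdr_real[a] = float(fdrs[sel].mean()) if sel.any() else 0.0
        del B
        dem = emergent.cognitive_demand(d_sp, traj)
        subjects.append(SubjectMetrics(
            regime=cfg.transition_regime, noise_level=cfg.noise_level,
            p_t=d.p_t, rho_t=d.rho_t, d_maha_norm=d.d_maha_norm,
            d_sp=d_sp, demand_raw=dem.raw, demand_squashed=dem.squashed,
            fdr_counts=fdr_counts, fdr_realized=fdr_real))
        if progress and (i + 1) % 10 == 0:
            logger.info("subject %d/%d done (%.1fs)", i + 1, len(firs),
                        time.time() - t2)
    timings["subjects"] = time.time() - t2

    t3 = time.time()
    state_rec = evaluate_state_recovery(decoded, truths)
    trans_rec = evaluate_transition_recovery(decoded, truths)
    timings["recovery"] = time.time() - t3

    t4 = time.time()
    result = StudyResult(global_params=gp, subjects=subjects,
                         state_recovery=state_rec, transition_recovery=trans_rec,
                         timings=timings)
    thr: dict[str, ThresholdSet] = {}
    thr["rho"] = thresholding.gmm_intersection_threshold(
        result.pooled("rho_t"), support=(0.0, 1.0), metric="rho", seed=thr_seed)
    thr["p"] = thresholding.gmm_intersection_threshold(
        result.pooled("p_t"), support=(0.0, 1.0), metric="p", seed=thr_seed)
    thr["d_maha"] = thresholding.gmm_intersection_threshold(
        result.pooled("d_maha_norm"), support=(0.0, 1.0), metric="d_maha",
        seed=thr_seed)
    thr["d_sp"] = dsp_thresholds(result.pooled("d_sp"), seed=thr_seed)

    # mode-dependent metrics need the D^SP boundaries
    for s in subjects:
        s.mode = emergent.classify_mode(s.d_sp, thr["d_sp"].taus["low"],
                                        thr["d_sp"].taus["high"])
        s.resource = emergent.resource_level(s.demand_raw, s.mode)
        s.bottleneck = emergent.serial_bottleneck(s.mode, s.demand_raw)

    thr["demand"] = thresholding.quartile_bootstrap_thresholds(
        [s.demand_squashed for s in subjects], n_boot=n_boot, seed=thr_seed,
        metric="demand")
    thr["resource"] = thresholding.quartile_bootstrap_thresholds(
        [s.resource.squashed for s in subjects], n_boot=n_boot, seed=thr_seed,
        metric="resource")

    raw_bneck = np.asarray([s.bottleneck.raw for s in subjects])
    scaler = emergent.CohortScaler.fit(raw_bneck)
    squashed_bneck = np.tanh(scaler.transform(raw_bneck))
    for s, v in zip(subjects, squashed_bneck):
        s.bottleneck.squashed = float(v)
    result.bottleneck_stats = {
        "scaler": {"median": scaler.median, "mad": scaler.mad},
        "squashed": squashed_bneck.tolist(),
        "negative_fraction": float(np.mean(squashed_bneck < 0)),
        "positive_fraction": float(np.mean(squashed_bneck > 0)),
    }
    try:
        tail = squashed_bneck[squashed_bneck > 0]
        if tail.size >= 20:
            kde = thresholding.kde_valley_threshold(
                tail, support=(0.0, 1.0), metric="bottleneck_tail")
            result.bottleneck_stats["tail_thresholds"] = kde.taus
    except thresholding.ThresholdNotFoundError:
        pass
    result.thresholds = thr

    result.fdr = {
        "alpha_grid": list(alpha_grid),
        "mean_retained": {a: float(np.mean([s.fdr_counts[a] for s in subjects]))
                          for a in alpha_grid},
        "mean_realized": {a: float(np.mean([s.fdr_realized[a] for s in subjects]))
                          for a in alpha_grid},
        "default_alpha": fdr_alpha,
    }
    timings["thresholds"] = time.time() - t4
    timings["total"] = time.time() - t0
    return result
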