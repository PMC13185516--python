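"""Ground-truth recovery and cross-validated stability evaluation.

Compares template-aligned decoded state sequences against the simulator's
ground truth (per-state precision/recall/F1, overall accuracy, confusion
matrices), separately for discrete states and for the binary stay/change
transition process, optionally stratified by transition regime and noise
level.  Also provides Dice-coefficient spatial-pattern consistency and a
k-fold stability check of the global model fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import KFold

from .fir import FirSeries
from .simulator import GroundTruth
from .state_model import GmmHmmParams, fit_global, score

__all__ = [
    "RecoveryReport",
    "evaluate_state_recovery",
    "evaluate_transition_recovery",
    "dice_similarity",
    "crossval_global_stability",
]


@dataclass
class RecoveryReport:
    """Classification-style recovery metrics with optional strata."""

    labels: list
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    macro_f1: float
    confusion: np.ndarray
    strata: dict = field(default_factory=dict)   # name -> RecoveryReport

    def to_dict(self) -> dict:
        out = {
            "labels": [str(x) for x in self.labels],
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "support": self.support.tolist(),
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "confusion": self.confusion.tolist(),
        }
        if self.strata:
            out["strata"] = {k: v.to_dict() for k, v in self.strata.items()}
        return out


def _classification_report(y_true: np.ndarray, y_pred: np.ndarray,
                           labels: list) -> RecoveryReport:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # absent classes yield 0-division warnings
        p, r, f1, sup = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, zero_division=0)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    present = np.isin(labels, np.unique(y_true))
    macro = float(f1[present].mean()) if present.any() else 0.0
    return RecoveryReport(labels=list(labels), precision=p, recall=r, f1=f1,
                          support=sup, accuracy=float(np.mean(y_true == y_pred)),
                          macro_f1=macro, confusion=cm)


def _stratify(keys: list[str], y_true: np.ndarray, y_pred: np.ndarray,
              groups: np.ndarray, labels: list) -> dict:
    out = {}
    for key in keys:
        mask = groups == key
        if mask.any():
            out[key] = _classification_report(y_true[mask], y_pred[mask], labels)
    return out


def evaluate_state_recovery(pred: list[np.ndarray], truth: list[GroundTruth],
                            by_regime: bool = True,
                            by_noise: bool = True) -> RecoveryReport:
    """Pooled per-state recovery of decoded (template-aligned) sequences.

    ``pred`` holds one decoded state sequence per subject, already aligned
    to the template labelling; strata reports repeat the metrics per
    transition regime and per noise level.
    """
    if len(pred) != len(truth):
        raise ValueError("prediction and truth lists differ in length")
    for p, t in zip(pred, truth):
        if len(p) != t.K:
            raise ValueError("sequence length mismatch")
    y_pred = np.concatenate(pred)
    y_true = np.concatenate([t.state_seq for t in truth])
    labels = sorted(np.unique(y_true).tolist())
    report = _classification_report(y_true, y_pred, labels)
    if by_regime:
        groups = np.concatenate([np.full(t.K, t.regime) for t in truth])
        report.strata.update({f"regime={k}": v for k, v in _stratify(
            sorted(set(groups)), y_true, y_pred, groups, labels).items()})
    if by_noise:
        groups = np.concatenate([np.full(t.K, t.noise_level) for t in truth])
        report.strata.update({f"noise={k}": v for k, v in _stratify(
            sorted(set(groups)), y_true, y_pred, groups, labels).items()})
    return report


def evaluate_transition_recovery(pred: list[np.ndarray], truth: list[GroundTruth],
                                 by_regime: bool = True,
                                 by_noise: bool = True) -> RecoveryReport:
    """Stay(0)/change(1) recovery, excluding the first bin of every trial.

    Transition indicators are undefined across trial boundaries, so only
    within-trial steps enter the 2x2 confusion matrix.  Metrics for a class
    absent from the ground truth are excluded from the macro average rather
    than reported as NaN.
    """
    if len(pred) != len(truth):
        raise ValueError("prediction and truth lists differ in length")
    yt, yp, reg, noi = [], [], [], []
    for p, t in zip(pred, truth):
        if len(p) != t.K:
            raise ValueError("sequence length mismatch")
        change_t, valid = t.transition_seq()
        change_p = np.zeros(t.K, dtype=int)
        change_p[1:] = np.asarray(p)[1:] != np.asarray(p)[:-1]
        yt.append(change_t[valid])
        yp.append(change_p[valid])
        reg.append(np.full(valid.sum(), t.regime))
        noi.append(np.full(valid.sum(), t.noise_level))
    y_true = np.concatenate(yt)
    y_pred = np.concatenate(yp)
    labels = [0, 1]
    report = _classification_report(y_true, y_pred, labels)
    if by_regime:
        groups = np.concatenate(reg)
        report.strata.update({f"regime={k}": v for k, v in _stratify(
            sorted(set(groups)), y_true, y_pred, groups, labels).items()})
    if by_noise:
        groups = np.concatenate(noi)
        report.strata.update({f"noise={k}": v for k, v in _stratify(
            sorted(set(groups)), y_true, y_pred, groups, labels).items()})
    return report


def dice_similarity(a: np.ndarray, b: np.ndarray,
                    binarize: str | float = "top_quartile") -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) between binarised patterns.

    ``binarize`` is either ``"top_quartile"`` (membership = |x| at or above
    the pattern's own 75th percentile of magnitudes) or a numeric absolute
    threshold.  Two empty sets count as perfectly overlapping (Dice 1).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("patterns must have equal length")
    if binarize == "top_quartile":
        sa = np.abs(a) >= np.percentile(np.abs(a), 75)
        sb = np.abs(b) >= np.percentile(np.abs(b), 75)
    else:
        thr = float(binarize)
        sa = np.abs(a) >= thr
        sb = np.abs(b) >= thr
    denom = sa.sum() + sb.sum()
    if denom == 0:
        warnings.warn("both binarised patterns empty; Dice defined as 1", stacklevel=2)
        return 1.0
    return float(2.0 * np.sum(sa & sb) / denom)


def crossval_global_stability(fir_stack: list[FirSeries], k: int = 5,
                              seed: int | None = None,
                              global_params: GmmHmmParams | None = None,
                              **fit_kwargs) -> dict:
    """k-fold stability of the global fit: held-out LL spread and Dice.

    Refits the global model on each training fold, scores the held-out
    subjects (log likelihood per observation), and checks that every fold
    value stays within 2 SD of the fold mean.  Spatial consistency is the
    Dice overlap between fold-specific and full-data state mean / variance
    patterns (top-quartile binarisation, states in template order).
    """
    if len(fir_stack) < k:
        raise ValueError("need at least as many subjects as folds")
    rng = np.random.default_rng(seed)
    fit_kwargs.setdefault("n_init", 2)
    if global_params is None:
        global_params = fit_global(fir_stack, seed=int(rng.integers(2 ** 31)),
                                   **fit_kwargs)
    kf = KFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2 ** 31)))
    fold_ll, dice_means, dice_vars = [], [], []
    from .state_model import align_to_template
    for train, test in kf.split(fir_stack):
        fp = fit_global([fir_stack[i] for i in train],
                        C=global_params.C, M=global_params.M,
                        seed=int(rng.integers(2 ** 31)), **fit_kwargs)
        fp = align_to_template(fp, global_params).aligned
        tot = sum(score(fp, fir_stack[i]) for i in test)
        n = sum(fir_stack[i].K for i in test)
        fold_ll.append(tot / n)
        for c in range(global_params.C):
            dice_means.append(dice_similarity(fp.state_means()[c],
                                              global_params.state_means()[c]))
            dice_vars.append(dice_similarity(fp.variances[c].mean(axis=0),
                                             global_params.variances[c].mean(axis=0)))
    fold_ll = np.asarray(fold_ll)
    sd = fold_ll.std(ddof=1) if len(fold_ll) > 1 else 0.0
    within = (np.abs(fold_ll - fold_ll.mean()) <= 2 * sd) | (sd == 0)
    return {
        "fold_loglik_per_obs": fold_ll.tolist(),
        "stable": bool(np.all(within)),
        "dice_means": dice_means,
        "dice_variances": dice_vars,
        "dice_means_avg": float(np.mean(dice_means)),
        "dice_variances_avg": float(np.mean(dice_vars)),
    }
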