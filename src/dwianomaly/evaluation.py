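"""Masked Dice / ROC-AUC metrics and the 7-fold cross-validation harness.

All metrics are confined to the evaluation mask (white + gray matter).  AUC
is computed per subject over the masked voxels with rank-based tie handling
(equivalent to the Mann-Whitney U statistic) and aggregated as unweighted
mean ± population std across subjects, the usual "mean ± std" report
format.  Dice of two empty masks is defined as 1 (a healthy phantom scored
as fully healthy); subjects with an empty groundtruth are excluded from AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .io import AnomalyMap, BinaryLesionMask, DWIVolume, EvaluationMask
from .maps import normalize_scores, residual, restrict
from .thresholding import (
    SUPERVISED_METHODS,
    binarize,
    morphological_opening,
    select_threshold,
)


@dataclass
class FoldSplit:
    """Partition of subjects into folds (each used once for validation)."""

    n_subjects: int
    n_folds: int = 7
    seed: int = 0
    assignments: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.n_subjects < self.n_folds:
            raise ValueError(
                f"cannot split {self.n_subjects} subjects into {self.n_folds} folds"
            )
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(self.n_subjects)
        # round-robin over a random order: fold sizes differ by at most 1
        self.assignments = np.empty(self.n_subjects, dtype=int)
        self.assignments[order] = np.arange(self.n_subjects) % self.n_folds

    def fold(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, val_idx) for fold k."""
        if not 0 <= k < self.n_folds:
            raise ValueError(f"fold index {k} out of range")
        val = np.flatnonzero(self.assignments == k)
        train = np.flatnonzero(self.assignments != k)
        return train, val

    def __iter__(self):
        return (self.fold(k) for k in range(self.n_folds))


@dataclass
class MetricReport:
    """Per-subject metric table plus recomputable aggregates."""

    table: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        """Mean ± population std of every numeric metric column."""
        cols = [c for c in ("dice_raw", "dice_post", "auc") if c in self.table]
        agg = self.table[cols].agg(["mean", lambda s: s.std(ddof=0)])
        agg.index = ["mean", "std"]
        return agg

    def format_summary(self) -> str:
        agg = self.aggregate()
        parts = [
            f"{col}={agg.loc['mean', col]:.3f} ± {agg.loc['std', col]:.2f}"
            for col in agg.columns
        ]
        return ", ".join(parts)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def dice(
    a: BinaryLesionMask | np.ndarray,
    b: BinaryLesionMask | np.ndarray,
    eval_mask: EvaluationMask | None = None,
) -> float:
    """2|A∩B| / (|A|+|B|) over the evaluation mask; both-empty ⇒ 1."""
    av = (a.voxels if isinstance(a, BinaryLesionMask) else np.asarray(a)).astype(bool)
    bv = (b.voxels if isinstance(b, BinaryLesionMask) else np.asarray(b)).astype(bool)
    if av.shape != bv.shape:
        raise ValueError("mask shapes differ")
    if eval_mask is not None:
        av = av & eval_mask.voxels
        bv = bv & eval_mask.voxels
    denom = int(av.sum()) + int(bv.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((av & bv).sum()) / denom


def roc_auc(
    scores: AnomalyMap | np.ndarray,
    groundtruth: BinaryLesionMask | np.ndarray,
    eval_mask: EvaluationMask | None = None,
    subject_id: str = "?",
) -> tuple[np.ndarray, float]:
    """(ROC operating points as (fpr, tpr) array, AUC) over masked voxels."""
    s = scores.scores if isinstance(scores, AnomalyMap) else np.asarray(scores, dtype=float)
    g = (
        groundtruth.voxels
        if isinstance(groundtruth, BinaryLesionMask)
        else np.asarray(groundtruth)
    ).astype(bool)
    keep = np.isfinite(s)
    if eval_mask is not None:
        keep &= eval_mask.voxels
    sv, gv = s[keep].ravel(), g[keep].ravel()
    if not (gv.any() and (~gv).any()):
        raise ValueError(f"subject {subject_id}: groundtruth has a single class")
    fpr, tpr, _ = roc_curve(gv, sv)
    auc = float(roc_auc_score(gv, sv))
    return np.column_stack([fpr, tpr]), auc


def score_density(
    maps: Sequence[AnomalyMap],
    groundtruths: Sequence[BinaryLesionMask | np.ndarray],
    n_bins: int = 50,
) -> dict:
    """Score densities for lesion vs. non-lesion voxels, pooled over subjects.

    Returns bin edges, per-class densities (integrating to 1) and the
    separation statistic (difference of class means).
    """
    if not maps:
        raise ValueError("need at least one subject")
    lesion_vals, healthy_vals = [], []
    for amap, gt in zip(maps, groundtruths):
        g = (gt.voxels if isinstance(gt, BinaryLesionMask) else np.asarray(gt)).astype(bool)
        finite = amap.finite_mask
        lesion_vals.append(amap.scores[finite & g])
        healthy_vals.append(amap.scores[finite & ~g])
    lesion = np.concatenate(lesion_vals)
    healthy = np.concatenate(healthy_vals)
    lo = min(healthy.min(), lesion.min() if lesion.size else np.inf)
    hi = max(healthy.max(), lesion.max() if lesion.size else -np.inf)
    edges = np.linspace(lo, hi if hi > lo else lo + 1.0, n_bins + 1)
    dens_lesion = (
        np.histogram(lesion, bins=edges, density=True)[0] if lesion.size else np.zeros(n_bins)
    )
    dens_healthy = np.histogram(healthy, bins=edges, density=True)[0]
    separation = float(lesion.mean() - healthy.mean()) if lesion.size else 0.0
    return {
        "edges": edges,
        "lesion_density": dens_lesion,
        "healthy_density": dens_healthy,
        "separation": separation,
    }


# ---------------------------------------------------------------------------
# scoring pipeline + cross-validation
# ---------------------------------------------------------------------------

def score_subject(
    estimator,
    vol: DWIVolume,
    groundtruth: BinaryLesionMask | None,
    threshold_method: str = "pooled_max",
    pool_kernel: int = 5,
    normalize_residual: bool = True,
) -> dict:
    """Run the full map → threshold → opening → metrics pipeline for one subject.

    DAE-style estimators (with ``reconstruct``) use the residual map,
    min-max normalized by default; discriminator estimators use their
    probability output raw.
    """
    eval_mask = EvaluationMask.from_tissue_mask(vol.tissue_mask)
    if hasattr(estimator, "reconstruct"):
        model_kind = "dae"
        amap = residual(vol.signal, estimator.reconstruct(vol))
        amap = restrict(amap, eval_mask)
        if normalize_residual:
            amap = normalize_scores(amap)
    else:
        model_kind = "recdisc"
        amap = restrict(estimator.anomaly_map(vol), eval_mask)

    gt_vox = groundtruth.voxels if groundtruth is not None else np.zeros_like(eval_mask.voxels)
    gt_eval = gt_vox & eval_mask.voxels
    threshold = select_threshold(
        threshold_method,
        amap,
        model_kind=model_kind,
        groundtruth=gt_eval if threshold_method in SUPERVISED_METHODS else None,
        kernel=pool_kernel,
    )
    raw = binarize(amap, threshold, eval_mask, method=threshold_method)
    opened = morphological_opening(raw)
    row = {
        "subject": vol.subject_id,
        "model": model_kind,
        "method": threshold_method,
        "threshold": threshold,
        "dice_raw": dice(raw, gt_eval, eval_mask),
        "dice_post": dice(opened, gt_eval, eval_mask),
    }
    if gt_eval.any() and (~gt_eval & eval_mask.voxels).any():
        row["auc"] = roc_auc(amap, gt_vox, eval_mask, subject_id=vol.subject_id)[1]
    else:
        row["auc"] = np.nan
    return row


def crossvalidate(
    cohort: Sequence[DWIVolume],
    make_estimator: Callable[[], object],
    eval_set: Sequence[tuple[DWIVolume, BinaryLesionMask]],
    n_folds: int = 7,
    seed: int = 0,
    threshold_method: str = "pooled_max",
    pool_kernel: int = 5,
) -> MetricReport:
    """k-fold cross-validation: train per fold, score the evaluation set.

    The healthy cohort is split into ``n_folds`` random subsets; each fold
    trains on the rest with its subset as validation (checkpoint selection
    by validation loss), then scores every evaluation subject.  Rows carry
    (fold, subject); aggregates are recomputable from the table.
    """
    cohort = list(cohort)
    split = FoldSplit(n_subjects=len(cohort), n_folds=n_folds, seed=seed)
    rows = []
    for k, (train_idx, val_idx) in enumerate(split):
        if len(train_idx) < 1 or len(val_idx) < 1:
            raise ValueError(f"fold {k} has an empty train or validation set")
        est = make_estimator()
        est.fit([cohort[i] for i in train_idx], validation=[cohort[i] for i in val_idx])
        for vol, gt in eval_set:
            row = score_subject(
                est, vol, gt, threshold_method=threshold_method, pool_kernel=pool_kernel
            )
            row["fold"] = k
            rows.append(row)
    return MetricReport(table=pd.DataFrame(rows))
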