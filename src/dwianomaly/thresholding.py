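"""Threshold selection, binarization and morphological post-processing.

Five strategies are provided.  Unsupervised: a fixed value (0.5 for the
discriminator output, 0.3 for the DAE residual), Otsu's between-class
variance maximization, and the pooled-maximum rule T = max(I ∗ f_local)
where f_local is a cubic local-average kernel (16³ at full scale).
Supervised (requiring groundtruth, for model comparison only): the maximum
of Youden's index J = TPR − FPR, and the threshold maximizing the raw Dice
coefficient.  Binarization is strict (score > T); post-processing is a
morphological opening with a 3×3×3 full-cube structuring element.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .io import AnomalyMap, BinaryLesionMask, EvaluationMask

#: Full-scale defaults
FIXED_THRESHOLDS = {"recdisc": 0.5, "dae": 0.3}
DEFAULT_POOL_KERNEL = 16
OTSU_BINS = 256

SUPERVISED_METHODS = ("youden", "dice_optimal")
UNSUPERVISED_METHODS = ("fixed", "otsu", "pooled_max")


def fixed_threshold(model_kind: str, override: float | None = None) -> float:
    """Pre-defined threshold per model family; an override passes through."""
    if override is not None:
        return float(override)
    try:
        return FIXED_THRESHOLDS[model_kind]
    except KeyError:
        raise ValueError(
            f"unknown model kind {model_kind!r}; expected one of {sorted(FIXED_THRESHOLDS)}"
        ) from None


def _finite_scores(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=np.float64).ravel()
    return scores[np.isfinite(scores)]


def otsu_threshold(scores: np.ndarray, n_bins: int = OTSU_BINS) -> float:
    """Histogram threshold maximizing between-class variance.

    Ties resolve to the lowest qualifying bin edge.  Raises on (near-)
    constant input, where no two classes exist.
    """
    vals = _finite_scores(scores)
    if vals.size < 2 or vals.min() == vals.max():
        raise ValueError("Otsu requires at least two distinct score values")
    counts, edges = np.histogram(vals, bins=n_bins, range=(vals.min(), vals.max()))
    counts = counts.astype(np.float64)
    total = counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    s0 = np.cumsum(counts * centers)[:-1]
    mu0 = np.where(w0 > 0, s0 / np.maximum(w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (s0[-1] + counts[-1] * centers[-1] - s0) / np.maximum(w1, 1), 0.0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise ValueError("Otsu failed: all mass in a single bin")
    between[~valid] = -np.inf
    best = int(np.argmax(between))  # argmax returns the first (lowest) tie
    return float(edges[best + 1])


def pooled_max_threshold(amap: AnomalyMap | np.ndarray, kernel: int = DEFAULT_POOL_KERNEL) -> float:
    """T = max(I ∗ f_local): maximum of the k³ local average, valid windows only.

    NaN voxels (outside the evaluation mask) count as zero signal, as in
    pooling a masked output image.
    """
    scores = amap.scores if isinstance(amap, AnomalyMap) else np.asarray(amap, dtype=np.float64)
    if any(s < kernel for s in scores.shape):
        raise ValueError(
            f"map extent {scores.shape} smaller than pooling kernel {kernel}"
        )
    filled = np.nan_to_num(scores, nan=0.0)
    # integral-image box sums: exact k³ window means at every valid position
    pad = np.zeros(tuple(s + 1 for s in filled.shape))
    pad[1:, 1:, 1:] = filled
    s = pad.cumsum(axis=0).cumsum(axis=1).cumsum(axis=2)
    k = kernel
    box = (
        s[k:, k:, k:] - s[:-k, k:, k:] - s[k:, :-k, k:] - s[k:, k:, :-k]
        + s[:-k, :-k, k:] + s[:-k, k:, :-k] + s[k:, :-k, :-k] - s[:-k, :-k, :-k]
    )
    return float(box.max() / k**3)


def _roc_candidates(scores: np.ndarray, groundtruth: np.ndarray, max_exact: int = 10**5,
                    grid: int = 512) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Candidate thresholds (midpoints between unique scores) with TPR/FPR.

    Uses every unique value below ``max_exact`` voxels, else a quantile grid.
    Candidates are midpoints so that the strict ``score > T`` binarization
    separates adjacent score values cleanly.
    """
    finite = np.isfinite(scores)
    s = scores[finite].ravel()
    g = np.asarray(groundtruth, dtype=bool).ravel()[finite.ravel()]
    if not (g.any() and (~g).any()):
        raise ValueError("groundtruth must contain both classes")
    uniq = np.unique(s)
    if uniq.size > max_exact:
        qs = np.quantile(s, np.linspace(0, 1, grid))
        uniq = np.unique(qs)
    # thresholds: below the minimum, between consecutive values
    cand = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0])
    pos, neg = g.sum(), (~g).sum()
    order = np.argsort(s, kind="stable")
    s_sorted, g_sorted = s[order], g[order]
    # for each candidate T: predictions are s > T
    idx = np.searchsorted(s_sorted, cand, side="right")
    cum_pos = np.concatenate([[0], np.cumsum(g_sorted)])
    tp = pos - cum_pos[idx]
    fp = neg - (idx - cum_pos[idx])
    return cand, tp / pos, fp / neg


def youden_threshold(scores: np.ndarray, groundtruth: np.ndarray) -> float:
    """Threshold maximizing Youden's J = TPR − FPR; ties → lower threshold."""
    cand, tpr, fpr = _roc_candidates(np.asarray(scores, dtype=np.float64), groundtruth)
    j = tpr - fpr
    best = np.flatnonzero(j >= j.max() - 1e-12)
    return float(cand[best.min()])


def dice_optimal_threshold(scores: np.ndarray, groundtruth: np.ndarray) -> tuple[float, float]:
    """Threshold maximizing the raw (unpostprocessed) Dice; returns (T, Dice)."""
    scores = np.asarray(scores, dtype=np.float64)
    finite = np.isfinite(scores)
    s = scores[finite].ravel()
    g = np.asarray(groundtruth, dtype=bool).ravel()[finite.ravel()]
    if not (g.any() and (~g).any()):
        raise ValueError("groundtruth must contain both classes")
    cand, tpr, fpr = _roc_candidates(scores, groundtruth)
    pos, neg = g.sum(), (~g).sum()
    tp = tpr * pos
    fp = fpr * neg
    pred = tp + fp
    dice = 2.0 * tp / np.maximum(pred + pos, 1e-300)
    best = np.flatnonzero(dice >= dice.max() - 1e-12)
    k = best.min()
    return float(cand[k]), float(dice[k])


def binarize(
    amap: AnomalyMap,
    threshold: float,
    eval_mask: EvaluationMask | None = None,
    method: str = "fixed",
) -> BinaryLesionMask:
    """Voxel true iff score > T; false at NaN and outside the evaluation mask."""
    with np.errstate(invalid="ignore"):
        voxels = amap.scores > threshold
    voxels &= np.isfinite(amap.scores)
    if eval_mask is not None:
        voxels &= eval_mask.voxels
    return BinaryLesionMask(
        voxels=voxels, threshold_method=method, threshold_value=float(threshold)
    )


#: 3×3×3 full-cube structuring element used for post-processing
OPENING_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


def morphological_opening(mask: BinaryLesionMask) -> BinaryLesionMask:
    """Erosion then dilation with the 3³ cube; removes sub-kernel specks."""
    opened = ndimage.binary_opening(mask.voxels, structure=OPENING_STRUCTURE)
    return BinaryLesionMask(
        voxels=opened,
        threshold_method=mask.threshold_method,
        threshold_value=mask.threshold_value,
        postprocessed=True,
    )


def select_threshold(
    method: str,
    amap: AnomalyMap,
    model_kind: str = "dae",
    groundtruth: np.ndarray | None = None,
    kernel: int = DEFAULT_POOL_KERNEL,
    n_bins: int = OTSU_BINS,
    fixed_value: float | None = None,
) -> float:
    """Dispatch over the five strategies (supervised ones need groundtruth)."""
    if method == "fixed":
        return fixed_threshold(model_kind, override=fixed_value)
    if method == "otsu":
        return otsu_threshold(amap.scores, n_bins=n_bins)
    if method == "pooled_max":
        return pooled_max_threshold(amap, kernel=kernel)
    if method in SUPERVISED_METHODS:
        if groundtruth is None:
            raise ValueError(f"{method} is supervised and requires a groundtruth mask")
        if method == "youden":
            return youden_threshold(amap.scores, groundtruth)
        return dice_optimal_threshold(amap.scores, groundtruth)[0]
    raise ValueError(f"unknown threshold method {method!r}")
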