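"""Turning model outputs into anomaly maps.

The DAE residual is computed per voxel as the absolute value of the
channel-summed signed residual, |Σ_c (output − input)| — summing before
taking the absolute value lets independent per-channel noise cancel while a
consistent signed deviation (the lesion signature) accumulates.  Maps can be
restricted to an evaluation mask (excluded voxels become NaN and never enter
thresholds or metrics) and min-max normalized so fixed thresholds are
comparable across subjects.
"""

from __future__ import annotations

import numpy as np

from .io import AnomalyMap, EvaluationMask


def residual(input_signal: np.ndarray, output_signal: np.ndarray) -> AnomalyMap:
    """|Σ_c (output − input)| per voxel: channel-summed, then absolute value."""
    input_signal = np.asarray(input_signal, dtype=np.float64)
    output_signal = np.asarray(output_signal, dtype=np.float64)
    if input_signal.shape != output_signal.shape:
        raise ValueError(
            f"shape mismatch: input {input_signal.shape} vs output {output_signal.shape}"
        )
    if input_signal.ndim != 4:
        raise ValueError("expected 4D (X, Y, Z, C) arrays")
    scores = np.abs((output_signal - input_signal).sum(axis=3))
    return AnomalyMap(scores=scores, score_range=(0.0, np.inf), source_model="dae-residual")


def restrict(amap: AnomalyMap, mask: EvaluationMask) -> AnomalyMap:
    """NaN out every voxel outside the evaluation mask (idempotent)."""
    if mask.voxels.shape != amap.scores.shape:
        raise ValueError("evaluation mask shape does not match map")
    if not mask.voxels.any():
        raise ValueError("evaluation mask is empty")
    scores = np.where(mask.voxels, amap.scores, np.nan)
    return AnomalyMap(scores=scores, score_range=amap.score_range,
                      source_model=amap.source_model)


def normalize_scores(amap: AnomalyMap) -> AnomalyMap:
    """Min-max rescale the finite scores to [0, 1] (order-preserving)."""
    finite = amap.finite_mask
    vals = amap.scores[finite]
    if vals.size == 0:
        raise ValueError("no finite scores to normalize")
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise ValueError("constant map cannot be min-max normalized")
    scores = amap.scores.copy()
    scores[finite] = (vals - lo) / (hi - lo)
    return AnomalyMap(
        scores=scores,
        score_range=(0.0, 1.0),
        source_model=amap.source_model + "+minmax",
    )
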