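"""Reading, writing and validation of diffusion-MRI artifacts.

All computation in this package happens in voxel space with 0-based indices
and channel-last ``(X, Y, Z, C)`` arrays; the NIfTI affine is carried along
for round-tripping but never interpreted.  Gradient tables follow the FSL
convention: a ``.bval`` file with one b-value per channel and a ``.bvec``
file with three rows (x, y, z components).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger("dwianomaly")

# Tissue labels used throughout the package.
BACKGROUND, WM, GM, CSF = 0, 1, 2, 3

#: b-values at or below this (s/mm²) count as unweighted (b≈0) channels.
B0_THRESHOLD = 50.0


class FormatError(ValueError):
    """Structural problem with an on-disk artifact (shape / length mismatch)."""


class DataError(ValueError):
    """Values in an artifact violate the data contract (e.g. non-finite)."""


@dataclass
class DWIVolume:
    """A 4D diffusion-weighted volume with its gradient table and tissue mask.

    ``signal`` holds dimensionless diffusion attenuation, shape (X, Y, Z, C).
    After :func:`normalize_attenuation` all values lie in [0, 1] and the b≈0
    channel has been consumed.  ``tissue_mask`` is a 3D label grid using
    the module-level ``BACKGROUND/WM/GM/CSF`` labels.
    """

    signal: np.ndarray
    voxel_size: tuple[float, float, float]
    bvals: np.ndarray
    bvecs: np.ndarray
    tissue_mask: np.ndarray
    subject_id: str = "unknown"
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    normalized: bool = False

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.bvals = np.asarray(self.bvals, dtype=np.float64).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=np.float64)
        self.tissue_mask = np.asarray(self.tissue_mask)
        self.validate()

    def validate(self) -> None:
        if self.signal.ndim != 4:
            raise FormatError(f"signal must be 4D (X,Y,Z,C), got ndim={self.signal.ndim}")
        n_chan = self.signal.shape[3]
        if self.bvals.shape[0] != n_chan:
            raise FormatError(
                f"channel axis mismatch: image has {n_chan} channels "
                f"but bval file lists {self.bvals.shape[0]} entries"
            )
        if self.bvecs.shape != (n_chan, 3):
            raise FormatError(
                f"bvec table must have shape ({n_chan}, 3), got {self.bvecs.shape}"
            )
        if self.tissue_mask.shape != self.signal.shape[:3]:
            raise FormatError(
                f"tissue mask shape {self.tissue_mask.shape} does not match "
                f"image spatial shape {self.signal.shape[:3]}"
            )
        bad = ~np.isfinite(self.signal)
        if bad.any():
            raise DataError(f"signal contains {int(bad.sum())} non-finite voxel values")
        weighted = self.bvals > B0_THRESHOLD
        norms = np.linalg.norm(self.bvecs[weighted], axis=1)
        if weighted.any() and not np.allclose(norms, 1.0, atol=1e-3):
            raise DataError("bvec rows must have unit norm where b > 0")
        if self.normalized and (self.signal.min() < 0 or self.signal.max() > 1 + 1e-9):
            raise DataError("normalized signal must lie in [0, 1]")

    # -- convenience views -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.signal.shape

    @property
    def brain_mask(self) -> np.ndarray:
        """Boolean grid of all in-brain voxels (WM ∪ GM ∪ CSF)."""
        return self.tissue_mask != BACKGROUND

    @property
    def b0_channels(self) -> np.ndarray:
        return np.flatnonzero(self.bvals <= B0_THRESHOLD)

    @property
    def has_b0(self) -> bool:
        return self.b0_channels.size > 0


@dataclass
class EvaluationMask:
    """Boolean grid of voxels eligible for scoring: white and gray matter only.

    CSF/ventricles and background are always excluded so that trivially
    anomalous free-water regions cannot inflate the metrics.
    """

    voxels: np.ndarray
    derivation: str = "tissue_mask in {WM, GM}"

    @classmethod
    def from_tissue_mask(cls, tissue_mask: np.ndarray) -> "EvaluationMask":
        tissue_mask = np.asarray(tissue_mask)
        return cls(voxels=np.isin(tissue_mask, (WM, GM)))

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class AnomalyMap:
    """Per-voxel anomaly scores on a 3D grid.

    ``scores`` may contain NaN at voxels excluded by :func:`~dwianomaly.maps.restrict`;
    NaN voxels never enter thresholds or metrics.  ``score_range`` declares the
    semantics: ``(0, inf)`` for residual maps, ``(0, 1)`` for discriminator output.
    """

    scores: np.ndarray
    score_range: tuple[float, float] = (0.0, np.inf)
    source_model: str = "unknown"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 3:
            raise FormatError("anomaly map must be 3D")
        finite = self.scores[np.isfinite(self.scores)]
        if finite.size and finite.min() < -1e-12:
            raise DataError("anomaly scores must be non-negative")
        if self.score_range[1] == 1.0 and finite.size and finite.max() > 1 + 1e-9:
            raise DataError("scores exceed declared [0, 1] range")

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.scores)


@dataclass
class BinaryLesionMask:
    """A thresholded segmentation with its provenance."""

    voxels: np.ndarray
    threshold_method: str = "unknown"
    threshold_value: float = float("nan")
    postprocessed: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise FormatError("lesion mask must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_gradient_table(path_bval, path_bvec) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-style .bval (one row) and .bvec (three rows) text files."""
    bvals = np.loadtxt(path_bval, ndmin=1, dtype=np.float64).ravel()
    bvecs = np.loadtxt(path_bvec, ndmin=2, dtype=np.float64)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous 3x3: FSL convention stores one column per channel
        bvecs = bvecs.T
    if bvecs.shape[1] != 3:
        raise FormatError(f"bvec file must have 3 rows (FSL convention), got shape {bvecs.shape}")
    if bvals.shape[0] != bvecs.shape[0]:
        raise FormatError(
            f"gradient table length mismatch: {bvals.shape[0]} b-values "
            f"vs {bvecs.shape[0]} directions"
        )
    return bvals, bvecs


def write_gradient_table(bvals, bvecs, path_bval, path_bvec) -> None:
    np.savetxt(path_bval, np.asarray(bvals)[None], fmt="%.1f")
    np.savetxt(path_bvec, np.asarray(bvecs).T, fmt="%.8f")


def read_dwi(path_image, path_bval, path_bvec, path_mask, subject_id: str | None = None) -> DWIVolume:
    """Load a 4D NIfTI volume, its FSL gradient table and a tissue-label mask.

    Raises :class:`FormatError` on any shape/length mismatch (naming the
    offending axis) and :class:`DataError` on non-finite voxels.
    """
    img = nib.load(str(path_image))
    signal = np.asarray(img.dataobj, dtype=np.float64)
    if signal.ndim != 4:
        raise FormatError(f"expected a 4D image, got ndim={signal.ndim}")
    bvals, bvecs = read_gradient_table(path_bval, path_bvec)
    mask_img = nib.load(str(path_mask))
    tissue_mask = np.asarray(mask_img.dataobj).astype(np.int16)
    zooms = img.header.get_zooms()[:3]
    vol = DWIVolume(
        signal=signal,
        voxel_size=tuple(float(z) for z in zooms),
        bvals=bvals,
        bvecs=bvecs,
        tissue_mask=tissue_mask,
        subject_id=subject_id or Path(str(path_image)).name.split(".")[0],
        affine=np.asarray(img.affine),
    )
    logger.info(
        "read_dwi subject=%s shape=%s b0_channels=%d",
        vol.subject_id, vol.shape, vol.b0_channels.size,
    )
    return vol


def write_dwi(vol: DWIVolume, path_image, path_bval, path_bvec, path_mask) -> None:
    nib.save(nib.Nifti1Image(vol.signal.astype(np.float32), vol.affine), str(path_image))
    write_gradient_table(vol.bvals, vol.bvecs, path_bval, path_bvec)
    nib.save(nib.Nifti1Image(vol.tissue_mask.astype(np.int16), vol.affine), str(path_mask))


def normalize_attenuation(vol: DWIVolume, mode: str = "auto") -> DWIVolume:
    """Map the signal to [0, 1] attenuation, consuming any b≈0 channels.

    mode="b0-ratio" divides each diffusion-weighted channel by the (mean) b≈0
    channel inside the brain mask and clips to [0, 1]; this is the physical
    attenuation S/S0.  mode="global-max" divides by the per-volume maximum
    inside the brain mask.  mode="auto" picks b0-ratio when a b≈0 channel
    exists, else global-max.  Outside the brain mask the signal is zeroed.
    """
    if mode == "auto":
        mode = "b0-ratio" if vol.has_b0 else "global-max"
    brain = vol.brain_mask
    dw = vol.bvals > B0_THRESHOLD
    sig = vol.signal[..., dw].copy()

    if mode == "b0-ratio":
        if not vol.has_b0:
            raise FormatError("b0-ratio normalization requires a b≈0 channel")
        b0 = vol.signal[..., vol.b0_channels].mean(axis=3)
        n_zero = int(((b0 <= 0) & brain).sum())
        if n_zero:
            logger.warning("normalize: %d zero-valued b0 voxels inside mask (clipped)", n_zero)
        with np.errstate(divide="ignore", invalid="ignore"):
            sig = sig / b0[..., None]
        sig[~np.isfinite(sig)] = 0.0
    elif mode == "global-max":
        peak = sig[brain].max() if brain.any() else sig.max()
        if peak <= 0:
            raise DataError("cannot normalize: non-positive maximum inside brain mask")
        sig = sig / peak
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")

    sig = np.clip(sig, 0.0, 1.0)
    sig[~brain] = 0.0
    return replace(
        vol,
        signal=sig,
        bvals=vol.bvals[dw],
        bvecs=vol.bvecs[dw],
        normalized=True,
    )


def _check_reference(arr: np.ndarray, reference: DWIVolume) -> None:
    if arr.shape != reference.signal.shape[:3]:
        raise FormatError(
            f"spatial shape {arr.shape} does not match reference {reference.signal.shape[:3]}"
        )


def write_map(amap: AnomalyMap, reference: DWIVolume, path) -> None:
    """Write an anomaly map as float32 NIfTI in the reference geometry."""
    _check_reference(amap.scores, reference)
    nib.save(nib.Nifti1Image(amap.scores.astype(np.float32), reference.affine), str(path))


def read_map(path, score_range=(0.0, np.inf), source_model="file") -> AnomalyMap:
    img = nib.load(str(path))
    return AnomalyMap(
        scores=np.asarray(img.dataobj, dtype=np.float64),
        score_range=score_range,
        source_model=source_model,
    )


def write_mask(mask: BinaryLesionMask, reference: DWIVolume, path) -> None:
    """Write a binary mask as {0,1} integers in the reference geometry."""
    _check_reference(mask.voxels, reference)
    nib.save(
        nib.Nifti1Image(mask.voxels.astype(np.uint8), reference.affine), str(path)
    )


def read_mask(path) -> BinaryLesionMask:
    img = nib.load(str(path))
    return BinaryLesionMask(voxels=np.asarray(img.dataobj) > 0)
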