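"""Synthetic diffusion-MRI phantom: healthy and lesioned test objects.

The phantom emulates the statistical structure the anomaly models assume:
a multi-channel diffusion-attenuated signal in [0, 1] generated from a
single-tensor model S(v, i) = S0 · exp(−b · gᵢᵀ D(v) gᵢ), with
tissue-dependent tensors (anisotropic white matter whose principal direction
follows concentric-shell tangents, isotropic gray matter and CSF), Rician
magnitude noise, and optional tumor-like lesions realised as ellipsoids with
multiplied mean diffusivity and scaled fractional anisotropy.

Units: b-values in s/mm², diffusivities in mm²/s, geometry in voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import BACKGROUND, CSF, GM, WM, BinaryLesionMask, DWIVolume, normalize_attenuation

# Default per-tissue tensor parameters: mean diffusivity (mm²/s), fractional
# anisotropy.  Values are in the range reported for healthy adult brain.
DEFAULT_TENSORS: dict[int, tuple[float, float]] = {
    WM: (0.75e-3, 0.65),
    GM: (0.85e-3, 0.0),
    CSF: (3.0e-3, 0.0),
}

# Nested-ellipsoid geometry as semi-axis fractions of the grid dimensions:
# brain envelope, white-matter core, central ventricle (CSF).
DEFAULT_GEOMETRY: dict[str, tuple[float, float, float]] = {
    "brain": (0.44, 0.44, 0.42),
    "wm_core": (0.34, 0.34, 0.32),
    "ventricle": (0.12, 0.07, 0.10),
}


@dataclass
class LesionSpec:
    """An ellipsoidal lesion with altered diffusivity.

    ``md_multiplier`` > 1 raises mean diffusivity (edema-like signal drop in
    the attenuation images); ``fa_multiplier`` < 1 reduces anisotropy
    (fiber disruption).  Geometry is in voxel units; ``rotation`` is a
    z–y–z Euler triple in radians.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    md_multiplier: float = 1.8
    fa_multiplier: float = 0.3

    def __post_init__(self) -> None:
        if self.md_multiplier <= 0 or self.fa_multiplier <= 0:
            raise ValueError("lesion multipliers must be positive")


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (32, 32, 20)
    n_channels: int = 8
    bval: float = 1000.0
    tissue_geometry: dict = field(default_factory=lambda: dict(DEFAULT_GEOMETRY))
    tensor_params: dict = field(default_factory=lambda: dict(DEFAULT_TENSORS))
    noise_sigma: float = 0.02
    lesion: LesionSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 16:
            raise ValueError("grid_shape components must be >= 16")
        if self.n_channels < 6:
            raise ValueError("n_channels must be >= 6")
        for label, (md, fa) in self.tensor_params.items():
            if md <= 0:
                raise ValueError(f"diffusivity for label {label} must be positive")
            if not 0 <= fa < 1:
                raise ValueError(f"FA for label {label} must lie in [0, 1)")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def rotation_matrix(angles: Sequence[float]) -> np.ndarray:
    """z-y-z Euler rotation matrix."""
    a, b, c = angles
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
    ry = np.array([[cb, 0, sb], [0, 1.0, 0], [-sb, 0, cb]])
    rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1.0]])
    return rz1 @ ry @ rz2


def ellipsoid_mask(
    grid_shape: Sequence[int],
    center: Sequence[float],
    semi_axes: Sequence[float],
    rotation: Sequence[float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Boolean grid: voxel inside iff the rotated quadratic form is <= 1."""
    idx = np.indices(grid_shape, dtype=np.float64)
    rel = idx - np.asarray(center, dtype=np.float64)[:, None, None, None]
    rot = rotation_matrix(rotation)
    # body-frame coordinates: R^T (x - c)
    body = np.einsum("ji,jxyz->ixyz", rot, rel)
    q = sum((body[i] / semi_axes[i]) ** 2 for i in range(3))
    return q <= 1.0


def axially_symmetric_eigenvalues(md: float, fa: float) -> tuple[float, float]:
    """Eigenvalues (axial, radial) of a prolate tensor with given MD and FA.

    Solves λ1 + 2λ2 = 3·MD and FA = (λ1 − λ2)/sqrt(λ1² + 2λ2²) in closed form.
    """
    if fa == 0:
        return md, md
    # with d = λ1 − λ2 and s = λ1 + 2λ2: FA²(s² + 2d²)/3 = d² ⇒ d = FA·s/sqrt(3 − 2FA²)
    s = 3.0 * md
    d = fa * s / np.sqrt(3.0 - 2.0 * fa * fa)
    lam1 = (s + 2.0 * d) / 3.0
    lam2 = (s - d) / 3.0
    if lam2 <= 0:
        raise ValueError(f"FA={fa} with MD={md} yields non-positive radial eigenvalue")
    return float(lam1), float(lam2)


# ---------------------------------------------------------------------------
# gradient table
# ---------------------------------------------------------------------------

def make_gradient_table(
    n_channels: int, bval: float = 1000.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """One b≈0 entry plus ``n_channels`` quasi-uniform unit directions.

    Directions are laid out with a spherical Fibonacci spiral restricted to
    the upper hemisphere, so no two directions are antipodal (diffusion is
    symmetric under g → −g, antipodal pairs would be redundant).  A small
    seeded random rotation decorrelates tables across subjects.
    """
    if n_channels < 6:
        raise ValueError("n_channels must be >= 6")
    i = np.arange(n_channels, dtype=np.float64)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    # upper hemisphere: z from ~1/n to ~1 (excludes equatorial antipodes)
    z = (i + 0.5) / n_channels
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(1.0 - z * z)
    dirs = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    rng = np.random.default_rng(seed)
    angles = rng.uniform(0, 2 * np.pi, size=3)
    dirs = dirs @ rotation_matrix(angles).T
    bvals = np.concatenate([[0.0], np.full(n_channels, float(bval))])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dirs])
    return bvals, bvecs


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _tissue_labels(config: PhantomConfig) -> np.ndarray:
    shape = np.asarray(config.grid_shape, dtype=np.float64)
    center = (shape - 1) / 2.0
    geo = config.tissue_geometry
    brain = ellipsoid_mask(config.grid_shape, center, shape * geo["brain"])
    core = ellipsoid_mask(config.grid_shape, center, shape * geo["wm_core"])
    vent = ellipsoid_mask(config.grid_shape, center, shape * geo["ventricle"])
    labels = np.full(config.grid_shape, BACKGROUND, dtype=np.int16)
    labels[brain] = GM
    labels[core] = WM
    labels[vent] = CSF
    return labels


def _principal_directions(grid_shape: Sequence[int]) -> np.ndarray:
    """Smooth WM fiber-direction field: tangents to concentric shells.

    At voxel v the direction is ẑ × r̂ projected in-plane (a circular
    fiber bundle around the phantom axis); degenerate on-axis voxels
    fall back to x̂.
    """
    shape = np.asarray(grid_shape, dtype=np.float64)
    center = (shape - 1) / 2.0
    idx = np.indices(grid_shape, dtype=np.float64)
    rel = idx - center[:, None, None, None]
    tang = np.stack([-rel[1], rel[0], np.zeros_like(rel[0])], axis=-1)
    norm = np.linalg.norm(tang, axis=-1, keepdims=True)
    small = norm[..., 0] < 1e-9
    tang[small] = (1.0, 0.0, 0.0)
    norm[norm < 1e-9] = 1.0
    return tang / norm


def tensor_attenuation(
    bvecs_dw: np.ndarray,
    bval: float,
    md: np.ndarray,
    fa: np.ndarray,
    principal: np.ndarray,
) -> np.ndarray:
    """Noiseless attenuation exp(−b gᵀDg) for axially symmetric tensors.

    gᵀDg = λ_radial + (λ_axial − λ_radial)(g·p)², evaluated per voxel and
    direction. ``md``/``fa`` are 3D fields, ``principal`` is (X,Y,Z,3).
    """
    md = np.asarray(md, dtype=np.float64)
    fa = np.asarray(fa, dtype=np.float64)
    s = 3.0 * md
    d = fa * s / np.sqrt(3.0 - 2.0 * fa * fa)
    lam_ax = (s + 2.0 * d) / 3.0
    lam_rad = (s - d) / 3.0
    cos = np.einsum("xyzi,ci->xyzc", principal, bvecs_dw)
    adc = lam_rad[..., None] + (lam_ax - lam_rad)[..., None] * cos**2
    return np.exp(-bval * adc)


def simulate_dwi(
    config: PhantomConfig, normalize: bool = True
) -> tuple[DWIVolume, BinaryLesionMask | None]:
    """Generate one phantom subject.

    Returns the (optionally normalized) volume together with the voxelwise
    lesion groundtruth, or ``None`` in the groundtruth slot for healthy
    phantoms.  Same config (incl. seed) always yields the identical volume.
    """
    rng = np.random.default_rng(config.seed)
    labels = _tissue_labels(config)
    bvals, bvecs = make_gradient_table(config.n_channels, config.bval, seed=config.seed)

    md = np.zeros(config.grid_shape)
    fa = np.zeros(config.grid_shape)
    for label, (md_t, fa_t) in config.tensor_params.items():
        md[labels == label] = md_t
        fa[labels == label] = fa_t

    groundtruth = None
    if config.lesion is not None:
        les = config.lesion
        lesion_vox = ellipsoid_mask(config.grid_shape, les.center, les.semi_axes, les.rotation)
        brain = labels != BACKGROUND
        if not lesion_vox.any() or not brain[tuple(np.round(les.center).astype(int))]:
            raise ValueError("lesion center must lie inside the brain label region")
        lesion_vox &= brain
        new_fa = np.clip(fa[lesion_vox] * les.fa_multiplier, 0.0, 0.99)
        md[lesion_vox] = md[lesion_vox] * les.md_multiplier
        fa[lesion_vox] = new_fa
        groundtruth = BinaryLesionMask(
            voxels=lesion_vox, threshold_method="simulation", threshold_value=0.0
        )

    principal = _principal_directions(config.grid_shape)
    atten = tensor_attenuation(bvecs[1:], config.bval, md, fa, principal)

    s0 = 1.0
    signal = np.concatenate(
        [np.full(config.grid_shape + (1,), s0), s0 * atten], axis=3
    )
    signal[labels == BACKGROUND] = 0.0

    if config.noise_sigma > 0:
        # Rician magnitude noise: |S + n1 + i·n2|, n ~ N(0, σ²)
        n1 = rng.normal(0.0, config.noise_sigma, size=signal.shape)
        n2 = rng.normal(0.0, config.noise_sigma, size=signal.shape)
        brain4 = (labels != BACKGROUND)[..., None]
        signal = np.where(brain4, np.sqrt((signal + n1) ** 2 + n2**2), signal)

    vol = DWIVolume(
        signal=signal,
        voxel_size=(2.4, 2.4, 2.4),
        bvals=bvals,
        bvecs=bvecs,
        tissue_mask=labels,
        subject_id=f"phantom-{config.seed}",
    )
    if normalize:
        vol = normalize_attenuation(vol, mode="b0-ratio")
    return vol, groundtruth


def random_lesion_spec(config: PhantomConfig, rng: np.random.Generator) -> LesionSpec:
    """Draw a lesion centered in the white-matter core with random geometry."""
    labels = _tissue_labels(config)
    wm_idx = np.argwhere(labels == WM)
    center = tuple(float(c) for c in wm_idx[rng.integers(len(wm_idx))])
    scale = min(config.grid_shape) / 32.0
    semi = tuple(float(a) for a in rng.uniform(3.0, 6.0, size=3) * scale)
    rot = (
        rng.uniform(0, 2 * np.pi),
        np.arccos(rng.uniform(-1, 1)),
        rng.uniform(0, 2 * np.pi),
    )
    return LesionSpec(
        center=center,
        semi_axes=semi,
        rotation=rot,
        md_multiplier=float(rng.uniform(1.6, 2.4)),
        fa_multiplier=float(rng.uniform(0.2, 0.5)),
    )


def make_cohort(
    n_subjects: int,
    config_template: PhantomConfig | None = None,
    seed: int = 0,
    lesioned: bool = False,
    geometry_jitter: float = 0.05,
    noise_jitter: float = 0.2,
) -> list[tuple[DWIVolume, BinaryLesionMask | None]]:
    """Simulate a cohort with per-subject jitter of geometry and noise level.

    Healthy cohorts (``lesioned=False``) emulate a control group for model
    training; lesioned cohorts add one random lesion per subject and return
    its groundtruth mask.  Deterministic under ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    template = config_template or PhantomConfig()
    subjects = []
    seeds = np.random.SeedSequence(seed).spawn(n_subjects)
    for k, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        geo = {
            name: tuple(np.asarray(ax) * (1.0 + rng.uniform(-geometry_jitter, geometry_jitter, 3)))
            for name, ax in template.tissue_geometry.items()
        }
        sigma = template.noise_sigma * (1.0 + rng.uniform(-noise_jitter, noise_jitter))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cfg = replace(
            template,
            tissue_geometry=geo,
            noise_sigma=float(sigma),
            lesion=None,
            seed=sub_seed,
        )
        if lesioned:
            cfg = replace(cfg, lesion=random_lesion_spec(cfg, rng))
        vol, gt = simulate_dwi(cfg)
        vol.subject_id = f"subj-{seed}-{k:03d}" + ("-lesion" if lesioned else "")
        subjects.append((vol, gt))
    return subjects
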