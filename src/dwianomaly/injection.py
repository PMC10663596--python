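"""Synthetic out-of-distribution corruption of healthy volumes.

Healthy diffusion volumes are "inpainted" with ellipsoidal noise patches so
a discrimination network can be trained on an artificial but perfectly known
groundtruth — no real lesion labels, and deliberately no attempt to imitate
tumor texture.  Per volume the number of patches is 0, 1 or 2 with
probabilities 0.2 / 0.6 / 0.2.  Patch values are drawn from a normal or a
uniform distribution parameterised by the mean and standard deviation of
in-brain signal (the mean optionally halved), with one of three spatial
structures:

random       independent per voxel and channel
directional  one draw per channel, constant over space (channel-specific)
isotropic    one draw per voxel, constant over channels

The same spatial support is applied to every channel, and corrupted values
are clipped to [0, 1] so they stay inside the models' input range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GM, WM, DWIVolume
from .phantom import ellipsoid_mask

FAMILIES = ("normal", "uniform")
MEAN_MODES = ("full", "half")
STRUCTURES = ("random", "directional", "isotropic")

#: patch-count distribution: P(0 patches), P(1), P(2)
PATCH_COUNT_PROBS = (0.2, 0.6, 0.2)


@dataclass(frozen=True)
class NoiseSpec:
    """Corruption recipe; any field may be "mix" to resolve randomly per patch."""

    family: str = "mix"
    mean_mode: str = "half"
    structure: str = "mix"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES + ("mix",):
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.mean_mode not in MEAN_MODES + ("mix",):
            raise ValueError(f"unknown mean mode {self.mean_mode!r}")
        if self.structure not in STRUCTURES + ("mix",):
            raise ValueError(f"unknown structure {self.structure!r}")

    def resolve(self, rng: np.random.Generator) -> "NoiseSpec":
        """Replace every "mix" entry with a concrete uniformly drawn choice."""
        return NoiseSpec(
            family=self.family if self.family != "mix" else FAMILIES[rng.integers(2)],
            mean_mode=self.mean_mode if self.mean_mode != "mix" else MEAN_MODES[rng.integers(2)],
            structure=self.structure
            if self.structure != "mix"
            else STRUCTURES[rng.integers(3)],
        )

    @property
    def concrete(self) -> bool:
        return "mix" not in (self.family, self.mean_mode, self.structure)


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    rotation: tuple[float, float, float]


@dataclass
class PatchPlan:
    n_patches: int
    patches: list[tuple[Ellipsoid, NoiseSpec]] = field(default_factory=list)


@dataclass
class CorruptedVolume:
    """A corrupted copy of a subject plus the voxelwise artificial groundtruth."""

    signal: np.ndarray
    artificial_groundtruth: np.ndarray
    plan: PatchPlan
    source: DWIVolume

    @property
    def n_corrupted_voxels(self) -> int:
        return int(self.artificial_groundtruth.sum())


def brain_statistics(vol: DWIVolume, include_csf: bool = True) -> tuple[float, float]:
    """Mean and (population) std of all in-brain signal values, pooled over channels."""
    mask = vol.brain_mask if include_csf else np.isin(vol.tissue_mask, (WM, GM))
    if not mask.any():
        raise ValueError("brain mask is empty")
    values = vol.signal[mask]
    return float(values.mean()), float(values.std())


def sample_noise_block(
    shape: tuple[int, int],
    spec: NoiseSpec,
    mu: float,
    sigma: float,
    rng: np.random.Generator,
    clip: bool = True,
    uniform_halfwidth: bool = True,
) -> np.ndarray:
    """Sample a (n_voxels, n_channels) noise block for one patch.

    The location parameter is ``mu`` (mean_mode="full") or ``mu/2`` ("half").
    The normal family uses scale ``sigma``; the uniform family spans a range
    equal to ``sigma`` around the location (total width sigma, i.e.
    m ± sigma/2) — set ``uniform_halfwidth=False`` for m ± sigma instead.
    Spatial structure decides the broadcast pattern (see module docstring).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if not spec.concrete:
        spec = spec.resolve(rng)
    n_vox, n_chan = shape
    m = mu if spec.mean_mode == "full" else mu / 2.0

    if spec.structure == "random":
        draw_shape: tuple[int, ...] = (n_vox, n_chan)
    elif spec.structure == "directional":
        draw_shape = (1, n_chan)
    else:  # isotropic
        draw_shape = (n_vox, 1)

    if spec.family == "normal":
        values = rng.normal(m, sigma, size=draw_shape)
    else:
        half = sigma / 2.0 if uniform_halfwidth else sigma
        values = rng.uniform(m - half, m + half, size=draw_shape)

    values = np.broadcast_to(values, (n_vox, n_chan)).copy()
    if clip:
        np.clip(values, 0.0, 1.0, out=values)
    return values


def _draw_ellipsoid(
    brain_idx: np.ndarray,
    size_range: tuple[float, float],
    rng: np.random.Generator,
) -> Ellipsoid:
    center = tuple(float(c) for c in brain_idx[rng.integers(len(brain_idx))])
    semi = rng.uniform(*size_range, size=3)
    # uniform over SO(3) for an axis-aligned ellipsoid: z-y-z Euler angles
    # with the middle angle drawn via cos β ~ U(−1, 1)
    rot = (
        rng.uniform(0, 2 * np.pi),
        np.arccos(rng.uniform(-1, 1)),
        rng.uniform(0, 2 * np.pi),
    )
    return Ellipsoid(center=center, semi_axes=tuple(float(a) for a in semi), rotation=rot)


def draw_patch_plan(
    vol: DWIVolume,
    spec: NoiseSpec,
    size_range: tuple[float, float],
    rng: np.random.Generator,
) -> PatchPlan:
    """Draw patch count, geometry and concrete noise choices for one volume."""
    n_patches = int(rng.choice(3, p=PATCH_COUNT_PROBS))
    brain_idx = np.argwhere(vol.brain_mask)
    if len(brain_idx) == 0:
        raise ValueError("brain mask is empty")
    patches = []
    for _ in range(n_patches):
        for _attempt in range(100):
            ell = _draw_ellipsoid(brain_idx, size_range, rng)
            if min(ell.semi_axes) >= 1.0:
                break
        patches.append((ell, spec.resolve(rng)))
    return PatchPlan(n_patches=n_patches, patches=patches)


def corrupt(
    vol: DWIVolume,
    spec: NoiseSpec = NoiseSpec(),
    size_range: tuple[float, float] = (2.0, 8.0),
    rng: np.random.Generator | int | None = None,
    clip: bool = True,
) -> CorruptedVolume:
    """Apply a random patch plan to one healthy volume.

    Ellipsoid centers are drawn from in-brain voxels and the rasterized
    patches are clipped to the brain mask, so background is never painted;
    voxels outside the artificial groundtruth are bit-identical to the input.
    """
    rng = np.random.default_rng(rng)
    plan = draw_patch_plan(vol, spec, size_range, rng)
    signal = vol.signal.copy()
    gt = np.zeros(vol.signal.shape[:3], dtype=bool)
    mu, sigma = brain_statistics(vol)
    brain = vol.brain_mask
    n_chan = vol.signal.shape[3]
    for ell, patch_spec in plan.patches:
        voxels = ellipsoid_mask(vol.signal.shape[:3], ell.center, ell.semi_axes, ell.rotation)
        voxels &= brain
        n_vox = int(voxels.sum())
        if n_vox == 0:
            continue
        block = sample_noise_block((n_vox, n_chan), patch_spec, mu, sigma, rng, clip=clip)
        signal[voxels] = block
        gt |= voxels
    return CorruptedVolume(signal=signal, artificial_groundtruth=gt, plan=plan, source=vol)


def augment(
    vol: DWIVolume,
    spec: NoiseSpec = NoiseSpec(),
    rng: np.random.Generator | int | None = None,
    n_augment: int = 4,
    size_range: tuple[float, float] = (2.0, 8.0),
) -> list[CorruptedVolume]:
    """Expand one subject into ``n_augment`` independently corrupted copies."""
    rng = np.random.default_rng(rng)
    return [corrupt(vol, spec, size_range=size_range, rng=rng) for _ in range(n_augment)]
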