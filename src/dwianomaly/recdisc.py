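"""Two-stage reconstruction + discrimination anomaly network.

Healthy volumes are synthetically corrupted with ellipsoidal noise patches
(:mod:`dwianomaly.injection`).  A reconstruction network learns to denoise
the corrupted input back to the clean volume (MSE), while a discrimination
network receives the input concatenated with its reconstruction (2·C
channels) and predicts a voxelwise anomaly logit against the artificial
groundtruth.  The joint loss is

    L = MSE + ω · [ −(1/n) Σᵢ ( p₁ ŷᵢ log σ(yᵢ) + (1 − ŷᵢ) log(1 − σ(yᵢ)) ) ]

with n the number of in-brain voxels, ω amplifying the BCE term and p₁
weighting the (rare) positive class.  At inference the discriminator output
σ(y) is the anomaly map directly — no residual computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import _nn
from ._nn import (
    Adam,
    Conv3d,
    ConvTranspose3d,
    InstanceNorm3d,
    LeakyReLU,
    Sequential,
    sigmoid,
)
from .dae import ConvVAE, TrainState, _stack_volumes
from .injection import NoiseSpec, corrupt
from .io import AnomalyMap, DWIVolume

logger = logging.getLogger("dwianomaly")


@dataclass
class RecDiscConfig:
    """Hyperparameters; optimizer/batch/epoch defaults follow the DAE."""

    noise: NoiseSpec = field(default_factory=NoiseSpec)
    bce_weight: float = 1.0
    positive_class_weight: float | str = "auto"
    latent_dim: int = 128
    enc_channels: tuple[int, ...] = (32, 64, 128, 256)
    disc_channels: int = 16
    negative_slope: float = 0.01
    epochs: int = 500
    batch_size: int = 4
    lr: float = 1e-4
    lr_decay: float = 0.95
    augment_factor: int = 4
    coupling: str = "joint"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bce_weight <= 0:
            raise ValueError("bce_weight must be positive")
        if isinstance(self.positive_class_weight, float) and self.positive_class_weight <= 0:
            raise ValueError("positive_class_weight must be positive")
        if self.coupling not in ("joint", "detached"):
            raise ValueError("coupling must be 'joint' or 'detached'")


@dataclass
class DiscriminationOutput:
    """Voxelwise logits y and probabilities σ(y)."""

    logits: np.ndarray

    @property
    def probabilities(self) -> np.ndarray:
        return sigmoid(self.logits)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _softplus(t: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(t))) + np.maximum(t, 0.0)


def weighted_bce_with_logits(
    logits: np.ndarray,
    target: np.ndarray,
    p1: float = 1.0,
    mask: np.ndarray | None = None,
) -> float:
    """−(1/n) Σ (p₁ ŷ log σ(y) + (1−ŷ) log(1−σ(y))), log-sum-exp stabilised."""
    target = np.asarray(target, dtype=np.float64)
    # log σ(y) = −softplus(−y);  log(1 − σ(y)) = −softplus(y)
    per = p1 * target * _softplus(-logits) + (1.0 - target) * _softplus(logits)
    if mask is not None:
        sel = np.broadcast_to(mask, per.shape)
        return float(per[sel].mean())
    return float(per.mean())


def recdisc_loss(
    clean: np.ndarray,
    reconstruction: np.ndarray,
    logits: np.ndarray,
    target: np.ndarray,
    bce_weight: float = 1.0,
    p1: float = 1.0,
    mask: np.ndarray | None = None,
) -> float:
    """Joint reconstruction + discrimination loss (see module docstring)."""
    if clean.shape != reconstruction.shape:
        raise ValueError("clean input and reconstruction shapes differ")
    if mask is None:
        mse = float(np.mean((reconstruction - clean) ** 2))
    else:
        sel = np.broadcast_to(mask, clean.shape)
        mse = float(((reconstruction - clean) ** 2)[sel].mean())
    return mse + bce_weight * weighted_bce_with_logits(logits, target, p1, mask)


# ---------------------------------------------------------------------------
# discrimination network: 3-stage U-Net, 2·C channels in, 1 logit channel out
# ---------------------------------------------------------------------------

def _block(c_in: int, c_out: int, stride: int, slope: float, rng) -> Sequential:
    return Sequential(
        Conv3d(c_in, c_out, k=3, stride=stride, rng=rng), InstanceNorm3d(), LeakyReLU(slope)
    )


def _up(c_in: int, c_out: int, slope: float, rng) -> Sequential:
    return Sequential(
        ConvTranspose3d(c_in, c_out, k=3, stride=2, rng=rng), InstanceNorm3d(), LeakyReLU(slope)
    )


class UNet3D:
    """Encoder-decoder with skip connections emitting one logit channel.

    Three stride-2 encoder stages with skips at 1/2 and 1/4 resolution; a
    final transposed convolution restores full resolution before the 1×1
    logit head, so every context-aggregating convolution runs on a
    downsampled grid.
    """

    def __init__(self, in_channels: int, base: int = 16, negative_slope: float = 0.01,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        f = base
        self.e0 = _block(in_channels, f, 2, negative_slope, rng)       # 1/2
        self.e1 = _block(f, 2 * f, 2, negative_slope, rng)             # 1/4
        self.e2 = _block(2 * f, 4 * f, 2, negative_slope, rng)         # 1/8
        self.u1 = _up(4 * f, 2 * f, negative_slope, rng)               # 1/4
        self.c1 = _block(4 * f, 2 * f, 1, negative_slope, rng)
        self.u2 = _up(2 * f, f, negative_slope, rng)                   # 1/2
        self.c2 = _block(2 * f, f, 1, negative_slope, rng)
        self.u3 = _up(f, f, negative_slope, rng)                       # full
        self.out = Conv3d(f, 1, k=1, stride=1, pad=0, rng=rng)
        self.f = f

    def params(self) -> list:
        mods = (self.e0, self.e1, self.e2, self.u1, self.c1, self.u2, self.c2,
                self.u3, self.out)
        return [p for m in mods for p in m.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x0 = self.e0.forward(x)
        x1 = self.e1.forward(x0)
        x2 = self.e2.forward(x1)
        y1 = self.c1.forward(np.concatenate([self.u1.forward(x2), x1], axis=1))
        y2 = self.c2.forward(np.concatenate([self.u2.forward(y1), x0], axis=1))
        return self.out.forward(self.u3.forward(y2))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        f = self.f
        dy2 = self.u3.backward(self.out.backward(dlogits))
        dcat2 = self.c2.backward(dy2)
        dx0 = dcat2[:, f:]
        dy1 = self.u2.backward(dcat2[:, :f])
        dcat1 = self.c1.backward(dy1)
        dx1 = dcat1[:, 2 * f :]
        dx2 = self.u1.backward(dcat1[:, : 2 * f])
        dx1 = dx1 + self.e2.backward(dx2)
        dx0 = dx0 + self.e1.backward(dx1)
        return self.e0.backward(dx0)


def build_recdisc(
    config: RecDiscConfig, grid_shape: Sequence[int], n_channels: int
) -> tuple[ConvVAE, UNet3D]:
    """Reconstruction net (plain conv autoencoder, DAE family) + discriminator."""
    rng = np.random.default_rng(config.seed)
    recon_net = ConvVAE(
        in_channels=n_channels,
        grid_shape=grid_shape,
        latent_dim=config.latent_dim,
        enc_channels=config.enc_channels,
        output_activation="sigmoid",
        negative_slope=config.negative_slope,
        variational=False,
        rng=rng,
    )
    disc_net = UNet3D(
        in_channels=2 * n_channels,
        base=config.disc_channels,
        negative_slope=config.negative_slope,
        rng=rng,
    )
    return recon_net, disc_net


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class RecDiscNet(BaseEstimator):
    """Reconstruction + discrimination anomaly detector (sklearn surface).

    ``fit`` takes healthy normalized volumes; each training subject is
    expanded into ``augment_factor`` corrupted copies drawn once up front
    (set ``resample_each_epoch=True`` to redraw per epoch).  ``coupling``
    controls whether discriminator gradients flow back into the
    reconstruction net ("joint") or not ("detached").

    Attributes set by fit: ``recon_net_``, ``disc_net_``, ``history_``,
    ``best_epoch_``, ``grid_shape_``, ``n_channels_``.
    """

    def __init__(
        self,
        noise_family: str = "mix",
        mean_mode: str = "half",
        structure: str = "mix",
        bce_weight: float = 1.0,
        positive_class_weight: float | str = "auto",
        latent_dim: int = 512,
        enc_channels: tuple[int, ...] = (32, 64, 128, 256),
        disc_channels: int = 16,
        negative_slope: float = 0.01,
        epochs: int = 500,
        batch_size: int = 4,
        lr: float = 1e-4,
        lr_decay: float = 0.95,
        augment_factor: int = 4,
        resample_each_epoch: bool = False,
        coupling: str = "joint",
        patch_size_range: tuple[float, float] = (2.0, 8.0),
        validation_fraction: float = 0.2,
        random_state: int = 0,
    ):
        self.noise_family = noise_family
        self.mean_mode = mean_mode
        self.structure = structure
        self.bce_weight = bce_weight
        self.positive_class_weight = positive_class_weight
        self.latent_dim = latent_dim
        self.enc_channels = enc_channels
        self.disc_channels = disc_channels
        self.negative_slope = negative_slope
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.lr_decay = lr_decay
        self.augment_factor = augment_factor
        self.resample_each_epoch = resample_each_epoch
        self.coupling = coupling
        self.patch_size_range = patch_size_range
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    @property
    def _spec(self) -> NoiseSpec:
        return NoiseSpec(
            family=self.noise_family, mean_mode=self.mean_mode, structure=self.structure
        )

    def _corrupt_set(
        self, volumes: Sequence[DWIVolume], rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Corrupted signal, clean target, groundtruth and brain mask arrays."""
        clean, mask = _stack_volumes(volumes)
        reps = self.augment_factor
        sigs, gts = [], []
        for vol in volumes:
            for _ in range(reps):
                cv = corrupt(vol, self._spec, size_range=self.patch_size_range, rng=rng)
                sigs.append(cv.signal.transpose(3, 0, 1, 2))
                gts.append(cv.artificial_groundtruth)
        dt = _nn.default_dtype()
        corrupted = np.stack(sigs).astype(dt)
        gt = np.stack(gts)[:, None].astype(dt)
        clean = np.repeat(clean, reps, axis=0).astype(dt)
        mask = np.repeat(mask, reps, axis=0)
        # discriminator has three stride-2 stages
        factor = max(2 ** len(self.enc_channels), 8)
        corrupted, self._crop = _nn.pad_to_multiple(corrupted, factor)
        clean, _ = _nn.pad_to_multiple(clean, factor)
        gt, _ = _nn.pad_to_multiple(gt, factor)
        mask, _ = _nn.pad_to_multiple(mask, factor)
        return corrupted, clean, gt, mask.astype(bool)

    def _p1(self, gt: np.ndarray, mask: np.ndarray) -> float:
        if self.positive_class_weight != "auto":
            return float(self.positive_class_weight)
        n_pos = float(gt[mask].sum())
        n_neg = float(mask.sum() - n_pos)
        return n_neg / n_pos if n_pos > 0 else 1.0

    def _loss_and_grad(self, corrupted, clean, gt, mask, train: bool) -> float:
        recon = self.recon_net_.forward(corrupted)[0]
        cat = np.concatenate([corrupted, recon], axis=1)
        logits = self.disc_net_.forward(cat)
        n_brain = max(int(mask.sum()), 1)
        p1 = self._p1(gt, mask)

        diff = np.where(np.broadcast_to(mask, clean.shape), recon - clean, 0.0)
        n_mse = max(int(mask.sum()) * clean.shape[1], 1)
        mse = float((diff**2).sum() / n_mse)
        y = np.where(mask, logits, 0.0)
        per = p1 * gt * _softplus(-y) + (1.0 - gt) * _softplus(y)
        bce = float(per[mask].sum() / n_brain)
        loss = mse + self.bce_weight * bce
        if train:
            sig_y = sigmoid(logits)
            dlogits = (
                self.bce_weight
                * np.where(mask, -p1 * gt * (1.0 - sig_y) + (1.0 - gt) * sig_y, 0.0)
                / n_brain
            )
            dcat = self.disc_net_.backward(dlogits)
            drecon = 2.0 * diff / n_mse
            if self.coupling == "joint":
                drecon = drecon + dcat[:, clean.shape[1] :]
            self.recon_net_.backward(drecon)
        return loss

    # -- sklearn surface ----------------------------------------------------
    def fit(self, X: Sequence[DWIVolume], y=None, validation: Sequence[DWIVolume] | None = None):
        rng = np.random.default_rng(self.random_state)
        X = list(X)
        if validation is None:
            n_val = max(1, int(round(self.validation_fraction * len(X)))) if len(X) > 1 else 0
            order = rng.permutation(len(X))
            validation = [X[i] for i in order[:n_val]]
            X = [X[i] for i in order[n_val:]]
        if not X:
            raise ValueError("empty training set")
        self.n_channels_ = X[0].signal.shape[3]
        self.grid_shape_ = X[0].signal.shape[:3]

        corrupted, clean, gt, mask = self._corrupt_set(X, rng)
        if validation:
            vc, vcl, vgt, vmask = self._corrupt_set(validation, rng)
        self.recon_net_, self.disc_net_ = build_recdisc(
            RecDiscConfig(
                noise=self._spec,
                bce_weight=self.bce_weight,
                positive_class_weight=self.positive_class_weight,
                latent_dim=self.latent_dim,
                enc_channels=self.enc_channels,
                disc_channels=self.disc_channels,
                negative_slope=self.negative_slope,
                seed=self.random_state,
            ),
            corrupted.shape[2:],
            self.n_channels_,
        )
        params = self.recon_net_.params() + self.disc_net_.params()
        opt = Adam(params, lr=self.lr, lr_decay=self.lr_decay)
        history = {"train_loss": [], "val_loss": [], "lr": []}
        best_val, best_state, best_epoch = np.inf, None, -1
        n = corrupted.shape[0]
        for epoch in range(self.epochs):
            opt.epoch = epoch
            if self.resample_each_epoch and epoch > 0:
                corrupted, clean, gt, mask = self._corrupt_set(X, rng)
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                opt.zero_grad()
                loss = self._loss_and_grad(
                    corrupted[sel], clean[sel], gt[sel], mask[sel], train=True
                )
                opt.step()
                losses.append(loss)
            train_loss = float(np.mean(losses))
            if not np.isfinite(train_loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={train_loss}"
                )
            if validation:
                val_losses = [
                    self._loss_and_grad(
                        vc[k : k + self.batch_size],
                        vcl[k : k + self.batch_size],
                        vgt[k : k + self.batch_size],
                        vmask[k : k + self.batch_size],
                        train=False,
                    )
                    for k in range(0, vc.shape[0], self.batch_size)
                ]
                val_loss = float(np.mean(val_losses))
            else:
                val_loss = train_loss
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            history["lr"].append(opt.lr)
            if val_loss < best_val:
                best_val, best_epoch = val_loss, epoch
                best_state = _nn.get_state(params)
            logger.debug("recdisc epoch=%d train=%.5f val=%.5f", epoch, train_loss, val_loss)
        if best_state is not None:
            _nn.set_state(params, best_state)
        self.history_ = history
        self.best_epoch_ = best_epoch
        return self

    def anomaly_map(self, vol_or_signal) -> AnomalyMap:
        """Score one volume: σ(logits) of the discriminator, range [0, 1]."""
        if isinstance(vol_or_signal, DWIVolume):
            signal = vol_or_signal.signal
        else:
            signal = np.asarray(vol_or_signal, dtype=np.float64)
        if signal.shape[3] != self.n_channels_:
            raise ValueError(
                f"volume has {signal.shape[3]} channels, model expects {self.n_channels_}"
            )
        x = signal.transpose(3, 0, 1, 2)[None].astype(_nn.default_dtype())
        factor = max(2 ** len(self.enc_channels), 8)
        x, crop = _nn.pad_to_multiple(x, factor)
        recon = self.recon_net_.forward(x)[0]
        logits = self.disc_net_.forward(np.concatenate([x, recon], axis=1))
        probs = sigmoid(logits[crop][0, 0])
        return AnomalyMap(scores=probs, score_range=(0.0, 1.0), source_model="recdisc")


def train_recdisc(
    cohort: Sequence[DWIVolume],
    noise_spec: NoiseSpec | None = None,
    config: RecDiscConfig | None = None,
    fold: tuple[Sequence[int], Sequence[int]] | None = None,
) -> TrainState:
    """Train a RecDiscNet on a healthy cohort with an optional fold split."""
    config = config or RecDiscConfig()
    spec = noise_spec or config.noise
    est = RecDiscNet(
        noise_family=spec.family,
        mean_mode=spec.mean_mode,
        structure=spec.structure,
        bce_weight=config.bce_weight,
        positive_class_weight=config.positive_class_weight,
        latent_dim=config.latent_dim,
        enc_channels=config.enc_channels,
        disc_channels=config.disc_channels,
        negative_slope=config.negative_slope,
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr=config.lr,
        lr_decay=config.lr_decay,
        augment_factor=config.augment_factor,
        coupling=config.coupling,
        random_state=config.seed,
    )
    if fold is not None:
        train_idx, val_idx = fold
        est.fit([cohort[i] for i in train_idx], validation=[cohort[i] for i in val_idx])
    else:
        est.fit(list(cohort))
    return TrainState(estimator=est, history=est.history_, best_epoch=est.best_epoch_)


def score(state: TrainState | RecDiscNet, vol: DWIVolume) -> AnomalyMap:
    est = state.estimator if isinstance(state, TrainState) else state
    return est.anomaly_map(vol)
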