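"""Denoising variational autoencoder for healthy-brain reconstruction.

A 3D convolutional VAE with a flat (linear) latent space is trained only on
healthy diffusion volumes.  Because it can only reproduce patterns it has
seen, out-of-distribution tissue (a tumor) reconstructs poorly and shows up
in the input–output residual.  The loss is

    L = MSE + ω · [ −(1/2)(1/n) Σⱼ (1 + log Σ(xⱼ) − μ(xⱼ)² − Σ(xⱼ)) ]

i.e. mean squared reconstruction error plus a lightly weighted (ω = 1.22e-5
by default) KL divergence of the diagonal-Gaussian latent posterior from the
standard normal prior.  MSE is computed over in-brain voxels only.

Exact layer counts are a design choice of this package: stride-2 kernel-3
convolution stages (default channel widths 32-64-128-256 at full scale),
each instance-normalized and LeakyReLU(0.01)-activated, mirrored by
transposed convolutions in the decoder; the output layer applies the
configured activation (sigmoid or linear).  Inference uses the posterior
mean (no latent sampling) so anomaly maps are deterministic.
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
    Identity,
    InstanceNorm3d,
    LeakyReLU,
    Linear,
    Sequential,
    Sigmoid,
)
from .io import DWIVolume

logger = logging.getLogger("dwianomaly")

LATENT_SIZES = (16, 32, 64, 128, 256, 512)


@dataclass
class DAEConfig:
    """Hyperparameters of the denoising VAE (full-scale defaults)."""

    latent_dim: int = 512
    output_activation: str = "sigmoid"
    kl_weight: float = 1.22e-5
    negative_slope: float = 0.01
    epochs: int = 500
    batch_size: int = 4
    lr: float = 1e-4
    lr_decay: float = 0.95
    enc_channels: tuple[int, ...] = (32, 64, 128, 256)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.output_activation not in ("sigmoid", "linear"):
            raise ValueError("output_activation must be 'sigmoid' or 'linear'")


@dataclass
class LatentPosterior:
    """Diagonal-Gaussian posterior q(z|x) = N(mu, diag(exp(log_var)))."""

    mu: np.ndarray
    log_var: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=np.float64))
        self.log_var = np.atleast_2d(np.asarray(self.log_var, dtype=np.float64))
        if self.mu.shape != self.log_var.shape:
            raise ValueError("mu and log_var must have the same shape")
        if not (np.isfinite(self.mu).all() and np.isfinite(self.log_var).all()):
            raise ValueError("non-finite latent posterior")

    @property
    def n(self) -> int:
        return self.mu.shape[1]


@dataclass
class TrainState:
    """Result of one training run: the fitted estimator plus bookkeeping."""

    estimator: "DiffusionAnomalyVAE"
    history: dict = field(default_factory=dict)
    best_epoch: int = -1
    fold: int | None = None


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def kl_divergence(posterior: LatentPosterior) -> float:
    """KL(q(z|x) ‖ N(0, I)) averaged over the latent size n and the batch."""
    mu, lv = posterior.mu, posterior.log_var
    per_sample = -0.5 / posterior.n * np.sum(1.0 + lv - mu**2 - np.exp(lv), axis=1)
    return float(per_sample.mean())


def masked_mse(x: np.ndarray, recon: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean squared error, restricted to ``mask`` voxels when given."""
    if mask is None:
        return float(np.mean((recon - x) ** 2))
    diff2 = (recon - x) ** 2
    w = np.broadcast_to(mask, x.shape)
    return float(diff2[w].mean())


def dae_loss(
    x: np.ndarray,
    recon: np.ndarray,
    posterior: LatentPosterior,
    kl_weight: float,
    mask: np.ndarray | None = None,
) -> float:
    """Reconstruction MSE plus ω-weighted latent KL divergence."""
    if x.shape != recon.shape:
        raise ValueError("input and reconstruction shapes differ")
    return masked_mse(x, recon, mask) + kl_weight * kl_divergence(posterior)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def _conv_block(c_in: int, c_out: int, slope: float, rng) -> list:
    return [
        Conv3d(c_in, c_out, k=3, stride=2, rng=rng),
        InstanceNorm3d(),
        LeakyReLU(slope),
    ]


class ConvVAE:
    """3D convolutional (variational) autoencoder on (N, C, X, Y, Z) arrays.

    With ``variational=False`` the latent heads collapse to a single dense
    bottleneck (a plain autoencoder), which the reconstruction stage of the
    two-network model uses.
    """

    def __init__(
        self,
        in_channels: int,
        grid_shape: Sequence[int],
        latent_dim: int = 128,
        enc_channels: Sequence[int] = (32, 64, 128, 256),
        output_activation: str = "sigmoid",
        negative_slope: float = 0.01,
        variational: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        depth = len(enc_channels)
        factor = 2**depth
        if any(s % factor for s in grid_shape):
            raise ValueError(
                f"grid {tuple(grid_shape)} must be divisible by the total "
                f"downsampling factor {factor} (pad or crop the input)"
            )
        self.in_channels = in_channels
        self.grid_shape = tuple(grid_shape)
        self.variational = variational
        self.small = tuple(s // factor for s in grid_shape)
        self.c_last = enc_channels[-1]
        self.flat_dim = self.c_last * int(np.prod(self.small))

        enc_layers: list = []
        prev = in_channels
        for c in enc_channels:
            enc_layers += _conv_block(prev, c, negative_slope, rng)
            prev = c
        self.encoder = Sequential(*enc_layers)

        self.fc_mu = Linear(self.flat_dim, latent_dim, rng=rng)
        self.fc_logvar = Linear(self.flat_dim, latent_dim, rng=rng) if variational else None
        self.fc_dec = Linear(latent_dim, self.flat_dim, rng=rng)

        dec_layers: list = []
        rev = list(enc_channels[::-1])
        for c_in, c_out in zip(rev[:-1], rev[1:]):
            dec_layers += [
                ConvTranspose3d(c_in, c_out, k=3, stride=2, rng=rng),
                InstanceNorm3d(),
                LeakyReLU(negative_slope),
            ]
        dec_layers.append(ConvTranspose3d(rev[-1], in_channels, k=3, stride=2, rng=rng))
        dec_layers.append(Sigmoid() if output_activation == "sigmoid" else Identity())
        self.decoder = Sequential(*dec_layers)

    def params(self) -> list:
        parts = self.encoder.params() + self.fc_mu.params()
        if self.fc_logvar is not None:
            parts += self.fc_logvar.params()
        return parts + self.fc_dec.params() + self.decoder.params()

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    # -- forward / backward ------------------------------------------------
    def forward(
        self, x: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, LatentPosterior | None]:
        """Returns (reconstruction, posterior).  Sampling only if rng given."""
        n = x.shape[0]
        h = self.encoder.forward(x)
        self._h_shape = h.shape
        hf = h.reshape(n, -1)
        mu = self.fc_mu.forward(hf)
        posterior = None
        if self.variational:
            logvar = self.fc_logvar.forward(hf)
            posterior = LatentPosterior(mu=mu, log_var=logvar)
            if rng is not None:
                self._eps = rng.standard_normal(mu.shape)
                self._std = np.exp(0.5 * logvar)
                z = mu + self._eps * self._std
            else:
                self._eps = None
                z = mu
        else:
            self._eps = None
            z = mu
        g = self.fc_dec.forward(z)
        recon = self.decoder.forward(g.reshape(self._h_shape[:1] + (self.c_last,) + self.small))
        return recon, posterior

    def backward(
        self,
        drecon: np.ndarray,
        dmu: np.ndarray | float = 0.0,
        dlogvar: np.ndarray | float = 0.0,
    ) -> np.ndarray:
        n = drecon.shape[0]
        dg = self.decoder.backward(drecon).reshape(n, -1)
        dz = self.fc_dec.backward(dg)
        dmu_total = dz + dmu
        dhf = self.fc_mu.backward(dmu_total)
        if self.variational:
            dlv = np.zeros_like(dz) + dlogvar
            if self._eps is not None:
                dlv = dlv + dz * self._eps * 0.5 * self._std
            dhf = dhf + self.fc_logvar.backward(dlv)
        return self.encoder.backward(dhf.reshape(self._h_shape))


def build_dae(config: DAEConfig, grid_shape: Sequence[int], n_channels: int) -> ConvVAE:
    """Instantiate the VAE for a stride-compatible grid (raises otherwise)."""
    return ConvVAE(
        in_channels=n_channels,
        grid_shape=grid_shape,
        latent_dim=config.latent_dim,
        enc_channels=config.enc_channels,
        output_activation=config.output_activation,
        negative_slope=config.negative_slope,
        variational=True,
        rng=np.random.default_rng(config.seed),
    )


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

def _stack_volumes(volumes: Sequence[DWIVolume]) -> tuple[np.ndarray, np.ndarray]:
    """List of DWIVolume → ((N, C, X, Y, Z) signal, (N, 1, X, Y, Z) brain mask)."""
    sig = np.stack([v.signal.transpose(3, 0, 1, 2) for v in volumes])
    mask = np.stack([v.brain_mask[None] for v in volumes])
    return sig.astype(np.float64), mask


class DiffusionAnomalyVAE(BaseEstimator):
    """Denoising-VAE anomaly detector with a scikit-learn estimator surface.

    Parameters mirror :class:`DAEConfig`; ``fit`` expects a sequence of
    healthy, normalized :class:`~dwianomaly.io.DWIVolume` (an optional
    ``validation`` sequence drives checkpoint selection, otherwise
    ``validation_fraction`` of the input is split off).  Inputs are
    zero-padded to the nearest stride-compatible grid; padding is excluded
    from the loss through the brain mask and cropped away on output.

    Attributes set by fit: ``model_``, ``history_``, ``best_epoch_``,
    ``grid_shape_``, ``n_channels_``.
    """

    def __init__(
        self,
        latent_dim: int = 512,
        output_activation: str = "sigmoid",
        kl_weight: float = 1.22e-5,
        negative_slope: float = 0.01,
        epochs: int = 500,
        batch_size: int = 4,
        lr: float = 1e-4,
        lr_decay: float = 0.95,
        enc_channels: tuple[int, ...] = (32, 64, 128, 256),
        validation_fraction: float = 0.2,
        random_state: int = 0,
    ):
        self.latent_dim = latent_dim
        self.output_activation = output_activation
        self.kl_weight = kl_weight
        self.negative_slope = negative_slope
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.lr_decay = lr_decay
        self.enc_channels = enc_channels
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _prepare(self, volumes: Sequence[DWIVolume]) -> tuple[np.ndarray, np.ndarray]:
        sig, mask = _stack_volumes(volumes)
        factor = 2 ** len(self.enc_channels)
        sig, crop = _nn.pad_to_multiple(sig, factor)
        mask, _ = _nn.pad_to_multiple(mask, factor)
        self._crop = crop
        return sig.astype(_nn.default_dtype()), mask.astype(bool)

    def _loss_and_grad(
        self, x: np.ndarray, mask: np.ndarray, rng: np.random.Generator | None
    ) -> tuple[float, float, float]:
        """Forward + backward on one batch; returns (loss, mse, kl)."""
        model = self.model_
        recon, post = model.forward(x, rng=rng)
        w = np.broadcast_to(mask, x.shape)
        count = max(int(w.sum()), 1)
        diff = np.where(w, recon - x, 0.0)
        mse = float((diff**2).sum() / count)
        kl = kl_divergence(post)
        if rng is not None:  # training pass
            drecon = 2.0 * diff / count
            nb, nlat = post.mu.shape
            dmu = self.kl_weight * post.mu / (nlat * nb)
            dlogvar = self.kl_weight * (-0.5) * (1.0 - np.exp(post.log_var)) / (nlat * nb)
            model.backward(drecon, dmu, dlogvar)
        return mse + self.kl_weight * kl, mse, kl

    # -- sklearn surface ----------------------------------------------------
    def fit(self, X: Sequence[DWIVolume], y=None, validation: Sequence[DWIVolume] | None = None):
        rng = np.random.default_rng(self.random_state)
        X = list(X)
        if validation is None:
            n_val = max(1, int(round(self.validation_fraction * len(X)))) if len(X) > 1 else 0
            order = rng.permutation(len(X))
            val_idx, train_idx = order[:n_val], order[n_val:]
            validation = [X[i] for i in val_idx]
            X = [X[i] for i in train_idx]
        if not X:
            raise ValueError("empty training set")
        self.n_channels_ = X[0].signal.shape[3]
        self.grid_shape_ = X[0].signal.shape[:3]

        sig, mask = self._prepare(X)
        if validation:
            vsig, vmask = self._prepare(validation)
        self.model_ = ConvVAE(
            in_channels=self.n_channels_,
            grid_shape=sig.shape[2:],
            latent_dim=self.latent_dim,
            enc_channels=self.enc_channels,
            output_activation=self.output_activation,
            negative_slope=self.negative_slope,
            variational=True,
            rng=rng,
        )
        opt = Adam(self.model_.params(), lr=self.lr, lr_decay=self.lr_decay)
        history = {"train_loss": [], "val_loss": [], "lr": []}
        best_val, best_state, best_epoch = np.inf, None, -1
        n = sig.shape[0]
        for epoch in range(self.epochs):
            opt.epoch = epoch
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                opt.zero_grad()
                loss, _, _ = self._loss_and_grad(sig[sel], mask[sel], rng)
                opt.step()
                losses.append(loss)
            train_loss = float(np.mean(losses))
            if validation:
                val_loss, _, _ = self._loss_and_grad(vsig, vmask, None)
            else:
                val_loss = train_loss
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            history["lr"].append(opt.lr)
            if not np.isfinite(train_loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={train_loss}"
                )
            if val_loss < best_val:
                best_val, best_epoch = val_loss, epoch
                best_state = _nn.get_state(self.model_.params())
            logger.debug("dae epoch=%d train=%.5f val=%.5f", epoch, train_loss, val_loss)
        if best_state is not None:
            _nn.set_state(self.model_.params(), best_state)
        self.history_ = history
        self.best_epoch_ = best_epoch
        return self

    def reconstruct(self, vol: DWIVolume) -> np.ndarray:
        """Deterministic reconstruction (posterior mean, no sampling)."""
        if vol.signal.shape[3] != self.n_channels_:
            raise ValueError(
                f"volume has {vol.signal.shape[3]} channels, model expects {self.n_channels_}"
            )
        if vol.signal.shape[:3] != self.grid_shape_:
            raise ValueError(
                f"volume grid {vol.signal.shape[:3]} does not match training "
                f"geometry {self.grid_shape_}"
            )
        sig, _ = _stack_volumes([vol])
        factor = 2 ** len(self.enc_channels)
        sig, crop = _nn.pad_to_multiple(sig, factor)
        recon, _ = self.model_.forward(sig.astype(_nn.default_dtype()), rng=None)
        return recon[crop][0].transpose(1, 2, 3, 0)


def train_dae(
    cohort: Sequence[DWIVolume],
    config: DAEConfig | None = None,
    fold: tuple[Sequence[int], Sequence[int]] | None = None,
) -> TrainState:
    """Train a DAE on a cohort with an optional (train_idx, val_idx) fold."""
    config = config or DAEConfig()
    est = DiffusionAnomalyVAE(
        latent_dim=config.latent_dim,
        output_activation=config.output_activation,
        kl_weight=config.kl_weight,
        negative_slope=config.negative_slope,
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr=config.lr,
        lr_decay=config.lr_decay,
        enc_channels=config.enc_channels,
        random_state=config.seed,
    )
    if fold is not None:
        train_idx, val_idx = fold
        est.fit([cohort[i] for i in train_idx], validation=[cohort[i] for i in val_idx])
    else:
        est.fit(list(cohort))
    return TrainState(estimator=est, history=est.history_, best_epoch=est.best_epoch_)


def reconstruct(state: TrainState | DiffusionAnomalyVAE, vol: DWIVolume) -> np.ndarray:
    est = state.estimator if isinstance(state, TrainState) else state
    return est.reconstruct(vol)
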