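"""Convolutional variational autoencoder trained on pooled tooth images.

The model is a standard diagonal-Gaussian VAE: the encoder maps a square
grayscale image x to the parameters (mu, log sigma^2) of q(z|x), a latent
code is drawn by the reparameterization z = mu + sigma * eps, and the
decoder reconstructs x from z with a sigmoid output so pixels stay in
[0, 1].  The training objective is

    L = gamma_KL * D_KL(q(z|x) || N(0, I)) + gamma_rec * L_rec(x, x_hat)

with the reconstruction term a per-pixel mean squared error (a Gaussian
decoder likelihood with fixed variance, up to an affine constant); a
summed-pixel reduction is available behind ``rec_reduction='sum'``.

Architecture: five stride-2 4x4 conv blocks with LeakyReLU halve the
spatial side from ``image_side`` down to ``image_side / 32``, a linear head
reads out mu and log-var, and the decoder mirrors the stack with transposed
convolutions.  Latents are always handled as flat vectors of length
``n_latent``.  Everything runs in numpy (see ``_nn``); training is
deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import _nn

__all__ = [
    "VAEConfig",
    "LossWeights",
    "LatentDistribution",
    "TrainedVAE",
    "encode",
    "decode",
    "sample_latent",
    "kl_loss",
    "reconstruction_loss",
    "vae_loss",
    "train_single_vae",
    "save_checkpoint",
    "load_checkpoint",
]

N_BLOCKS = 5  # stride-2 conv blocks; spatial side shrinks by 2**5


@dataclass(frozen=True)
class VAEConfig:
    """Architecture and optimization settings."""

    image_side: int = 64
    channels: tuple[int, ...] = (8, 16, 32, 32, 32)
    n_latent: int = 32
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    rec_reduction: str = "mean"   # 'mean' (per-pixel) or 'sum' (per-image)
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        if self.image_side % 2 ** N_BLOCKS != 0 or self.image_side < 32:
            raise ValueError("image_side must be a multiple of 32")
        if len(self.channels) != N_BLOCKS:
            raise ValueError(f"channels must list {N_BLOCKS} widths")
        if self.rec_reduction not in ("mean", "sum"):
            raise ValueError("rec_reduction must be 'mean' or 'sum'")
        if self.n_latent < 1:
            raise ValueError("n_latent must be >= 1")

    @property
    def spatial0(self) -> int:
        return self.image_side // 2 ** N_BLOCKS

    @property
    def feat_dim(self) -> int:
        return self.channels[-1] * self.spatial0 ** 2


@dataclass(frozen=True)
class LossWeights:
    """Loss-term weights gamma1..gamma5.

    Single-VAE objective: gamma1 * KL + gamma2 * rec.
    Parallel objective:   gamma1 * KL_a + gamma2 * KL_b
                        + gamma3 * rec_a + gamma4 * rec_b
                        + gamma5 * separate.
    """

    gamma1: float = 0.0
    gamma2: float = 0.0
    gamma3: float = 0.0
    gamma4: float = 0.0
    gamma5: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.gamma1, self.gamma2, self.gamma3, self.gamma4, self.gamma5)
        if any(g < 0 for g in vals):
            raise ValueError("loss weights must be non-negative")
        if all(g == 0 for g in vals[:4]):
            raise ValueError("at least one of gamma1..gamma4 must be positive")

    @classmethod
    def single_default(cls) -> "LossWeights":
        """Published single-VAE weights: reconstruction 1, KL 0.00001."""
        return cls(gamma1=0.00001, gamma2=1.0)

    @classmethod
    def preset(cls, name: str, gamma5: float = 1.0) -> "LossWeights":
        """Named parallel-loss weight combinations (loss1..loss5).

        The published table fixes gamma1..gamma4 only; the separate-loss
        weight gamma5 is a free choice and defaults to 1 (the separate loss
        is a dimensionless ratio of order one).
        """
        table = {
            "loss1": (0.00001, 0.00001, 1.0, 1.0),
            "loss2": (0.000001, 0.00001, 0.1, 1.0),
            "loss3": (0.001, 0.00001, 10.0, 1.0),
            "loss4": (0.00001, 0.000001, 1.0, 0.1),
            "loss5": (0.00001, 0.001, 1.0, 10.0),
        }
        if name not in table:
            raise KeyError(f"unknown preset {name!r}; choose from {sorted(table)}")
        g1, g2, g3, g4 = table[name]
        return cls(gamma1=g1, gamma2=g2, gamma3=g3, gamma4=g4, gamma5=gamma5)


@dataclass
class LatentDistribution:
    """Diagonal-Gaussian posterior parameters (mu, log sigma^2)."""

    mu: np.ndarray
    log_var: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.log_var = np.asarray(self.log_var, dtype=float)
        if self.mu.shape != self.log_var.shape:
            raise ValueError("mu and log_var must have the same shape")


@dataclass
class TrainedVAE:
    """Encoder/decoder parameters plus the training loss history."""

    config: VAEConfig
    params: dict[str, np.ndarray]
    history: list[dict] = field(default_factory=list)

    @property
    def n_latent(self) -> int:
        return self.config.n_latent


# ---------------------------------------------------------------------------
# parameter init

def init_params(config: VAEConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    p: dict[str, np.ndarray] = {}
    chans = (1,) + tuple(config.channels)
    for i in range(N_BLOCKS):
        p[f"e{i}_w"] = _nn.he_conv(rng, chans[i + 1], chans[i])
        p[f"e{i}_b"] = np.zeros(chans[i + 1])
    p["mu_w"] = _nn.he_linear(rng, config.n_latent, config.feat_dim)
    p["mu_b"] = np.zeros(config.n_latent)
    p["lv_w"] = _nn.he_linear(rng, config.n_latent, config.feat_dim)
    p["lv_b"] = np.zeros(config.n_latent)
    p["fc_w"] = _nn.he_linear(rng, config.feat_dim, config.n_latent)
    p["fc_b"] = np.zeros(config.feat_dim)
    rev = tuple(reversed(chans))  # (c4, c3, ..., c0, 1)
    for i in range(N_BLOCKS):
        p[f"d{i}_w"] = _nn.he_conv(rng, rev[i], rev[i + 1])  # (F_in, C_out, K, K)
        p[f"d{i}_b"] = np.zeros(rev[i + 1])
    return p


# ---------------------------------------------------------------------------
# batched forward/backward (internal; public ops wrap the single-image case)

def _encode_fw(params, cfg: VAEConfig, x: np.ndarray):
    caches = []
    h = x
    for i in range(N_BLOCKS):
        h, c_conv = _nn.conv_forward(h, params[f"e{i}_w"], params[f"e{i}_b"])
        h, c_act = _nn.leaky_relu_forward(h, cfg.leaky_slope)
        caches.append((c_conv, c_act))
    flat = h.reshape(h.shape[0], -1)
    mu, _ = _nn.linear_forward(flat, params["mu_w"], params["mu_b"])
    lv, _ = _nn.linear_forward(flat, params["lv_w"], params["lv_b"])
    return mu, lv, (caches, flat, h.shape)


def _encode_bw(params, cfg: VAEConfig, dmu, dlv, cache):
    caches, flat, hshape = cache
    grads = {}
    dflat1, grads["mu_w"], grads["mu_b"] = _nn.linear_backward(dmu, params["mu_w"], flat)
    dflat2, grads["lv_w"], grads["lv_b"] = _nn.linear_backward(dlv, params["lv_w"], flat)
    dh = (dflat1 + dflat2).reshape(hshape)
    for i in reversed(range(N_BLOCKS)):
        c_conv, c_act = caches[i]
        dh = _nn.leaky_relu_backward(dh, c_act)
        dh, grads[f"e{i}_w"], grads[f"e{i}_b"] = _nn.conv_backward(
            dh, params[f"e{i}_w"], c_conv)
    return grads


def _decode_fw(params, cfg: VAEConfig, z: np.ndarray):
    flat, _ = _nn.linear_forward(z, params["fc_w"], params["fc_b"])
    h = flat.reshape(z.shape[0], cfg.channels[-1], cfg.spatial0, cfg.spatial0)
    caches = []
    for i in range(N_BLOCKS):
        h, c_conv = _nn.convT_forward(h, params[f"d{i}_w"], params[f"d{i}_b"])
        if i < N_BLOCKS - 1:
            h, c_act = _nn.leaky_relu_forward(h, cfg.leaky_slope)
        else:
            h = _nn.sigmoid(h)
            c_act = h
        caches.append((c_conv, c_act))
    return h, (caches, z)


def _decode_bw(params, cfg: VAEConfig, dy, cache):
    caches, z = cache
    grads = {}
    dh = dy
    for i in reversed(range(N_BLOCKS)):
        c_conv, c_act = caches[i]
        if i < N_BLOCKS - 1:
            dh = _nn.leaky_relu_backward(dh, c_act)
        else:
            dh = _nn.sigmoid_backward(dh, c_act)
        dh, grads[f"d{i}_w"], grads[f"d{i}_b"] = _nn.convT_backward(
            dh, params[f"d{i}_w"], c_conv)
    dflat = dh.reshape(dh.shape[0], -1)
    dz, grads["fc_w"], grads["fc_b"] = _nn.linear_backward(dflat, params["fc_w"], z)
    return dz, grads


def _check_image(img: np.ndarray, side: int) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape != (side, side):
        raise ValueError(f"expected a {side}x{side} image, got shape {img.shape}")
    return img


# ---------------------------------------------------------------------------
# public operations

def encode(model: TrainedVAE, img: np.ndarray) -> LatentDistribution:
    """Deterministic encoder pass for a single image -> (mu, log_var)."""
    x = _check_image(img, model.config.image_side)[None, None]
    mu, lv, _ = _encode_fw(model.params, model.config, x)
    return LatentDistribution(mu=mu[0], log_var=lv[0])


def decode(model: TrainedVAE, z: np.ndarray) -> np.ndarray:
    """Deterministic decoder pass for a single latent vector -> image in [0,1]."""
    z = np.asarray(z, dtype=float).ravel()
    if z.shape[0] != model.config.n_latent:
        raise ValueError(
            f"latent length {z.shape[0]} != configured {model.config.n_latent}")
    y, _ = _decode_fw(model.params, model.config, z[None])
    return y[0, 0]


def sample_latent(dist: LatentDistribution, stream: np.random.Generator) -> np.ndarray:
    """Reparameterized draw z = mu + exp(log_var/2) * eps, eps ~ N(0, I)."""
    if not (np.all(np.isfinite(dist.mu)) and np.all(np.isfinite(dist.log_var))):
        raise FloatingPointError("latent distribution parameters must be finite")
    eps = stream.standard_normal(dist.mu.shape)
    return dist.mu + np.exp(0.5 * dist.log_var) * eps


def kl_loss(dist: LatentDistribution) -> float:
    """D_KL( N(mu, diag(sigma^2)) || N(0, I) ) in closed form.

    Equals 0.5 * sum_i (mu_i^2 + sigma_i^2 - log sigma_i^2 - 1); zero iff
    the posterior already is the standard normal prior.
    """
    if not (np.all(np.isfinite(dist.mu)) and np.all(np.isfinite(dist.log_var))):
        raise FloatingPointError("latent distribution parameters must be finite")
    return float(0.5 * np.sum(
        dist.mu ** 2 + np.exp(dist.log_var) - dist.log_var - 1.0))


def reconstruction_loss(x: np.ndarray, x_hat: np.ndarray,
                        reduction: str = "mean") -> float:
    """Pixel MSE between input and reconstruction (Gaussian decoder NLL
    up to an affine constant).  ``reduction='sum'`` sums over pixels."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    sq = (x - x_hat) ** 2
    return float(sq.sum() if reduction == "sum" else sq.mean())


def vae_loss(kl: float, rec: float, w: LossWeights) -> float:
    """Single-VAE objective gamma1 * KL + gamma2 * rec."""
    if kl < 0 or rec < 0:
        raise ValueError("loss components must be non-negative")
    return w.gamma1 * kl + w.gamma2 * rec


# ---------------------------------------------------------------------------
# training

def _as_batch(images, side: int) -> np.ndarray:
    """Stack a list of images into a (B,1,S,S) batch."""
    if len(images) == 0:
        raise ValueError("empty image list")
    arr = np.stack([_check_image(im, side) for im in images])
    return arr[:, None]


def _stack_images(images, side: int) -> np.ndarray:
    if len(images) < 2:
        raise ValueError("need at least 2 training images")
    return _as_batch(images, side)


def _batch_losses(x, y, mu, lv, cfg: VAEConfig):
    B = x.shape[0]
    if cfg.rec_reduction == "mean":
        rec = float(((y - x) ** 2).mean())
    else:
        rec = float(((y - x) ** 2).sum()) / B
    kl = float(0.5 * np.sum(mu ** 2 + np.exp(lv) - lv - 1.0)) / B
    return kl, rec


def _rec_grad(x, y, cfg: VAEConfig):
    if cfg.rec_reduction == "mean":
        return 2.0 * (y - x) / x.size
    return 2.0 * (y - x) / x.shape[0]


def train_single_vae(images, w: LossWeights | None = None,
                     config: VAEConfig | None = None,
                     stream: np.random.Generator | None = None) -> TrainedVAE:
    """Train one VAE on a pooled list of images (both tooth types mixed).

    Minimizes gamma1 * KL + gamma2 * rec with Adam; returns the model with a
    per-epoch loss history.  Fully deterministic given ``stream``.
    """
    w = w or LossWeights.single_default()
    cfg = config or VAEConfig()
    rng = stream if stream is not None else np.random.default_rng(0)

    x_all = _stack_images(images, cfg.image_side)
    n = x_all.shape[0]
    params = init_params(cfg, rng)
    opt = _nn.Adam(params, lr=cfg.learning_rate)
    history: list[dict] = []

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep = {"kl": 0.0, "rec": 0.0, "total": 0.0}
        nb = 0
        for start in range(0, n, cfg.batch_size):
            x = x_all[order[start:start + cfg.batch_size]]
            B = x.shape[0]
            mu, lv, enc_cache = _encode_fw(params, cfg, x)
            eps = rng.standard_normal(mu.shape)
            z = mu + np.exp(0.5 * lv) * eps
            y, dec_cache = _decode_fw(params, cfg, z)

            kl, rec = _batch_losses(x, y, mu, lv, cfg)
            total = vae_loss(kl, rec, w)

            dy = w.gamma2 * _rec_grad(x, y, cfg)
            dz, dec_grads = _decode_bw(params, cfg, dy, dec_cache)
            dmu = dz + w.gamma1 * mu / B
            dlv = dz * 0.5 * np.exp(0.5 * lv) * eps \
                + w.gamma1 * 0.5 * (np.exp(lv) - 1.0) / B
            enc_grads = _encode_bw(params, cfg, dmu, dlv, enc_cache)

            opt.step(params, {**enc_grads, **dec_grads})
            ep["kl"] += kl
            ep["rec"] += rec
            ep["total"] += total
            nb += 1
        history.append({"epoch": epoch + 1,
                        **{k: v / nb for k, v in ep.items()}})

    return TrainedVAE(config=cfg, params=params, history=history)


def loss_history_frame(model) -> pd.DataFrame:
    """Per-epoch loss components as a DataFrame (for CSV export / curves)."""
    return pd.DataFrame(model.history)


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(model: TrainedVAE, path) -> None:
    """Single-file checkpoint: parameters plus embedded config and history."""
    meta = json.dumps({"config": asdict(model.config),
                       "history": model.history})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.params)


def load_checkpoint(path) -> TrainedVAE:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k: data[k] for k in data.files if k != "__meta__"}
    cfg_d = meta["config"]
    cfg_d["channels"] = tuple(cfg_d["channels"])
    return TrainedVAE(config=VAEConfig(**cfg_d), params=params,
                      history=meta["history"])
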