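"""Parallel VAE: two branches with a shared (common) latent half.

Two VAEs are trained jointly on paired images of the same subject — branch
A on the molar-like image, branch B on the canine-like image.  Each
branch's latent vector of length n = 2k is split into a *unique* half
(first k coordinates, type-specific) and a *common* half (last k
coordinates, shared across types).  The coupling term

    L_separate = L_common / L_unique,
    L_common = (1/k) sum_i (z_Ac_i - z_Bc_i)^2,
    L_unique = (1/k) sum_i (z_Au_i - z_Bu_i)^2,

pushes the two common halves to agree while letting the unique halves
diverge.  The joint objective is

    L = gamma1*KL_A + gamma2*KL_B + gamma3*rec_A + gamma4*rec_B
        + gamma5*L_separate.

The denominator of L_separate is guarded by a small epsilon and the ratio
is clamped during training so near-identical unique halves at
initialization cannot blow up the gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import json
import numpy as np

from . import _nn
from .vae import (LossWeights, TrainedVAE, VAEConfig, _as_batch, _batch_losses,
                  _decode_bw, _decode_fw, _encode_bw, _encode_fw, _rec_grad,
                  _stack_images, init_params)

__all__ = [
    "PartitionedLatent",
    "ParallelBatchLoss",
    "TrainedParallelVAE",
    "partition_latent",
    "common_loss",
    "unique_loss",
    "separate_loss",
    "parallel_loss",
    "train_parallel_vae",
    "latent_agreement",
    "save_parallel_checkpoint",
    "load_parallel_checkpoint",
]

SEPARATE_EPS = 1e-8     # denominator guard of the separate loss
SEPARATE_CAP = 1e6      # training-time clamp on the ratio


@dataclass
class PartitionedLatent:
    """A latent vector split into its unique and common halves."""

    z_u: np.ndarray
    z_c: np.ndarray

    @property
    def k(self) -> int:
        return self.z_u.shape[0]

    def concatenate(self) -> np.ndarray:
        """Rebuild the full latent: [unique, common], the fixed convention."""
        return np.concatenate([self.z_u, self.z_c])


@dataclass(frozen=True)
class ParallelBatchLoss:
    kl_m: float
    kl_c: float
    rec_m: float
    rec_c: float
    common: float
    unique: float
    separate: float
    total: float


@dataclass
class TrainedParallelVAE:
    branch_a: TrainedVAE
    branch_b: TrainedVAE
    k: int
    weights: LossWeights
    history: list[dict] = field(default_factory=list)

    @property
    def n_latent(self) -> int:
        return self.branch_a.config.n_latent


# ---------------------------------------------------------------------------
# latent-partition operations

def partition_latent(z: np.ndarray, k: int) -> PartitionedLatent:
    """Split z (length 2k) into unique (first k) and common (last k) halves."""
    z = np.asarray(z, dtype=float).ravel()
    if z.shape[0] != 2 * k:
        raise ValueError(f"latent length {z.shape[0]} != 2k = {2 * k}")
    return PartitionedLatent(z_u=z[:k].copy(), z_c=z[k:].copy())


def common_loss(z1c: np.ndarray, z2c: np.ndarray) -> float:
    """Mean squared difference between the two common halves."""
    a = np.asarray(z1c, dtype=float)
    b = np.asarray(z2c, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError(f"shape mismatch or empty: {a.shape} vs {b.shape}")
    return float(((a - b) ** 2).mean())


def unique_loss(z1u: np.ndarray, z2u: np.ndarray) -> float:
    """Mean squared difference between the two unique halves."""
    return common_loss(z1u, z2u)


def separate_loss(common: float, unique: float, eps: float = SEPARATE_EPS) -> float:
    """Ratio common / (unique + eps); minimizing it couples the common
    halves while pushing the unique halves apart."""
    if common < 0 or unique < 0:
        raise ValueError("loss components must be non-negative")
    return common / (unique + eps)


def parallel_loss(components: Mapping[str, float], w: LossWeights) -> ParallelBatchLoss:
    """Weighted sum gamma1*KL_m + gamma2*KL_c + gamma3*rec_m + gamma4*rec_c
    + gamma5*separate over one batch's loss components."""
    required = ("kl_m", "kl_c", "rec_m", "rec_c", "separate")
    vals = {}
    for key in required:
        v = float(components[key])
        if v < 0:
            raise ValueError(f"component {key} must be non-negative, got {v}")
        vals[key] = v
    total = (w.gamma1 * vals["kl_m"] + w.gamma2 * vals["kl_c"]
             + w.gamma3 * vals["rec_m"] + w.gamma4 * vals["rec_c"]
             + w.gamma5 * vals["separate"])
    return ParallelBatchLoss(
        kl_m=vals["kl_m"], kl_c=vals["kl_c"],
        rec_m=vals["rec_m"], rec_c=vals["rec_c"],
        common=float(components.get("common", 0.0)),
        unique=float(components.get("unique", 0.0)),
        separate=vals["separate"], total=total)


# ---------------------------------------------------------------------------
# joint training

def train_parallel_vae(pairs, w: LossWeights | None = None,
                       config: VAEConfig | None = None,
                       stream: np.random.Generator | None = None) -> TrainedParallelVAE:
    """Jointly train both branches on paired subject records.

    ``pairs`` is a list of objects with ``image_a`` / ``image_b`` (e.g.
    :class:`~paravae.phantom.SubjectRecord`).  The latent split index is
    k = n_latent / 2.  Deterministic given ``stream``.
    """
    w = w or LossWeights.preset("loss2")
    cfg = config or VAEConfig()
    rng = stream if stream is not None else np.random.default_rng(0)
    if cfg.n_latent % 2 != 0:
        raise ValueError("parallel mode needs an even n_latent (n = 2k)")
    k = cfg.n_latent // 2
    if len(pairs) < 2:
        raise ValueError("need at least 2 paired records")

    xa_all = _stack_images([r.image_a for r in pairs], cfg.image_side)
    xb_all = _stack_images([r.image_b for r in pairs], cfg.image_side)
    n = xa_all.shape[0]

    pa = init_params(cfg, rng)
    pb = init_params(cfg, rng)
    joint = {**{"a_" + key: v for key, v in pa.items()},
             **{"b_" + key: v for key, v in pb.items()}}
    pa = {key[2:]: v for key, v in joint.items() if key.startswith("a_")}
    pb = {key[2:]: v for key, v in joint.items() if key.startswith("b_")}
    opt = _nn.Adam(joint, lr=cfg.learning_rate)
    history: list[dict] = []

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        acc = {f: 0.0 for f in ("kl_m", "kl_c", "rec_m", "rec_c",
                                "common", "unique", "separate", "total")}
        nb = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xa, xb = xa_all[idx], xb_all[idx]
            B = xa.shape[0]

            mua, lva, ca_enc = _encode_fw(pa, cfg, xa)
            mub, lvb, cb_enc = _encode_fw(pb, cfg, xb)
            epsa = rng.standard_normal(mua.shape)
            epsb = rng.standard_normal(mub.shape)
            za = mua + np.exp(0.5 * lva) * epsa
            zb = mub + np.exp(0.5 * lvb) * epsb
            ya, ca_dec = _decode_fw(pa, cfg, za)
            yb, cb_dec = _decode_fw(pb, cfg, zb)

            kl_a, rec_a = _batch_losses(xa, ya, mua, lva, cfg)
            kl_b, rec_b = _batch_losses(xb, yb, mub, lvb, cfg)
            du = za[:, :k] - zb[:, :k]       # unique halves
            dc = za[:, k:] - zb[:, k:]       # common halves
            l_uni = float((du ** 2).mean())
            l_com = float((dc ** 2).mean())
            l_sep = l_com / (l_uni + SEPARATE_EPS)
            capped = l_sep > SEPARATE_CAP
            l_sep = min(l_sep, SEPARATE_CAP)

            batch = parallel_loss(
                {"kl_m": kl_a, "kl_c": kl_b, "rec_m": rec_a, "rec_c": rec_b,
                 "common": l_com, "unique": l_uni, "separate": l_sep}, w)

            # reconstruction path
            dya = w.gamma3 * _rec_grad(xa, ya, cfg)
            dyb = w.gamma4 * _rec_grad(xb, yb, cfg)
            dza, ga_dec = _decode_bw(pa, cfg, dya, ca_dec)
            dzb, gb_dec = _decode_bw(pb, cfg, dyb, cb_dec)

            # separate-loss path (zero gradient when the ratio is clamped)
            if w.gamma5 > 0 and not capped:
                denom = l_uni + SEPARATE_EPS
                gc = w.gamma5 * 2.0 * dc / (B * k) / denom
                gu = -w.gamma5 * l_com / denom ** 2 * 2.0 * du / (B * k)
                dza[:, k:] += gc
                dzb[:, k:] -= gc
                dza[:, :k] += gu
                dzb[:, :k] -= gu

            dmua = dza + w.gamma1 * mua / B
            dlva = dza * 0.5 * np.exp(0.5 * lva) * epsa \
                + w.gamma1 * 0.5 * (np.exp(lva) - 1.0) / B
            dmub = dzb + w.gamma2 * mub / B
            dlvb = dzb * 0.5 * np.exp(0.5 * lvb) * epsb \
                + w.gamma2 * 0.5 * (np.exp(lvb) - 1.0) / B
            ga_enc = _encode_bw(pa, cfg, dmua, dlva, ca_enc)
            gb_enc = _encode_bw(pb, cfg, dmub, dlvb, cb_enc)

            grads = {**{"a_" + key: v for key, v in {**ga_enc, **ga_dec}.items()},
                     **{"b_" + key: v for key, v in {**gb_enc, **gb_dec}.items()}}
            opt.step(joint, grads)

            for f, v in (("kl_m", kl_a), ("kl_c", kl_b), ("rec_m", rec_a),
                         ("rec_c", rec_b), ("common", l_com), ("unique", l_uni),
                         ("separate", l_sep), ("total", batch.total)):
                acc[f] += v
            nb += 1
        history.append({"epoch": epoch + 1,
                        **{f: v / nb for f, v in acc.items()}})

    return TrainedParallelVAE(
        branch_a=TrainedVAE(config=cfg, params=pa, history=[]),
        branch_b=TrainedVAE(config=cfg, params=pb, history=[]),
        k=k, weights=w, history=history)


def latent_agreement(model: TrainedParallelVAE, records) -> tuple[float, float]:
    """Mean common / unique losses over records, on the posterior means.

    Returns ``(mean_common, mean_unique)``; their ratio is the package's
    disentanglement diagnostic (small ratio = converged common halves).
    """
    cfg = model.branch_a.config
    xa = _as_batch([r.image_a for r in records], cfg.image_side)
    xb = _as_batch([r.image_b for r in records], cfg.image_side)
    mua, _, _ = _encode_fw(model.branch_a.params, cfg, xa)
    mub, _, _ = _encode_fw(model.branch_b.params, cfg, xb)
    k = model.k
    com = [common_loss(mua[i, k:], mub[i, k:]) for i in range(len(records))]
    uni = [unique_loss(mua[i, :k], mub[i, :k]) for i in range(len(records))]
    return float(np.mean(com)), float(np.mean(uni))


# ---------------------------------------------------------------------------
# checkpoints

def save_parallel_checkpoint(model: TrainedParallelVAE, path) -> None:
    from dataclasses import asdict
    meta = json.dumps({"config": asdict(model.branch_a.config),
                       "k": model.k,
                       "weights": asdict(model.weights),
                       "history": model.history})
    np.savez(path,
             __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **{"a_" + key: v for key, v in model.branch_a.params.items()},
             **{"b_" + key: v for key, v in model.branch_b.params.items()})


def load_parallel_checkpoint(path) -> TrainedParallelVAE:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        pa = {key[2:]: data[key] for key in data.files if key.startswith("a_")}
        pb = {key[2:]: data[key] for key in data.files if key.startswith("b_")}
    cfg_d = meta["config"]
    cfg_d["channels"] = tuple(cfg_d["channels"])
    cfg = VAEConfig(**cfg_d)
    return TrainedParallelVAE(
        branch_a=TrainedVAE(config=cfg, params=pa, history=[]),
        branch_b=TrainedVAE(config=cfg, params=pb, history=[]),
        k=meta["k"], weights=LossWeights(**meta["weights"]),
        history=meta["history"])
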