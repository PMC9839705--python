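"""Latent traversal along the regression direction and attribution maps.

Because the age readout is linear in the latent features, the coefficient
vector beta is the direction in latent space along which the predicted age
changes fastest.  Shifting a subject's features by s * beta and decoding
yields virtual images of the same subject "younger" (s < 0) or "older"
(s > 0); the predicted age moves by exactly s * ||beta||^2 per step.  The
signed pixel difference between a shifted image and the s = 0
reconstruction shows which regions the age direction controls: positive
(rendered red) = brighter with age, negative (blue) = darker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regression import AgeRegressionModel, FeatureMatrix, extract_features, predict_age
from .vae import TrainedVAE, decode
from .parallel import TrainedParallelVAE

__all__ = [
    "TraversalSeries",
    "DifferenceMap",
    "shift_latents",
    "generate_traversal",
    "difference_map",
    "render_overlay",
    "localization_score",
    "save_traversal_figure",
]


@dataclass
class TraversalSeries:
    """Decoded images along the beta direction, keyed by step scale s."""

    reference: np.ndarray                  # the s = 0 reconstruction
    images: dict[int, np.ndarray]          # includes s = 0 (== reference)
    predicted_ages: dict[int, float]
    latent_source: str                     # 'single' or 'parallel:a' / 'parallel:b'

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class DifferenceMap:
    """Signed per-pixel difference (shifted - reference)."""

    values: np.ndarray

    @property
    def vmax(self) -> float:
        return float(np.abs(self.values).max())


def shift_latents(z: np.ndarray, beta: np.ndarray, s: float) -> np.ndarray:
    """z' = z + s * beta; s > 0 moves toward older, s < 0 toward younger."""
    z = np.asarray(z, dtype=float).ravel()
    beta = np.asarray(beta, dtype=float).ravel()
    if z.shape != beta.shape:
        raise ValueError(f"length mismatch: z {z.shape} vs beta {beta.shape}")
    return z + s * beta


def _decode_features(model, feats: np.ndarray, branch: str) -> np.ndarray:
    """Decode a feature vector back to an image.

    Parallel layout [unique_a (k), unique_b (k), common (k)]: the chosen
    branch decodes [its unique half, the shifted common half] — the common
    shift is applied identically to both branches.
    """
    if isinstance(model, TrainedParallelVAE):
        k = model.k
        if branch == "a":
            z = np.concatenate([feats[:k], feats[2 * k:]])
            return decode(model.branch_a, z)
        if branch == "b":
            z = np.concatenate([feats[k:2 * k], feats[2 * k:]])
            return decode(model.branch_b, z)
        raise ValueError(f"branch must be 'a' or 'b', got {branch!r}")
    return decode(model, feats)


def generate_traversal(model, reg: AgeRegressionModel, record,
                       steps: int = 1, branch: str = "a",
                       step_years: float | None = None) -> TraversalSeries:
    """Decode the record at feature shifts s * beta for s = -steps..+steps.

    ``record`` is an image in single mode or a paired subject record in
    parallel mode.  The reference is the s = 0 reconstruction (decoder
    artifacts cancel in the difference maps).

    By default one step adds the raw coefficient vector beta, which moves
    the predicted age by ||beta||^2 years.  When the latent scale makes
    ||beta||^2 an unreasonable age jump, ``step_years`` rescales the step so
    one unit of s corresponds to exactly that many years
    (s -> s * step_years / ||beta||^2).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    records = [record]
    fm = extract_features(model, records)
    if fm.column_origin != reg.feature_layout:
        raise ValueError("regression layout does not match the model's features")
    f0 = fm.X[0]
    scale = 1.0
    if step_years is not None:
        bsq = float(reg.beta @ reg.beta)
        if bsq == 0.0:
            raise ValueError("cannot normalize step: beta is the zero vector")
        scale = step_years / bsq
    images, ages = {}, {}
    for s in range(-steps, steps + 1):
        fs = shift_latents(f0, reg.beta, s * scale)
        images[s] = _decode_features(model, fs, branch)
        ages[s] = float(predict_age(reg, fs[None])[0])
    source = f"parallel:{branch}" if isinstance(model, TrainedParallelVAE) else "single"
    return TraversalSeries(reference=images[0], images=images,
                           predicted_ages=ages, latent_source=source)


def difference_map(reference: np.ndarray, shifted: np.ndarray) -> DifferenceMap:
    """Signed map shifted - reference (positive = brighter with the shift)."""
    reference = np.asarray(reference, dtype=float)
    shifted = np.asarray(shifted, dtype=float)
    if reference.shape != shifted.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {shifted.shape}")
    return DifferenceMap(values=shifted - reference)


def render_overlay(dmap: DifferenceMap, base: np.ndarray,
                   alpha: float = 0.5) -> np.ndarray:
    """Diverging red/blue rendering of the map, alpha-blended over the base.

    The color scale is symmetric about zero with endpoints at +-max|value|
    (red = positive = brighter, blue = negative = darker); alpha = 0 returns
    the grayscale base as RGB, alpha = 1 the pure color map.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    base = np.asarray(base, dtype=float)
    if base.shape != dmap.values.shape:
        raise ValueError("base image and map shapes differ")
    from matplotlib import colormaps
    vmax = dmap.vmax
    normed = np.zeros_like(dmap.values) if vmax == 0 else dmap.values / vmax
    rgba = colormaps["bwr"]((normed + 1.0) / 2.0)
    color = rgba[..., :3]
    gray = np.repeat(base[..., None], 3, axis=-1)
    return (1.0 - alpha) * gray + alpha * color


def localization_score(dmap: DifferenceMap, mask: np.ndarray) -> float:
    """Fraction of the map's absolute mass inside the mask, in [0, 1]."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dmap.values.shape:
        raise ValueError("mask and map shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    total = float(np.abs(dmap.values).sum())
    if total == 0.0:
        raise ValueError("difference map is identically zero; score undefined")
    return float(np.abs(dmap.values[mask]).sum() / total)


def save_traversal_figure(series: TraversalSeries, path,
                          alpha: float = 0.5) -> None:
    """Three-row figure: virtual images / diverging maps / overlays."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    steps = sorted(series.images)
    ncol = len(steps)
    fig, axes = plt.subplots(3, ncol, figsize=(2.2 * ncol, 6.6), squeeze=False)
    vmax = max(difference_map(series.reference, series.images[s]).vmax
               for s in steps) or 1.0
    for j, s in enumerate(steps):
        img = series.images[s]
        dm = difference_map(series.reference, img)
        axes[0][j].imshow(img, cmap="gray", vmin=0, vmax=1)
        axes[0][j].set_title(f"s={s:+d}  ({series.predicted_ages[s]:.1f} y)",
                             fontsize=8)
        axes[1][j].imshow(dm.values, cmap="bwr", vmin=-vmax, vmax=vmax)
        axes[2][j].imshow(render_overlay(dm, img, alpha=alpha))
        for row in range(3):
            axes[row][j].set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
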