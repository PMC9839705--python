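"""Synthetic paired tooth phantoms with ground-truth age-region masks.

Clinical panoramic radiographs of the kind this pipeline targets cannot be
redistributed, so every stage is exercised on procedurally generated
phantoms instead.  Each synthetic subject contributes a *pair* of grayscale
images sharing one age-driven appearance factor:

* type A — a broad, two-rooted (molar-like) silhouette,
* type B — a narrow, single-rooted (canine-like) silhouette.

Both carry a bright central "pulp cavity" whose mean intensity increases
affinely with age and a dark "cervical" band whose intensity decreases
affinely with age, identically parameterised across the two types (the
shared/common factor).  Type-specific position/scale jitter and additive
pixel noise are the nuisance factors.  Because age enters only through the
intensity of the two masked regions — never the geometry — the ground-truth
attribution region for the latent-traversal analysis is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PhantomConfig",
    "SubjectRecord",
    "generate_subject",
    "generate_dataset",
    "mirror_image",
]

#: Fixed decade labels used throughout the package (ages 10-79).
DECADES = [(10, 19), (20, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 79)]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom generator.

    Intensities are on the [0, 1] grayscale; slopes are intensity units per
    year of age.  Defaults keep every generated pixel inside [0, 1] for all
    ages in ``age_range`` before noise, so clamping only ever acts on noise.
    """

    image_side: int = 64
    age_range: tuple[int, int] = (10, 79)
    pulp_brightness_slope: float = 0.008
    cervical_darkness_slope: float = 0.008
    pulp_base: float = 0.30        # cavity intensity at age 0
    cervical_base: float = 0.78    # band intensity at age 0
    body_intensity: float = 0.55
    background_intensity: float = 0.05
    nuisance_sd: float = 0.02      # per-type jitter of centre/scale (image units)
    noise_sd: float = 0.02         # additive Gaussian pixel noise
    seed: int = 0
    #: optional per-decade sampling weights (len 7, 10-19 .. 70-79); None = uniform
    decade_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.image_side < 32:
            raise ValueError(f"image_side must be >= 32, got {self.image_side}")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range min must be < max, got {self.age_range}")
        for age in (lo, hi):
            if not 0.0 <= self.pulp_base + self.pulp_brightness_slope * age <= 1.0:
                raise ValueError("pulp intensity leaves [0,1] within age_range")
            if not 0.0 <= self.cervical_base - self.cervical_darkness_slope * age <= 1.0:
                raise ValueError("cervical intensity leaves [0,1] within age_range")
        if self.decade_weights is not None and len(self.decade_weights) != len(DECADES):
            raise ValueError("decade_weights must have one entry per decade (7)")

    def cavity_intensity(self, age: float) -> float:
        """Mean pulp-cavity intensity at ``age`` (increasing affine law)."""
        return self.pulp_base + self.pulp_brightness_slope * age

    def band_intensity(self, age: float) -> float:
        """Mean cervical-band intensity at ``age`` (decreasing affine law)."""
        return self.cervical_base - self.cervical_darkness_slope * age


@dataclass
class SubjectRecord:
    """One synthetic subject: age, paired images, ground-truth masks."""

    subject_id: str
    age: float
    side: str                       # 'L' or 'R'
    image_a: np.ndarray             # molar-like phantom, float in [0,1]
    image_b: np.ndarray             # canine-like phantom
    mask_age_region_a: np.ndarray = None   # bool, cavity ∪ cervical band
    mask_age_region_b: np.ndarray = None
    mask_cavity_a: np.ndarray = None
    mask_cervical_a: np.ndarray = None
    mask_cavity_b: np.ndarray = None
    mask_cervical_b: np.ndarray = None
    truth_factors: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry helpers

def _grid(side: int) -> tuple[np.ndarray, np.ndarray]:
    c = (np.arange(side) + 0.5) / side
    return np.meshgrid(c, c)  # xx (columns), yy (rows)


def _ellipse(xx, yy, cx, cy, rx, ry) -> np.ndarray:
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def _tooth_regions(kind: str, side: int, jitter: np.ndarray):
    """Binary silhouette / cavity / cervical-band masks for one tooth type.

    ``jitter`` = (dx, dy, log-scale) nuisance displacement of the whole
    template; masks are derived from the same jittered geometry so the
    ground truth tracks the nuisance.
    """
    xx, yy = _grid(side)
    dx, dy, ds = jitter
    s = float(np.exp(ds))

    def ell(cx, cy, rx, ry):
        return _ellipse(xx, yy, cx + dx, cy + dy, rx * s, ry * s)

    if kind == "A":  # broad crown, two roots
        crown = ell(0.50, 0.34, 0.30, 0.18)
        roots = ell(0.38, 0.62, 0.09, 0.24) | ell(0.62, 0.62, 0.09, 0.24)
        cavity = ell(0.50, 0.34, 0.15, 0.09)
        band_lo, band_hi = 0.46, 0.55
    elif kind == "B":  # narrow crown, single long root
        crown = ell(0.50, 0.30, 0.16, 0.17)
        roots = ell(0.50, 0.60, 0.08, 0.27)
        cavity = ell(0.50, 0.31, 0.08, 0.10)
        band_lo, band_hi = 0.42, 0.51
    else:  # pragma: no cover - internal
        raise ValueError(f"unknown tooth type {kind!r}")

    silhouette = crown | roots
    band = silhouette & (yy >= band_lo + dy) & (yy <= band_hi + dy) & ~cavity
    return silhouette, cavity & silhouette, band


def _render(kind: str, age: float, config: PhantomConfig, jitter: np.ndarray,
            rng: np.random.Generator):
    silhouette, cavity, band = _tooth_regions(kind, config.image_side, jitter)
    img = np.full(silhouette.shape, config.background_intensity)
    img[silhouette] = config.body_intensity
    img[cavity] = config.cavity_intensity(age)
    img[band] = config.band_intensity(age)
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0), cavity, band


# ---------------------------------------------------------------------------
# public operations

def generate_subject(age: float, side: str, config: PhantomConfig,
                     stream: np.random.Generator,
                     subject_id: str = "S0000") -> SubjectRecord:
    """Generate one subject's paired type-A/type-B phantoms.

    The cavity and band intensities follow the same affine-in-age law in
    both images (the common factor); geometric jitter is drawn independently
    per type (the unique factors).  Deterministic given ``stream`` state.
    """
    lo, hi = config.age_range
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside configured range {config.age_range}")
    if side not in ("L", "R"):
        raise ValueError(f"side must be 'L' or 'R', got {side!r}")

    jit_a = stream.normal(0.0, config.nuisance_sd, size=3)
    jit_b = stream.normal(0.0, config.nuisance_sd, size=3)
    img_a, cav_a, band_a = _render("A", age, config, jit_a, stream)
    img_b, cav_b, band_b = _render("B", age, config, jit_b, stream)

    return SubjectRecord(
        subject_id=subject_id,
        age=age,
        side=side,
        image_a=img_a,
        image_b=img_b,
        mask_age_region_a=cav_a | band_a,
        mask_age_region_b=cav_b | band_b,
        mask_cavity_a=cav_a,
        mask_cervical_a=band_a,
        mask_cavity_b=cav_b,
        mask_cervical_b=band_b,
        truth_factors={
            "age": age,
            "cavity_intensity": config.cavity_intensity(age),
            "band_intensity": config.band_intensity(age),
            "jitter_a": tuple(jit_a),
            "jitter_b": tuple(jit_b),
        },
    )


def _sample_ages(n: int, config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Integer ages, uniform over the range or weighted by decade."""
    lo, hi = config.age_range
    if config.decade_weights is None:
        return rng.integers(lo, hi + 1, size=n)
    w = np.asarray(config.decade_weights, dtype=float)
    w = w / w.sum()
    decades = rng.choice(len(DECADES), size=n, p=w)
    ages = np.empty(n, dtype=int)
    for i, d in enumerate(decades):
        dlo, dhi = DECADES[d]
        ages[i] = rng.integers(max(dlo, lo), min(dhi, hi) + 1)
    return ages


def generate_dataset(n_subjects: int, config: PhantomConfig) -> list[SubjectRecord]:
    """Generate ``n_subjects`` seeded subjects (ages uniform, sides 50/50)."""
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    rng = np.random.default_rng(config.seed)
    ages = _sample_ages(n_subjects, config, rng)
    sides = rng.choice(["L", "R"], size=n_subjects)
    return [
        generate_subject(int(ages[i]), str(sides[i]), config, rng,
                         subject_id=f"S{i:04d}")
        for i in range(n_subjects)
    ]


def mirror_image(img: np.ndarray) -> np.ndarray:
    """Horizontal flip (columns reversed); an involution on square images.

    Left-side tooth images are mirrored before training so laterality does
    not enter the learned representation.
    """
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError(f"expected a square 2-D image, got shape {img.shape}")
    return img[:, ::-1].copy()


def noise_free(config: PhantomConfig | None = None) -> PhantomConfig:
    """The noise-free variant of a config (no pixel noise, no jitter)."""
    base = config or PhantomConfig()
    return replace(base, noise_sd=0.0, nuisance_sd=0.0)
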