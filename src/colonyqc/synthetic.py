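"""Seeded synthetic iPSC-colony images and abstract feature tables.

The real grading problem distinguishes three colony phenotypes by texture
and edge morphology: *good* colonies are rounded with even translucent
color and sharply defined edges; *semigood* colonies show changed color or
internal structure but still clear edges; *bad* colonies have partially
lost edge structure and show vacuoles and three-dimensional areas.  The
generator emulates exactly those statistics — an elliptical colony on a
lighter background, with a controllable boundary blur (edge definition),
band-limited interior texture (color evenness), dark circular vacuoles and
bright dome-like bumps (3-D proxies) — and nothing else.  It makes no
attempt at photorealism: no feeder-cell layer, no illumination gradient,
no microscope optics.

Everything is a pure function of its spec, including the seed: identical
spec + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidSpecError
from .features import CLASS_NAMES, FeatureTable, as_class_code

#: default class composition (bad, good, semigood) of the benchmark dataset
DEFAULT_N_PER_CLASS = (41, 74, 58)

# Morphology presets per class code.  Orderings are part of the contract:
# edge_sharpness good > semigood > bad; texture_heterogeneity good <
# semigood < bad; vacuoles/bumps only appear outside class good.
CLASS_PRESETS = {
    1: dict(edge_sharpness=0.25, texture_heterogeneity=0.80, vacuole_count=2, bump_count=2),
    2: dict(edge_sharpness=0.90, texture_heterogeneity=0.15, vacuole_count=0, bump_count=0),
    3: dict(edge_sharpness=0.65, texture_heterogeneity=0.45, vacuole_count=0, bump_count=1),
}

#: intensity of vacuole interiors; far darker than any texture excursion,
#: so vacuoles are recoverable by thresholding the colony interior
VACUOLE_INTENSITY = 0.05
#: threshold separating vacuoles from ordinary interior texture
VACUOLE_THRESHOLD = 0.25


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Specification of one synthetic colony image.

    Morphology knobs left as ``None`` take the preset of ``class_label``.
    """

    class_label: int | str
    width: int = 256
    height: int = 256
    seed: int = 0
    edge_sharpness: float | None = None
    texture_heterogeneity: float | None = None
    vacuole_count: int | None = None
    bump_count: int | None = None

    def __post_init__(self):
        code = as_class_code(self.class_label)
        object.__setattr__(self, "class_label", code)
        preset = CLASS_PRESETS[code]
        for knob in ("edge_sharpness", "texture_heterogeneity", "vacuole_count", "bump_count"):
            if getattr(self, knob) is None:
                object.__setattr__(self, knob, preset[knob])
        if not (0.0 <= self.edge_sharpness <= 1.0):
            raise InvalidSpecError("edge_sharpness must lie in [0, 1]")
        if not (0.0 <= self.texture_heterogeneity <= 1.0):
            raise InvalidSpecError("texture_heterogeneity must lie in [0, 1]")
        if self.vacuole_count < 0 or self.bump_count < 0:
            raise InvalidSpecError("vacuole_count and bump_count must be >= 0")
        if self.width < 64 or self.height < 64:
            raise InvalidSpecError(
                f"image {self.width}x{self.height} too small to contain a colony (min 64)"
            )


def _band_limited_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """White noise low-passed at scale ``sigma`` and renormalized to unit sd."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma)
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_colony_image(spec: SyntheticImageSpec) -> np.ndarray:
    """Render one grayscale colony image in [0, 1].

    The colony is a smoothed ellipse darker than the background.  Edge
    sharpness maps to the Gaussian blur width of the colony boundary;
    texture heterogeneity scales band-limited interior noise; vacuoles are
    dark disks and bumps are bright Gaussian domes placed disjointly inside
    the colony.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    scale = min(h, w)

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy = h / 2 + rng.uniform(-0.03, 0.03) * h
    cx = w / 2 + rng.uniform(-0.03, 0.03) * w
    ry = rng.uniform(0.28, 0.36) * h
    rx = rng.uniform(0.28, 0.36) * w
    theta = rng.uniform(0, np.pi)
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    ellipse = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0

    # boundary softness: sharp edges -> sub-pixel blur, lost edges -> wide blur
    edge_sigma = 0.5 + (1.0 - spec.edge_sharpness) * 0.05 * scale
    soft = ndimage.gaussian_filter(ellipse.astype(np.float64), edge_sigma)

    background = 0.88 + 0.02 * _band_limited_noise(rng, (h, w), 0.08 * scale)

    amp = 0.22 * spec.texture_heterogeneity
    texture = (
        0.55
        + amp * _band_limited_noise(rng, (h, w), 0.015 * scale)
        + 0.5 * amp * _band_limited_noise(rng, (h, w), 0.05 * scale)
    )
    # floor the ordinary texture well above VACUOLE_THRESHOLD so vacuoles
    # are the only interior structures recoverable by thresholding
    texture = np.maximum(texture, 0.35)

    # bright dome-like bumps: proxies for three-dimensional areas
    centers = _disjoint_centers(
        rng, spec.bump_count + spec.vacuole_count, cx, cy, rx, ry, theta,
        radius=0.05 * scale,
    )
    bump_centers = centers[: spec.bump_count]
    vac_centers = centers[spec.bump_count:]
    for bx, by in bump_centers:
        r2 = (xx - bx) ** 2 + (yy - by) ** 2
        texture += 0.20 * np.exp(-r2 / (2 * (0.04 * scale) ** 2))

    # dark circular vacuoles, drawn last so nothing overwrites them
    for vx, vy in vac_centers:
        disk = (xx - vx) ** 2 + (yy - vy) ** 2 <= (0.035 * scale) ** 2
        texture[disk] = VACUOLE_INTENSITY

    img = background * (1.0 - soft) + texture * soft
    return np.clip(img, 0.0, 1.0)


def _disjoint_centers(rng, count, cx, cy, rx, ry, theta, radius):
    """Rejection-sample ``count`` disjoint centers well inside the ellipse."""
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < count and attempts < 1000:
        attempts += 1
        px = cx + rng.uniform(-0.55, 0.55) * rx
        py = cy + rng.uniform(-0.55, 0.55) * ry
        du = (px - cx) * np.cos(theta) + (py - cy) * np.sin(theta)
        dv = -(px - cx) * np.sin(theta) + (py - cy) * np.cos(theta)
        if (du / rx) ** 2 + (dv / ry) ** 2 > 0.45:  # keep clear of the boundary
            continue
        if any((px - qx) ** 2 + (py - qy) ** 2 < (2.5 * radius) ** 2 for qx, qy in centers):
            continue
        centers.append((px, py))
    if len(centers) < count:
        raise InvalidSpecError(
            f"could not place {count} disjoint structures inside the colony"
        )
    return centers


def generate_image_dataset(
    n_per_class=DEFAULT_N_PER_CLASS,
    base_seed: int = 0,
    width: int = 256,
    height: int = 256,
) -> list[tuple[np.ndarray, int]]:
    """Generate a labeled image dataset, classes in blocks (bad, good, semigood).

    Per-image seeds are ``base_seed + image_index``, so the dataset is
    reproducible while every image is distinct.
    """
    counts = tuple(int(c) for c in n_per_class)
    if len(counts) != 3 or any(c < 0 for c in counts):
        raise InvalidSpecError("n_per_class must be three non-negative counts")
    out = []
    index = 0
    for code, count in zip(sorted(CLASS_NAMES), counts):
        for _ in range(count):
            spec = SyntheticImageSpec(
                code, width=width, height=height, seed=base_seed + index
            )
            out.append((generate_colony_image(spec), code))
            index += 1
    return out


def write_image_dataset(dataset, out_dir) -> Path:
    """Write images as 8-bit grayscale PNGs plus a manifest CSV (path, label).

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, (img, label) in enumerate(dataset):
        name = f"{CLASS_NAMES[label]}_{i:04d}.png"
        iio.imwrite(out_dir / name, (np.round(img * 255)).astype(np.uint8))
        records.append({"path": name, "label": CLASS_NAMES[label]})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest


@dataclass(frozen=True)
class SyntheticFeatureSpec:
    """Abstract Gaussian-blob feature table, for testing classifiers
    without running SIFT.

    ``class_means`` defaults to centers ``separation * within_class_sd``
    apart along distinct coordinate axes (order bad, good, semigood).
    """

    n_per_class: tuple = DEFAULT_N_PER_CLASS
    dim: int = 128
    within_class_sd: float = 1.0
    class_means: np.ndarray | None = None
    separation: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.dim < 1:
            raise InvalidSpecError("dim must be >= 1")
        if np.any(np.asarray(self.within_class_sd) <= 0):
            raise InvalidSpecError("within_class_sd must be > 0")
        counts = tuple(int(c) for c in self.n_per_class)
        if len(counts) != 3 or any(c < 0 for c in counts):
            raise InvalidSpecError("n_per_class must be three non-negative counts")
        object.__setattr__(self, "n_per_class", counts)
        if self.class_means is None:
            # Spike two coordinates per class (one when dim < 6) so every
            # distance family — including rank-based measures — sees the
            # class signal; pairwise mean separation is separation*sd exactly.
            sd = float(np.max(self.within_class_sd))
            means = np.zeros((3, self.dim))
            if self.dim >= 6:
                for c in range(3):
                    means[c, 2 * c] = self.separation * sd / 2.0
                    means[c, 2 * c + 1] = self.separation * sd / 2.0
            else:
                for c in range(3):
                    means[c, c % self.dim] = self.separation * sd / np.sqrt(2.0)
            object.__setattr__(self, "class_means", means)
        else:
            means = np.asarray(self.class_means, dtype=np.float64)
            if means.shape != (3, self.dim):
                raise InvalidSpecError(
                    f"class_means must be (3, {self.dim}); got {means.shape}"
                )
            object.__setattr__(self, "class_means", means)


def generate_feature_table(spec: SyntheticFeatureSpec) -> FeatureTable:
    """Draw per-class Gaussian feature rows, classes in blocks (bad, good, semigood)."""
    rng = np.random.default_rng(spec.seed)
    feats, labels, ids = [], [], []
    for c, (code, count) in enumerate(zip(sorted(CLASS_NAMES), spec.n_per_class)):
        block = spec.class_means[c] + spec.within_class_sd * rng.standard_normal(
            (count, spec.dim)
        )
        feats.append(block)
        labels.extend([code] * count)
        ids.extend([f"{CLASS_NAMES[code]}_{i:04d}" for i in range(count)])
    return FeatureTable(np.vstack(feats), np.asarray(labels), ids)
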