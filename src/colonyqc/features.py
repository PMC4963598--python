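"""Image loading, SIFT extraction, and mean-descriptor features.

Each colony image is reduced to a single 128-dimensional feature vector:
the element-wise arithmetic mean of all of its SIFT descriptors.  Averaging
bypasses bag-of-features codebook construction entirely — no clustering,
no codebook size to tune — at the cost of discarding the spatial layout of
the keypoints.

Images are treated as 2-D float arrays with intensities in [0, 1]; loading
rescales by the bit depth of the source file so that 8-bit 255 and 16-bit
65535 both map to 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.feature import SIFT

from .errors import DimensionMismatchError, ImageError, NoKeypointsError

DESCRIPTOR_DIM = 128

#: integer class codes and their names, in code order
CLASS_NAMES = {1: "bad", 2: "good", 3: "semigood"}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}

# Significant digits used when feature tables are written as CSV text.
# 17 significant decimal digits round-trip IEEE-754 doubles exactly.
CSV_FLOAT_FORMAT = "%.17g"


def as_class_code(label) -> int:
    """Normalize a class label (name or code) to its integer code."""
    if isinstance(label, str):
        try:
            return CLASS_CODES[label.lower()]
        except KeyError:
            raise ImageError(f"unknown class label {label!r}") from None
    code = int(label)
    if code not in CLASS_NAMES:
        raise ImageError(f"unknown class code {label!r}; expected 1, 2 or 3")
    return code


@dataclass(frozen=True)
class DescriptorSet:
    """All SIFT descriptors of one image plus their keypoint frames.

    ``frames`` columns are (x, y, scale, orientation) with x = column,
    y = row, both 0-based.
    """

    descriptors: np.ndarray  # (n, 128) float64, non-negative
    frames: np.ndarray  # (n, 4) float64

    def __post_init__(self):
        d = np.asarray(self.descriptors, dtype=np.float64)
        f = np.asarray(self.frames, dtype=np.float64)
        if d.ndim != 2 or d.shape[1] != DESCRIPTOR_DIM:
            raise DimensionMismatchError(
                f"descriptors must be (n, {DESCRIPTOR_DIM}); got {d.shape}"
            )
        if f.shape != (d.shape[0], 4):
            raise DimensionMismatchError(
                f"frames must be ({d.shape[0]}, 4); got {f.shape}"
            )
        object.__setattr__(self, "descriptors", d)
        object.__setattr__(self, "frames", f)

    def __len__(self) -> int:
        return self.descriptors.shape[0]


@dataclass(frozen=True)
class FeatureVector:
    """The mean SIFT descriptor representing one image."""

    values: np.ndarray  # (128,) float64, finite
    image_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (DESCRIPTOR_DIM,):
            raise DimensionMismatchError(
                f"feature vector must have length {DESCRIPTOR_DIM}; got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ImageError(f"non-finite feature values for image {self.image_id!r}")
        object.__setattr__(self, "values", v)


@dataclass
class FeatureTable:
    """N feature rows with integer class labels in {1, 2, 3} and provenance ids."""

    features: np.ndarray  # (N, d) float64
    labels: np.ndarray  # (N,) int
    ids: list = field(default_factory=list)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise DimensionMismatchError("features must be a 2-D matrix")
        if self.labels.shape != (self.features.shape[0],):
            raise DimensionMismatchError("labels must match feature rows")
        if not self.ids:
            self.ids = [f"row{i:04d}" for i in range(len(self.labels))]
        if len(self.ids) != len(self.labels):
            raise DimensionMismatchError("ids must match feature rows")
        bad = set(np.unique(self.labels)) - set(CLASS_NAMES)
        if bad:
            raise ImageError(f"labels restricted to {sorted(CLASS_NAMES)}; got {bad}")

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, mask_or_index) -> "FeatureTable":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FeatureTable(
            self.features[idx],
            self.labels[idx],
            [self.ids[i] for i in idx],
        )


def load_image(path) -> np.ndarray:
    """Load a PNG/TIFF/JPEG as a grayscale float image in [0, 1].

    Multi-channel images are converted by Rec. 601 luminance; integer pixel
    values are divided by the maximum of the source dtype.
    """
    path = Path(path)
    if not path.exists():
        raise ImageError(f"image file does not exist: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - wrap any backend failure
        raise ImageError(f"could not read image {path}: {exc}") from exc
    return _to_unit_gray(arr, str(path))


def _to_unit_gray(arr: np.ndarray, origin: str = "") -> np.ndarray:
    # bit depth of the source pixels, before any float conversion below
    scale = float(np.iinfo(arr.dtype).max) if np.issubdtype(arr.dtype, np.integer) else None
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[..., :3]
        if arr.shape[2] == 3:
            # Rec. 601 luminance; weights sum to 1 so gray stays gray
            arr = (
                0.299 * arr[..., 0].astype(np.float64)
                + 0.587 * arr[..., 1]
                + 0.114 * arr[..., 2]
            )
        elif arr.shape[2] == 1:
            arr = arr[..., 0]
        else:
            raise ImageError(f"unsupported channel count in {origin}: {arr.shape}")
    elif arr.ndim != 2:
        raise ImageError(f"unsupported image shape in {origin}: {arr.shape}")
    out = arr.astype(np.float64)
    if scale is not None:
        out = out / scale
    if not np.all(np.isfinite(out)):
        raise ImageError(f"non-finite pixel values in {origin}")
    return np.clip(out, 0.0, 1.0)


def extract_sift_descriptors(image: np.ndarray) -> DescriptorSet:
    """Run SIFT at default parameters and return descriptors + frames.

    A featureless image (e.g. constant intensity) yields an empty
    DescriptorSet rather than an error.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ImageError(f"expected a non-empty 2-D image; got shape {img.shape}")
    sift = SIFT()
    try:
        sift.detect_and_extract(img)
    except RuntimeError:
        # backend signals "no features found" as a runtime error
        return DescriptorSet(
            np.empty((0, DESCRIPTOR_DIM)), np.empty((0, 4))
        )
    desc = sift.descriptors.astype(np.float64)
    # keypoints are (row, col); frames use x = col, y = row
    frames = np.column_stack(
        [
            sift.keypoints[:, 1].astype(np.float64),
            sift.keypoints[:, 0].astype(np.float64),
            sift.scales.astype(np.float64),
            sift.orientations.astype(np.float64),
        ]
    )
    return DescriptorSet(desc, frames)


def mean_descriptor(dset: DescriptorSet, image_id: str = "") -> FeatureVector:
    """Element-wise arithmetic mean over all descriptors of one image."""
    if len(dset) == 0:
        raise NoKeypointsError(
            f"image {image_id!r} produced no SIFT keypoints; no mean descriptor exists"
        )
    return FeatureVector(dset.descriptors.mean(axis=0), image_id)


def build_feature_table(
    images: Sequence, ids: Sequence[str] | None = None
) -> FeatureTable:
    """Reduce labeled images [(image, label), ...] to an N x 128 feature table.

    Row order follows input order.  An image with zero keypoints aborts the
    build, reporting the offending image id.
    """
    images = list(images)
    if not images:
        raise ImageError("cannot build a feature table from zero images")
    if ids is None:
        ids = [f"img{i:04d}" for i in range(len(images))]
    rows, labels = [], []
    for (img, label), image_id in zip(images, ids):
        dset = extract_sift_descriptors(img)
        rows.append(mean_descriptor(dset, image_id).values)
        labels.append(as_class_code(label))
    return FeatureTable(np.vstack(rows), np.asarray(labels), list(ids))


def write_feature_csv(table: FeatureTable, path) -> None:
    """Write a feature table as CSV: columns id,label,f001..f128 (or f{d}).

    Floats are printed with 17 significant digits (stated in the header
    comment), which reproduces IEEE doubles bit-exactly on re-read.
    """
    d = table.n_features
    cols = [f"f{j + 1:03d}" for j in range(d)]
    df = pd.DataFrame(table.features, columns=cols)
    df.insert(0, "label", table.labels)
    df.insert(0, "id", table.ids)
    with open(path, "w") as fh:
        fh.write(f"# colonyqc feature table; float format {CSV_FLOAT_FORMAT}\n")
        df.to_csv(fh, index=False, float_format=CSV_FLOAT_FORMAT)


def read_feature_csv(path) -> FeatureTable:
    """Inverse of :func:`write_feature_csv`."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    feature_cols = [c for c in df.columns if c.startswith("f")]
    return FeatureTable(
        df[feature_cols].to_numpy(dtype=np.float64),
        df["label"].to_numpy(dtype=int),
        df["id"].astype(str).tolist(),
    )


def read_manifest(path) -> list[tuple[Path, int]]:
    """Read a dataset manifest CSV with columns path,label."""
    df = pd.read_csv(path)
    base = Path(path).parent
    out = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        out.append((p, as_class_code(row["label"])))
    return out
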