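"""Distance-weighted k-nearest-neighbor classifier.

Seven distance measures (Chebyshev, cityblock, correlation, cosine,
Euclidean, standardized Euclidean, Spearman) crossed with three distance
weightings (equal, inverse, squared inverse).  k is kept odd to reduce
ties; a residual score tie is broken by a seeded random choice between the
tied classes.

Correlation, cosine and Spearman "distances" are the 1 - similarity forms;
Spearman uses average ranks for tied values.  Standardized Euclidean
divides each squared coordinate difference by a per-feature squared scale,
normally the training fold's per-feature sample standard deviation.

The tie-break RNG stream is derived from (rng_seed, CRC32 of the query
vector's bytes), so replays are bit-identical and results do not depend on
the order in which test points are evaluated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateDataError, DimensionMismatchError, InvalidSpecError

MEASURES = (
    "chebyshev",
    "cityblock",
    "correlation",
    "cosine",
    "euclidean",
    "std_euclidean",
    "spearman",
)
WEIGHTINGS = ("equal", "inverse", "squared_inverse")

#: the k grid used by nested-LOO selection: odd values 1..23 (12 values)
K_GRID = tuple(range(1, 24, 2))


@dataclass(frozen=True)
class KnnSpec:
    k: int = 1
    measure: str = "euclidean"
    weighting: str = "equal"
    rng_seed: int = 0

    def __post_init__(self):
        if self.k < 1 or self.k % 2 == 0:
            raise InvalidSpecError(f"k must be a positive odd integer; got {self.k}")
        if self.measure not in MEASURES:
            raise InvalidSpecError(f"measure must be one of {MEASURES}")
        if self.weighting not in WEIGHTINGS:
            raise InvalidSpecError(f"weighting must be one of {WEIGHTINGS}")


def _center_norm(v: np.ndarray) -> np.ndarray:
    c = v - v.mean()
    n = np.linalg.norm(c)
    if n == 0:
        raise DegenerateDataError("zero-variance vector for a correlation-type distance")
    return c / n


def distance(measure: str, x, y, train_sd=None) -> float:
    """Distance between two vectors under one of the seven measures."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise DimensionMismatchError(f"vectors disagree: {x.shape} vs {y.shape}")
    diff = x - y
    if measure == "chebyshev":
        return float(np.max(np.abs(diff)))
    if measure == "cityblock":
        return float(np.sum(np.abs(diff)))
    if measure == "euclidean":
        return float(np.linalg.norm(diff))
    if measure == "std_euclidean":
        sd = np.ones_like(x) if train_sd is None else np.asarray(train_sd, dtype=np.float64)
        if np.any(sd <= 0):
            raise DegenerateDataError("std_euclidean requires positive per-feature scales")
        return float(np.sqrt(np.sum(diff**2 / sd**2)))
    if measure == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            raise DegenerateDataError("cosine distance undefined for a zero vector")
        return float(1.0 - np.dot(x, y) / (nx * ny))
    if measure == "correlation":
        return float(1.0 - np.dot(_center_norm(x), _center_norm(y)))
    if measure == "spearman":
        rx, ry = rankdata(x), rankdata(y)  # average ranks on ties
        return float(1.0 - np.dot(_center_norm(rx), _center_norm(ry)))
    raise InvalidSpecError(f"unknown measure {measure!r}")


def distances_to(measure: str, X: np.ndarray, x: np.ndarray, train_sd=None) -> np.ndarray:
    """Vectorized distance from every row of X to x."""
    X = np.asarray(X, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if X.shape[1] != x.shape[0]:
        raise DimensionMismatchError(f"expected {X.shape[1]} features; got {x.shape[0]}")
    diff = X - x
    if measure == "chebyshev":
        return np.max(np.abs(diff), axis=1)
    if measure == "cityblock":
        return np.sum(np.abs(diff), axis=1)
    if measure == "euclidean":
        return np.sqrt(np.sum(diff**2, axis=1))
    if measure == "std_euclidean":
        sd = np.ones(X.shape[1]) if train_sd is None else np.asarray(train_sd, dtype=np.float64)
        if np.any(sd <= 0):
            raise DegenerateDataError("std_euclidean requires positive per-feature scales")
        return np.sqrt(np.sum(diff**2 / sd**2, axis=1))
    if measure == "cosine":
        nx = np.linalg.norm(X, axis=1)
        n = np.linalg.norm(x)
        if n == 0 or np.any(nx == 0):
            raise DegenerateDataError("cosine distance undefined for a zero vector")
        return 1.0 - (X @ x) / (nx * n)
    if measure == "correlation":
        Xc = X - X.mean(axis=1, keepdims=True)
        nrm = np.linalg.norm(Xc, axis=1)
        if np.any(nrm == 0):
            raise DegenerateDataError("zero-variance vector for a correlation-type distance")
        return 1.0 - (Xc / nrm[:, None]) @ _center_norm(x)
    if measure == "spearman":
        Rx = rankdata(X, axis=1)
        r = _center_norm(rankdata(x))
        Rc = Rx - Rx.mean(axis=1, keepdims=True)
        nrm = np.linalg.norm(Rc, axis=1)
        if np.any(nrm == 0):
            raise DegenerateDataError("zero-variance vector for a correlation-type distance")
        return 1.0 - (Rc / nrm[:, None]) @ r
    raise InvalidSpecError(f"unknown measure {measure!r}")


def _tie_rng(spec: KnnSpec, x: np.ndarray) -> np.random.Generator:
    key = zlib.crc32(np.ascontiguousarray(x).tobytes()) & 0x7FFFFFFF
    return np.random.default_rng([spec.rng_seed & 0x7FFFFFFF, key])


def knn_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    x: np.ndarray,
    spec: KnnSpec,
    train_sd=None,
) -> int:
    """Classify one point by its k nearest training rows.

    Distance ties at the k-th position are broken by lowest row index.
    Neighbors at distance exactly 0 carry all weight under the inverse
    weightings (majority among them).  Exact class-score ties are broken
    by a seeded uniform random choice between the tied classes.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    train_y = np.asarray(train_y, dtype=int)
    x = np.asarray(x, dtype=np.float64)
    d = distances_to(spec.measure, train_X, x, train_sd=train_sd)
    return predict_from_distances(d, train_y, x, spec)


def predict_from_distances(
    d: np.ndarray, train_y: np.ndarray, x: np.ndarray, spec: KnnSpec
) -> int:
    """The k-NN decision given precomputed distances to every training row.

    Exposed separately so grid search over k can reuse one distance pass."""
    train_y = np.asarray(train_y, dtype=int)
    n = d.shape[0]
    if spec.k > n:
        raise DegenerateDataError(f"k={spec.k} exceeds {n} training rows")
    idx = np.argsort(d, kind="stable")[: spec.k]  # stable: lowest index wins ties
    nd, ny = d[idx], train_y[idx]

    if spec.weighting == "equal":
        weights = np.ones_like(nd)
    elif np.any(nd == 0):
        weights = (nd == 0).astype(np.float64)  # zero-distance neighbors dominate
    elif spec.weighting == "inverse":
        weights = 1.0 / nd
    else:  # squared_inverse
        weights = 1.0 / nd**2

    classes = np.unique(ny)
    scores = np.array([weights[ny == c].sum() for c in classes])
    top = scores.max()
    tied = classes[scores == top]
    if len(tied) == 1:
        return int(tied[0])
    return int(_tie_rng(spec, x).choice(tied))
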