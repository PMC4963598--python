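"""Parameterless baseline classifiers evaluated under plain LOO.

Five methods: a Gini classification tree grown without depth limit or
pruning, linear discriminant analysis, multinomial logistic regression,
Gaussian naive Bayes, and naive Bayes with per-feature kernel-density
estimation under normal / box / Epanechnikov / triangle kernels (eight
configurations in total, counting the four KDE kernels).

Tree, LDA, MLR and Gaussian NB delegate to scikit-learn.  LDA first checks
that the pooled within-class covariance has full rank and fails loudly
otherwise — the same singular-covariance failure mode that rules out QDA
and the Mahalanobis discriminant when the feature dimension (128) exceeds
the per-class sample counts.  QDA and the Mahalanobis discriminant are
deliberately not implemented for that reason.

The KDE naive Bayes is written here: class priors are training class
proportions; each class x feature pair gets a 1-D KDE whose bandwidth
follows the normal-reference (Silverman) rule
h = 0.9 * min(sd, IQR/1.34) * n^(-1/5), logged per fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from .errors import (
    DegenerateDataError,
    DimensionMismatchError,
    InvalidSpecError,
    SingularSystemError,
)

logger = logging.getLogger(__name__)

METHODS = ("tree", "lda", "mlr", "nb", "nb_kde")
KDE_KERNELS = ("normal", "box", "epanechnikov", "triangle")


@dataclass(frozen=True)
class BaselineSpec:
    method: str
    kde_kernel: str | None = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise InvalidSpecError(f"method must be one of {METHODS}")
        if self.method == "nb_kde":
            if self.kde_kernel not in KDE_KERNELS:
                raise InvalidSpecError(f"nb_kde requires kde_kernel in {KDE_KERNELS}")
        elif self.kde_kernel is not None:
            raise InvalidSpecError("kde_kernel is only valid for nb_kde")


def all_baseline_specs() -> list[BaselineSpec]:
    """The eight baseline configurations."""
    out = [BaselineSpec(m) for m in ("tree", "lda", "mlr", "nb")]
    out += [BaselineSpec("nb_kde", k) for k in KDE_KERNELS]
    return out


# --- 1-D kernels (unit-integral densities on their support) ------------------

def _kernel_density(kernel: str, u: np.ndarray) -> np.ndarray:
    if kernel == "normal":
        return np.exp(-0.5 * u**2) / np.sqrt(2 * np.pi)
    a = np.abs(u)
    if kernel == "box":
        return np.where(a <= 1.0, 0.5, 0.0)
    if kernel == "epanechnikov":
        return np.where(a <= 1.0, 0.75 * (1.0 - u**2), 0.0)
    if kernel == "triangle":
        return np.where(a <= 1.0, 1.0 - a, 0.0)
    raise InvalidSpecError(f"unknown KDE kernel {kernel!r}")


def silverman_bandwidth(values: np.ndarray) -> float:
    """Normal-reference rule per feature per class; falls back to 1.0 when
    the spread is zero (a constant feature within a class)."""
    v = np.asarray(values, dtype=np.float64)
    n = v.size
    sd = v.std(ddof=1)
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * scale * n ** (-1 / 5)
    return float(h) if h > 0 else 1.0


class KDENaiveBayes:
    """Naive Bayes with per-class per-feature 1-D kernel-density estimates."""

    def __init__(self, kernel: str):
        self.kernel = kernel
        self.classes_: np.ndarray | None = None
        self.priors_: np.ndarray | None = None
        self._samples: list[np.ndarray] = []  # per class: (n_c, d)
        self._bandwidths: list[np.ndarray] = []  # per class: (d,)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KDENaiveBayes":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        self._samples, self._bandwidths = [], []
        for c in self.classes_:
            rows = X[y == c]
            if rows.shape[0] < 2:
                raise DegenerateDataError(
                    f"class {c} has {rows.shape[0]} row(s); density estimation needs >= 2"
                )
            hs = np.array([silverman_bandwidth(rows[:, j]) for j in range(X.shape[1])])
            logger.debug("KDE NB class %s bandwidths: %s", c, hs)
            self._samples.append(rows)
            self._bandwidths.append(hs)
        return self

    def class_feature_density(self, class_index: int, feature: int, grid: np.ndarray) -> np.ndarray:
        """KDE density of one class/feature evaluated on a grid (for checks)."""
        v = self._samples[class_index][:, feature]
        h = self._bandwidths[class_index][feature]
        u = (grid[:, None] - v[None, :]) / h
        return _kernel_density(self.kernel, u).mean(axis=1) / h

    def _joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        out = np.empty((X.shape[0], len(self.classes_)))
        with np.errstate(divide="ignore"):  # zero density outside support -> -inf
            for ci in range(len(self.classes_)):
                v, h = self._samples[ci], self._bandwidths[ci]
                u = (X[:, None, :] - v[None, :, :]) / h  # (n, n_c, d)
                dens = _kernel_density(self.kernel, u).mean(axis=1) / h
                out[:, ci] = np.log(self.priors_[ci]) + np.log(dens).sum(axis=1)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        jll = self._joint_log_likelihood(np.atleast_2d(X))
        # argmax takes the lowest class index on posterior ties (documented)
        return self.classes_[np.argmax(jll, axis=1)]


def _check_lda_covariance(X: np.ndarray, y: np.ndarray) -> None:
    """Reject LDA fits whose pooled within-class covariance is singular."""
    X = np.asarray(X, dtype=np.float64)
    classes = np.unique(y)
    d = X.shape[1]
    pooled = np.zeros((d, d))
    for c in classes:
        rows = X[y == c]
        centered = rows - rows.mean(axis=0)
        pooled += centered.T @ centered
    dof = X.shape[0] - len(classes)
    if dof < 1:
        raise DegenerateDataError("too few rows for LDA")
    pooled /= dof
    rank = np.linalg.matrix_rank(pooled)
    if rank < d:
        raise SingularSystemError(
            f"pooled within-class covariance is singular (rank {rank} < dim {d}); "
            "discriminant analysis requires an invertible covariance"
        )


def fit_baseline(spec: BaselineSpec, X: np.ndarray, y: np.ndarray):
    """Fit the named baseline on (already standardized) training data."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("need at least 2 classes")
    if spec.method == "tree":
        model = DecisionTreeClassifier(criterion="gini", random_state=0)
        logger.debug("classification tree: gini, no depth limit, no pruning")
        return model.fit(X, y)
    if spec.method == "lda":
        _check_lda_covariance(X, y)
        return LinearDiscriminantAnalysis().fit(X, y)
    if spec.method == "mlr":
        # unpenalized multinomial fit (C=inf disables regularization)
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        return model.fit(X, y)
    if spec.method == "nb":
        return GaussianNB().fit(X, y)
    return KDENaiveBayes(spec.kde_kernel).fit(X, y)


def predict_baseline(model, x: np.ndarray) -> int:
    """Predicted class code for a single feature vector."""
    x = np.asarray(x, dtype=np.float64)
    expected = getattr(model, "n_features_in_", None)
    if expected is None and isinstance(model, KDENaiveBayes):
        expected = model._samples[0].shape[1]
    if expected is not None and x.shape[-1] != expected:
        raise DimensionMismatchError(f"expected {expected} features; got {x.shape[-1]}")
    return int(model.predict(np.atleast_2d(x))[0])
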