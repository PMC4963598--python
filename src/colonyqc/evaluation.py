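"""Evaluation protocols: z-scoring, plain and nested leave-one-out,
parameter grids, and performance measures.

Plain LOO (for parameterless classifiers): each example is held out in
turn; the training fold is z-score standardized, the held-out example is
scaled by the fold's own mu/sigma, and the classifier is fit and queried.
Standardization statistics therefore never include the held-out example.

Nested LOO (for k-NN and the SVM schemes) adds an inner LOO over each
training fold: every grid point is scored by inner-LOO accuracy (with
per-inner-fold standardization), the best point is selected — ties broken
by canonical grid order: ascending k, or ascending C then ascending
sigma — the model is refit on the whole training fold with the winner, and
the held-out example is predicted.  The selected parameter may differ from
fold to fold and is recorded per fold.

Grids follow the printed protocol: C and sigma range over
{2^-15, ..., 2^15} (31 values, 961 (C, sigma) pairs for the RBF kernel)
and k over the odd values {1, 3, ..., 23} (12 values).

Performance measures: per-class true positives (TP, the diagonal of the
confusion matrix), per-class true-positive rate (TPR, %), and accuracy
(%, trace over total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import BaselineSpec, fit_baseline, predict_baseline
from .errors import ColonyQCError, DegenerateDataError, InvalidSpecError
from .features import CLASS_NAMES, FeatureTable
from .knn import K_GRID, KnnSpec, distances_to, knn_predict, predict_from_distances
from .lssvm import KernelSpec
from .multiclass import (
    enumerate_dag_structures,
    enumerate_tree_orders,
    predict as multiclass_predict,
    train_ova,
    train_ovo,
    train_tree,
)

logger = logging.getLogger(__name__)


# --- parameter grids ---------------------------------------------------------

def svm_c_grid() -> list[float]:
    """The 31 regularization values 2^-15 .. 2^15."""
    return [float(2.0**e) for e in range(-15, 16)]


def svm_rbf_grid() -> list[tuple[float, float]]:
    """The 961 (C, sigma) pairs, canonical order: ascending C, then sigma."""
    g = svm_c_grid()
    return [(c, s) for c in g for s in g]


def knn_k_grid() -> list[int]:
    """The 12 odd neighbor counts 1, 3, ..., 23."""
    return list(K_GRID)


# --- standardization ---------------------------------------------------------

@dataclass(frozen=True)
class Scaler:
    """Per-feature z-scoring statistics of one training fold."""

    mu: np.ndarray
    sd: np.ndarray


def fit_scaler(train: np.ndarray) -> Scaler:
    """Column means and sample standard deviations; sd 0 is treated as 1
    so constant columns scale to exactly 0."""
    X = np.atleast_2d(np.asarray(train, dtype=np.float64))
    if X.size == 0:
        raise DegenerateDataError("cannot fit a scaler on empty data")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
    sd = np.where(sd > 0, sd, 1.0)
    return Scaler(mu, sd)


def apply_scaler(scaler: Scaler, rows: np.ndarray) -> np.ndarray:
    return (np.asarray(rows, dtype=np.float64) - scaler.mu) / scaler.sd


# --- results -----------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Confusion matrix plus the derived measures and per-fold selections."""

    confusion: np.ndarray  # (M, M) ints; rows true, columns predicted
    classes: tuple
    tp: np.ndarray  # per-class correct counts (diagonal)
    tpr: np.ndarray  # per-class rates, %
    accuracy: float  # %
    per_fold_params: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """One report row in the Bad/Good/Semigood TP (TPR%) + ACC layout."""
        row = {}
        for idx, c in enumerate(self.classes):
            name = CLASS_NAMES.get(c, str(c)).capitalize()
            row[name] = f"{int(self.tp[idx])} ({self.tpr[idx]:.1f}%)"
        row["ACC"] = f"{self.accuracy:.1f}%"
        return row


def performance_measures(confusion: np.ndarray):
    """(tp, tpr%, accuracy%) from a confusion matrix (rows = true class)."""
    cm = np.asarray(confusion, dtype=int)
    total = cm.sum()
    if total == 0:
        raise DegenerateDataError("confusion matrix is empty")
    tp = np.diag(cm).astype(int)
    sizes = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(sizes > 0, 100.0 * tp / sizes, np.nan)
    accuracy = 100.0 * tp.sum() / total
    return tp, tpr, float(accuracy)


def _confusion(classes, true, pred) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true, pred):
        cm[index[int(t)], index[int(p)]] += 1
    return cm


def _result(classes, true, pred, per_fold_params=None, provenance=None) -> EvaluationResult:
    cm = _confusion(classes, true, pred)
    tp, tpr, acc = performance_measures(cm)
    return EvaluationResult(
        cm, tuple(classes), tp, tpr, acc,
        per_fold_params or [], provenance or {},
    )


# --- leave-one-out protocols -------------------------------------------------

def loo_evaluate(classifier, table: FeatureTable, provenance=None) -> EvaluationResult:
    """Plain LOO: per fold, fit the scaler on the training rows only, fit the
    classifier on the scaled fold, and predict the scaled held-out example."""
    n = len(table)
    if n < 2:
        raise DegenerateDataError("LOO needs at least 2 examples")
    classes = tuple(int(c) for c in table.classes)
    if len(classes) < 2:
        raise DegenerateDataError("LOO needs at least 2 classes")
    preds = np.zeros(n, dtype=int)
    for i in range(n):
        mask = np.arange(n) != i
        tr = table.subset(mask)
        scaler = fit_scaler(tr.features)
        try:
            clf = classifier.clone() if hasattr(classifier, "clone") else classifier
            clf.fit(apply_scaler(scaler, tr.features), tr.labels)
            preds[i] = clf.predict_one(apply_scaler(scaler, table.features[i]))
        except ColonyQCError as exc:
            raise type(exc)(f"fold {i}: {exc}") from exc
        logger.info("LOO fold %d/%d: true=%d pred=%d", i + 1, n, table.labels[i], preds[i])
    return _result(classes, table.labels, preds, provenance=provenance)


def nested_loo_evaluate(
    family, grid, table: FeatureTable, provenance=None
) -> EvaluationResult:
    """Nested LOO: outer folds for assessment, inner LOO on each training
    fold for grid selection, per-inner-fold standardization throughout.

    A grid point whose fit fails anywhere in a fold is skipped (logged) for
    that fold rather than aborting the run.
    """
    n = len(table)
    grid = list(grid)
    if n < 3:
        raise DegenerateDataError("nested LOO needs at least 3 examples")
    if not grid:
        raise InvalidSpecError("parameter grid is empty")
    classes = tuple(int(c) for c in table.classes)
    preds = np.zeros(n, dtype=int)
    per_fold_params = []
    for i in range(n):
        tr = table.subset(np.arange(n) != i)
        m = len(tr)
        scores = np.zeros(len(grid))
        failed = np.zeros(len(grid), dtype=bool)
        for j in range(m):
            inner = tr.subset(np.arange(m) != j)
            scaler = fit_scaler(inner.features)
            Xj = apply_scaler(scaler, inner.features)
            xj = apply_scaler(scaler, tr.features[j])
            for g, p in enumerate(family.grid_predictions(grid, Xj, inner.labels, xj)):
                if p is None:
                    failed[g] = True
                elif p == tr.labels[j]:
                    scores[g] += 1
        scores[failed] = -np.inf
        if failed.any():
            logger.debug("fold %d: %d grid point(s) skipped after solver failure",
                         i, int(failed.sum()))
        if np.all(np.isneginf(scores)):
            raise DegenerateDataError(f"fold {i}: every grid point failed to train")
        # first maximum == canonical grid order on ties
        scaler = fit_scaler(tr.features)
        Xtr = apply_scaler(scaler, tr.features)
        xte = apply_scaler(scaler, table.features[i])
        for g in np.argsort(-scores, kind="stable"):
            if np.isneginf(scores[g]):
                raise DegenerateDataError(f"fold {i}: no trainable grid point at refit")
            try:
                clf = family.make(grid[g])
                clf.fit(Xtr, tr.labels)
                preds[i] = clf.predict_one(xte)
                per_fold_params.append(grid[g])
                break
            except ColonyQCError as exc:
                logger.debug("fold %d: refit failed at %r (%s); trying next", i, grid[g], exc)
                continue
        else:
            raise DegenerateDataError(f"fold {i}: refit failed for every grid point")
        logger.info("NLOO fold %d/%d: selected %r, true=%d pred=%d",
                    i + 1, n, per_fold_params[-1], table.labels[i], preds[i])
    return _result(classes, table.labels, preds, per_fold_params, provenance)


# --- classifier adapters -----------------------------------------------------
# All adapters present fit(X, y) / predict_one(x) over fold-standardized data.

SCHEMES = ("ova", "ovo", "dag", "tree")


class MulticlassSVMClassifier:
    """One multiclass LS-SVM arrangement at fixed kernel parameters.

    ``structure_id`` 1-3 selects the DAG root pair ((bad,good),
    (bad,semigood), (good,semigood)); 4-6 selects the tree elimination root
    (bad, good, semigood).
    """

    def __init__(self, scheme: str, kernel: KernelSpec, structure_id: int | None = None):
        if scheme not in SCHEMES:
            raise InvalidSpecError(f"scheme must be one of {SCHEMES}")
        validate_structure_id(scheme, structure_id)
        self.scheme = scheme
        self.kernel = kernel
        self.structure_id = structure_id
        self.model = None

    def fit(self, X, y):
        table = FeatureTable(np.asarray(X), np.asarray(y))
        classes = tuple(int(c) for c in table.classes)
        if self.scheme == "ova":
            self.model = train_ova(table, self.kernel)
        elif self.scheme == "ovo":
            self.model = train_ovo(table, self.kernel)
        elif self.scheme == "dag":
            self.model = train_ovo(table, self.kernel, scheme="dagsvm")
            self.model.structure = enumerate_dag_structures(classes)[self.structure_id - 1]
        else:
            order = enumerate_tree_orders(classes)[self.structure_id - 4]
            self.model = train_tree(table, self.kernel, order)
        return self

    def predict_one(self, x) -> int:
        return multiclass_predict(self.model, x)

    def clone(self) -> "MulticlassSVMClassifier":
        return MulticlassSVMClassifier(self.scheme, self.kernel, self.structure_id)


def validate_structure_id(scheme: str, structure_id: int | None) -> None:
    """Structure ids 1-3 belong to DAG models, 4-6 to tree models."""
    if scheme == "dag" and structure_id not in (1, 2, 3):
        raise InvalidSpecError("dag requires structure_id in 1..3")
    if scheme == "tree" and structure_id not in (4, 5, 6):
        raise InvalidSpecError("tree requires structure_id in 4..6")
    if scheme in ("ova", "ovo") and structure_id is not None:
        raise InvalidSpecError(f"{scheme} takes no structure_id")


class KnnClassifier:
    """k-NN over the standardized fold; per-feature sd of the current
    training rows feeds the standardized-Euclidean measure."""

    def __init__(self, spec: KnnSpec):
        self.spec = spec
        self.X = self.y = self.sd = None

    def fit(self, X, y):
        self.X = np.asarray(X, dtype=np.float64)
        self.y = np.asarray(y, dtype=int)
        if self.X.shape[0] > 1:
            sd = self.X.std(axis=0, ddof=1)
            self.sd = np.where(sd > 0, sd, 1.0)
        else:
            self.sd = np.ones(self.X.shape[1])
        return self

    def predict_one(self, x) -> int:
        return knn_predict(self.X, self.y, x, self.spec, train_sd=self.sd)

    def clone(self) -> "KnnClassifier":
        return KnnClassifier(self.spec)


class BaselineClassifier:
    """Parameterless baseline behind the fit/predict_one protocol."""

    def __init__(self, spec: BaselineSpec):
        self.spec = spec
        self.model = None

    def fit(self, X, y):
        self.model = fit_baseline(self.spec, X, y)
        return self

    def predict_one(self, x) -> int:
        return predict_baseline(self.model, x)

    def clone(self) -> "BaselineClassifier":
        return BaselineClassifier(self.spec)


# --- classifier families (parameterized, for nested LOO) ---------------------

class ClassifierFamily:
    """A fit/predict pair parameterized by one grid point."""

    def make(self, param):
        raise NotImplementedError

    def grid_predictions(self, grid, X, y, x):
        """Predicted label of x for every grid point; None marks a point
        whose fit failed (skipped-and-logged by the caller)."""
        out = []
        for p in grid:
            try:
                out.append(self.make(p).fit(X, y).predict_one(x))
            except ColonyQCError as exc:
                logger.debug("grid point %r failed: %s", p, exc)
                out.append(None)
        return out


class SVMFamily(ClassifierFamily):
    """Multiclass LS-SVM family over C (or (C, sigma) for rbf).

    One shared grid point governs every sub-classifier of the scheme."""

    def __init__(self, scheme: str, kernel_shape: KernelSpec, structure_id: int | None = None):
        validate_structure_id(scheme, structure_id)
        self.scheme = scheme
        self.kernel_shape = kernel_shape
        self.structure_id = structure_id

    def make(self, param) -> MulticlassSVMClassifier:
        if self.kernel_shape.family == "rbf":
            c, sigma = param
            kernel = self.kernel_shape.with_params(C=c, sigma=sigma)
        else:
            kernel = self.kernel_shape.with_params(C=param)
        return MulticlassSVMClassifier(self.scheme, kernel, self.structure_id)

    def default_grid(self):
        return svm_rbf_grid() if self.kernel_shape.family == "rbf" else svm_c_grid()


class KnnFamily(ClassifierFamily):
    """k-NN family over k at a fixed measure/weighting; distances are
    computed once per query and reused across the whole k grid."""

    def __init__(self, measure: str, weighting: str, rng_seed: int = 0):
        self.base = KnnSpec(1, measure, weighting, rng_seed)

    def make(self, k: int) -> KnnClassifier:
        return KnnClassifier(KnnSpec(int(k), self.base.measure, self.base.weighting,
                                     self.base.rng_seed))

    def grid_predictions(self, grid, X, y, x):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        x = np.asarray(x, dtype=np.float64)
        if X.shape[0] > 1:
            sd = X.std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)
        else:
            sd = np.ones(X.shape[1])
        try:
            d = distances_to(self.base.measure, X, x, train_sd=sd)
        except ColonyQCError as exc:
            logger.debug("distance computation failed: %s", exc)
            return [None] * len(grid)
        out = []
        for k in grid:
            if k > X.shape[0]:
                out.append(None)
                continue
            spec = KnnSpec(int(k), self.base.measure, self.base.weighting, self.base.rng_seed)
            out.append(predict_from_distances(d, y, x, spec))
        return out

    def default_grid(self):
        return knn_k_grid()


# --- report tables -----------------------------------------------------------

def results_table(named_results) -> pd.DataFrame:
    """Rows of Bad/Good/Semigood 'TP (TPR%)' + ACC, one per arrangement."""
    rows = []
    for name, result in named_results:
        row = {"arrangement": name}
        row.update(result.to_row())
        rows.append(row)
    return pd.DataFrame(rows)
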