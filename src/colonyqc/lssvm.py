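"""Binary Least-Squares Support Vector Machine.

The LS-SVM replaces the hinge-loss inequality constraints of the standard
SVM with squared-error equality constraints, so training reduces to one
dense linear system instead of a quadratic program.  With training pairs
(x_i, y_i), y_i in {-1, +1}, kernel K and regularization C, the dual
solution (b, alpha) satisfies the saddle-point system

    [ 0   y^T      ] [ b     ]   [ 0 ]
    [ y   Omega+I/C] [ alpha ] = [ 1 ]

with Omega_ij = y_i y_j K(x_i, x_j).  The decision function is
f(x) = sign( sum_i alpha_i y_i K(x, x_i) + b ).  Multipliers alpha may be
negative, and 1/C is added to the diagonal exactly as written (not C*I).

Kernel conventions (the literature varies; these are fixed here):
  linear       K(a, b) = a . b
  polynomial   K(a, b) = (a . b + 1)^degree,  degree in 2..6
  rbf          K(a, b) = exp(-||a - b||^2 / (2 sigma^2)),
               sigma being the width of the Gaussian.

Optional autoscaling z-scores the training columns and stores (mu, sd) so
that every test point is scaled by the training statistics.  Zero-variance
columns use sd = 1 (they contribute 0 after centering).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    DegenerateDataError,
    DimensionMismatchError,
    InvalidSpecError,
    SingularSystemError,
)

KERNEL_FAMILIES = ("linear", "polynomial", "rbf")
POLY_DEGREES = (2, 3, 4, 5, 6)


@dataclass(frozen=True)
class KernelSpec:
    """One of the seven admissible kernels plus its parameters."""

    family: str
    C: float = 1.0
    degree: int | None = None
    sigma: float | None = None

    def __post_init__(self):
        if self.family not in KERNEL_FAMILIES:
            raise InvalidSpecError(
                f"kernel family must be one of {KERNEL_FAMILIES}; got {self.family!r}"
            )
        if self.C <= 0:
            raise InvalidSpecError("C must be > 0")
        if self.family == "polynomial":
            if self.degree not in POLY_DEGREES:
                raise InvalidSpecError(
                    f"polynomial degree must be in {POLY_DEGREES}; got {self.degree!r}"
                )
        elif self.degree is not None:
            raise InvalidSpecError(f"degree is only valid for polynomial kernels")
        if self.family == "rbf":
            if self.sigma is None or self.sigma <= 0:
                raise InvalidSpecError("rbf kernel requires sigma > 0")
        elif self.sigma is not None:
            raise InvalidSpecError("sigma is only valid for the rbf kernel")

    def with_params(self, C: float, sigma: float | None = None) -> "KernelSpec":
        """Same kernel shape with new grid-point parameters."""
        return KernelSpec(
            self.family, C=C, degree=self.degree,
            sigma=sigma if self.family == "rbf" else None,
        )


def all_kernel_families() -> list[KernelSpec]:
    """The seven kernel shapes: linear, polynomial degrees 2..6, rbf."""
    out = [KernelSpec("linear")]
    out += [KernelSpec("polynomial", degree=d) for d in POLY_DEGREES]
    out.append(KernelSpec("rbf", sigma=1.0))
    return out


def kernel_matrix(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Gram matrix K(A_i, B_j), shape (p, q)."""
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise DimensionMismatchError(
            f"kernel inputs disagree in dimension: {A.shape[1]} vs {B.shape[1]}"
        )
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise DegenerateDataError("kernel inputs must be finite")
    if spec.family == "linear":
        return A @ B.T
    if spec.family == "polynomial":
        return (A @ B.T + 1.0) ** spec.degree
    # rbf
    sq = cdist(A, B, "sqeuclidean")
    return np.exp(-sq / (2.0 * spec.sigma**2))


@dataclass
class BinaryLSSVM:
    """Fitted dual solution plus everything needed to score new points."""

    alphas: np.ndarray  # (m,)
    bias: float
    train_X: np.ndarray  # (m, d), post-scaling
    train_y: np.ndarray  # (m,) in {-1, +1}
    kernel: KernelSpec
    scaler_mu: np.ndarray | None = None  # (d,) or None when autoscale off
    scaler_sd: np.ndarray | None = None


def _zscore_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns contribute 0 after centering
    return mu, sd


def train_lssvm(
    X: np.ndarray, y: np.ndarray, spec: KernelSpec, autoscale: bool = True
) -> BinaryLSSVM:
    """Solve the (m+1)-dimensional dual system directly.

    Raises if only one class is present or the system is numerically
    singular (the condition estimate is reported).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.shape[0] != y.shape[0]:
        raise DimensionMismatchError("X rows and y length disagree")
    if X.shape[0] < 2:
        raise DegenerateDataError("need at least 2 training examples")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise DegenerateDataError("labels must be in {-1, +1}")
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("training labels contain a single class")

    mu = sd = None
    if autoscale:
        mu, sd = _zscore_params(X)
        X = (X - mu) / sd

    m = X.shape[0]
    K = kernel_matrix(spec, X, X)
    omega = np.outer(y, y) * K
    system = np.zeros((m + 1, m + 1))
    system[0, 1:] = y
    system[1:, 0] = y
    system[1:, 1:] = omega + np.eye(m) / spec.C
    rhs = np.concatenate([[0.0], np.ones(m)])
    try:
        sol = np.linalg.solve(system, rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularSystemError(f"dual system is singular: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        cond = np.linalg.cond(system)
        raise SingularSystemError(
            f"dual system numerically singular (condition estimate {cond:.3e})"
        )
    return BinaryLSSVM(
        alphas=sol[1:],
        bias=float(sol[0]),
        train_X=X,
        train_y=y,
        kernel=spec,
        scaler_mu=mu,
        scaler_sd=sd,
    )


def system_residual(model: BinaryLSSVM) -> float:
    """Max-norm residual of the dual system at the stored solution."""
    m = model.train_X.shape[0]
    K = kernel_matrix(model.kernel, model.train_X, model.train_X)
    omega = np.outer(model.train_y, model.train_y) * K
    system = np.zeros((m + 1, m + 1))
    system[0, 1:] = model.train_y
    system[1:, 0] = model.train_y
    system[1:, 1:] = omega + np.eye(m) / model.kernel.C
    rhs = np.concatenate([[0.0], np.ones(m)])
    sol = np.concatenate([[model.bias], model.alphas])
    return float(np.max(np.abs(system @ sol - rhs)))


def _apply_scaler(model: BinaryLSSVM, X: np.ndarray) -> np.ndarray:
    if model.scaler_mu is None:
        return X
    return (X - model.scaler_mu) / model.scaler_sd


def decision_values(model: BinaryLSSVM, X: np.ndarray) -> np.ndarray:
    """Decision function for a batch of points (rows)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.train_X.shape[1]:
        raise DimensionMismatchError(
            f"expected {model.train_X.shape[1]} features; got {X.shape[1]}"
        )
    X = _apply_scaler(model, X)
    K = kernel_matrix(model.kernel, X, model.train_X)
    return K @ (model.alphas * model.train_y) + model.bias


def decision_value(model: BinaryLSSVM, x: np.ndarray) -> float:
    """Decision function sum_i alpha_i y_i K(x, x_i) + b for one point."""
    return float(decision_values(model, np.asarray(x, dtype=np.float64)[None, :])[0])


def predict_sign(model: BinaryLSSVM, x: np.ndarray) -> int:
    """Sign of the decision value; an exact 0 predicts +1 (documented tie rule)."""
    return 1 if decision_value(model, x) >= 0.0 else -1


# --- serialization ----------------------------------------------------------
# JSON with repr-precision floats: Python's float repr round-trips IEEE
# doubles exactly, so save -> load is bit-exact for all reals.

def save_model(model: BinaryLSSVM, path) -> None:
    payload = {
        "schema": "colonyqc.BinaryLSSVM/1",
        "alphas": model.alphas.tolist(),
        "bias": model.bias,
        "train_X": model.train_X.tolist(),
        "train_y": model.train_y.tolist(),
        "kernel": {
            "family": model.kernel.family,
            "C": model.kernel.C,
            "degree": model.kernel.degree,
            "sigma": model.kernel.sigma,
        },
        "scaler_mu": None if model.scaler_mu is None else model.scaler_mu.tolist(),
        "scaler_sd": None if model.scaler_sd is None else model.scaler_sd.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> BinaryLSSVM:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != "colonyqc.BinaryLSSVM/1":
        raise InvalidSpecError(f"unrecognized model schema in {path}")
    k = payload["kernel"]
    return BinaryLSSVM(
        alphas=np.asarray(payload["alphas"], dtype=np.float64),
        bias=float(payload["bias"]),
        train_X=np.asarray(payload["train_X"], dtype=np.float64),
        train_y=np.asarray(payload["train_y"], dtype=np.float64),
        kernel=KernelSpec(k["family"], C=k["C"], degree=k["degree"], sigma=k["sigma"]),
        scaler_mu=None if payload["scaler_mu"] is None else np.asarray(payload["scaler_mu"]),
        scaler_sd=None if payload["scaler_sd"] is None else np.asarray(payload["scaler_sd"]),
    )
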