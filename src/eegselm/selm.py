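"""Binary sparse extreme learning machine (SELM).

The SELM solves the box-constrained dual quadratic program

    minimise  L_d(a) = 1/2 sum_ij a_i a_j t_i t_j k(x_i, x_j) - sum_i a_i
    subject to 0 <= a_i <= C,

with labels t_i in {-1, +1}.  Unlike the SVM dual there is no equality
(sum) constraint, hence no bias term, and the trained model keeps only the
samples with nonzero multipliers (the support vectors).

Training is single-coordinate descent: at each iteration the coordinate
with the most negative score J_i = g_i * d_i is updated, where g_i is the
gradient of L_d and d_i the feasible direction indicator (+1 at the lower
bound, -sign(g_i) strictly inside the box, -1 at the upper bound).  The
step is either the plain gradient step a_c <- a_c - g_c ("literal" mode,
exact for kernels with unit diagonal such as the Gaussian) or the Newton
step a_c <- a_c - g_c / k(x_c, x_c) ("newton" mode, the default, which
guarantees descent for any positive-definite kernel); the result is
clipped to [0, C] and the gradient updated with the clipped change.
Iteration stops when min_i J_i > -epsilon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "KernelSpec",
    "TrainState",
    "BinarySELMModel",
    "kernel_eval",
    "gram",
    "init_state",
    "select_index",
    "update_multiplier",
    "dual_objective",
    "train_binary",
    "decision_value",
    "decision_values",
    "predict_binary",
    "model_to_json",
    "model_from_json",
]

UpdateMode = Literal["newton", "literal"]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and its single parameter.

    gaussian  : ``exp(-||x-y||^2 / two_sigma_sq)``, parameter ``2*sigma^2``
    laplacian : ``exp(-||x-y|| / (2*sigma))`` by default; set
                ``laplacian_denominator="sigma"`` for ``exp(-||x-y||/sigma)``
    polynomial: ``(1 + x.y)^degree``
    """

    family: Literal["gaussian", "laplacian", "polynomial"]
    two_sigma_sq: float | None = None
    sigma: float | None = None
    degree: int | None = None
    laplacian_denominator: Literal["2sigma", "sigma"] = "2sigma"

    def __post_init__(self) -> None:
        if self.family == "gaussian":
            if self.two_sigma_sq is None or self.two_sigma_sq <= 0:
                raise ValueError("gaussian kernel needs two_sigma_sq > 0")
        elif self.family == "laplacian":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("laplacian kernel needs sigma > 0")
        elif self.family == "polynomial":
            if self.degree is None or int(self.degree) < 1:
                raise ValueError("polynomial kernel needs degree >= 1")
        else:
            raise ValueError(f"unknown kernel family {self.family!r}")

    @classmethod
    def gaussian(cls, two_sigma_sq: float) -> "KernelSpec":
        return cls(family="gaussian", two_sigma_sq=two_sigma_sq)

    @classmethod
    def laplacian(cls, sigma: float, denominator: Literal["2sigma", "sigma"] = "2sigma") -> "KernelSpec":
        return cls(family="laplacian", sigma=sigma, laplacian_denominator=denominator)

    @classmethod
    def polynomial(cls, degree: int) -> "KernelSpec":
        return cls(family="polynomial", degree=int(degree))

    def to_dict(self) -> dict:
        d = {"family": self.family}
        if self.family == "gaussian":
            d["two_sigma_sq"] = self.two_sigma_sq
        elif self.family == "laplacian":
            d["sigma"] = self.sigma
            d["laplacian_denominator"] = self.laplacian_denominator
        else:
            d["degree"] = self.degree
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(**d)


def gram(X: np.ndarray, Y: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Kernel matrix k(X_i, Y_j)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if spec.family == "gaussian":
        return np.exp(-cdist(X, Y, "sqeuclidean") / spec.two_sigma_sq)
    if spec.family == "laplacian":
        denom = 2.0 * spec.sigma if spec.laplacian_denominator == "2sigma" else spec.sigma
        return np.exp(-cdist(X, Y, "euclidean") / denom)
    return (1.0 + X @ Y.T) ** spec.degree


def kernel_eval(x: np.ndarray, y: np.ndarray, spec: KernelSpec) -> float:
    """Kernel value for a single pair of feature vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(gram(x[None, :], y[None, :], spec)[0, 0])


@dataclass
class TrainState:
    """Mutable optimiser state; the box 0 <= alpha <= C holds throughout."""

    alpha: np.ndarray
    g: np.ndarray
    t: np.ndarray
    C: float
    epsilon: float
    n_iter: int = 0

    def directions(self) -> np.ndarray:
        """Feasible update direction d_i: +1 / -sign(g_i) / -1 by box face."""
        d = -np.sign(self.g)
        d[self.alpha <= 0.0] = 1.0
        d[self.alpha >= self.C] = -1.0
        return d

    def scores(self) -> np.ndarray:
        """J_i = g_i * d_i; the stopping rule is min_i J_i > -epsilon."""
        return self.g * self.directions()


def init_state(
    X: np.ndarray, t: Sequence[float], C: float, epsilon: float
) -> TrainState:
    """Fresh state at alpha = 0: every gradient is -1, every score is -1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t = np.asarray(t, dtype=float).ravel()
    if t.size != X.shape[0] or t.size < 1:
        raise ValueError("need one label per training row, and at least one row")
    if not np.all(np.isin(t, (-1.0, 1.0))):
        raise ValueError("labels must be -1 or +1")
    if C <= 0:
        raise ValueError("C must be positive")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    n = t.size
    return TrainState(
        alpha=np.zeros(n), g=np.full(n, -1.0), t=t, C=float(C), epsilon=float(epsilon)
    )


def select_index(state: TrainState) -> int | None:
    """Coordinate with the most negative score, or ``None`` when converged.

    Ties break to the lowest index (``argmin`` convention); convergence is
    ``min_i J_i > -epsilon``.
    """
    J = state.scores()
    c = int(np.argmin(J))
    if J[c] > -state.epsilon:
        return None
    return c


def update_multiplier(
    state: TrainState, c: int, K: np.ndarray, mode: UpdateMode = "newton"
) -> TrainState:
    """Update coordinate ``c`` in place and propagate the gradient.

    The unconstrained step is clipped to [0, C] and the *clipped* change is
    propagated: ``g_i += t_i * t_c * K[i, c] * (a_c_clip - a_c_old)``,
    keeping the gradient consistent with the stored multipliers.
    """
    if not 0 <= c < state.alpha.size:
        raise IndexError(f"index {c} out of range")
    step = state.g[c] if mode == "literal" else state.g[c] / K[c, c]
    new = float(np.clip(state.alpha[c] - step, 0.0, state.C))
    delta = new - state.alpha[c]
    state.alpha[c] = new
    if delta != 0.0:
        state.g += state.t * state.t[c] * K[:, c] * delta
    state.n_iter += 1
    return state


def dual_objective(state: TrainState) -> float:
    """L_d = 1/2 a'Qa - sum(a), computed from the maintained gradient."""
    return float(0.5 * np.dot(state.alpha, state.g - 1.0))


@dataclass(frozen=True)
class BinarySELMModel:
    """A trained binary SELM: support vectors, signed weights, kernel.

    ``weights[i] = alpha_i * t_i`` for the support vectors (alpha_i > 0).
    There is no bias term.  ``positive_label`` / ``negative_label`` record
    which original classes were coded +1 / -1, when known.
    """

    support_vectors: np.ndarray
    weights: np.ndarray
    kernel: KernelSpec
    diagnostics: dict = field(default_factory=dict)
    positive_label: str | None = None
    negative_label: str | None = None

    @property
    def n_support(self) -> int:
        return int(self.weights.size)


def train_binary(
    X: np.ndarray,
    t: Sequence[float],
    C: float = 5.0,
    epsilon: float = 1e-3,
    kernel: KernelSpec = KernelSpec.gaussian(500.0),
    max_iter: int | None = None,
    mode: UpdateMode = "newton",
    positive_label: str | None = None,
    negative_label: str | None = None,
) -> BinarySELMModel:
    """Train a binary SELM by single-coordinate descent on the dual QP.

    Runs select/update until ``min_i J_i > -epsilon`` or ``max_iter``
    (default ``max(10_000, 50 * N)``; the floor matters for small
    ill-conditioned problems) iterations; a model hitting the cap is
    returned with ``diagnostics["converged"] = False``.  Only rows with
    alpha > 0 are retained as support vectors.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    state = init_state(X, t, C, epsilon)
    n = state.t.size
    if np.unique(state.t).size < 2:
        import warnings

        warnings.warn("training labels are all one class; model is degenerate")
    if max_iter is None:
        max_iter = max(10_000, 50 * n)
    K = gram(X, X, kernel)
    converged = False
    while state.n_iter < max_iter:
        c = select_index(state)
        if c is None:
            converged = True
            break
        update_multiplier(state, c, K, mode=mode)
    else:
        converged = select_index(state) is None
    sv = state.alpha > 0.0
    diagnostics = {
        "iterations": state.n_iter,
        "converged": bool(converged),
        "final_min_J": float(np.min(state.scores())),
        "dual_objective": dual_objective(state),
        "n_support": int(np.count_nonzero(sv)),
        "n_train": n,
        "sparsity_ratio": float(np.count_nonzero(sv) / n),
    }
    return BinarySELMModel(
        support_vectors=X[sv].copy(),
        weights=(state.alpha * state.t)[sv].copy(),
        kernel=kernel,
        diagnostics=diagnostics,
        positive_label=positive_label,
        negative_label=negative_label,
    )


def decision_values(model: BinarySELMModel, X: np.ndarray) -> np.ndarray:
    """Pre-sign decision values sum_i w_i k(x, sv_i) for rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.n_support == 0:
        return np.zeros(X.shape[0])
    return gram(X, model.support_vectors, model.kernel) @ model.weights


def decision_value(model: BinarySELMModel, x: np.ndarray) -> float:
    """Pre-sign decision value for a single feature vector."""
    return float(decision_values(model, np.asarray(x, dtype=float)[None, :])[0])


def predict_binary(model: BinarySELMModel, X: np.ndarray) -> np.ndarray:
    """Sign of the decision value, with sign(0) mapped to +1."""
    f = decision_values(model, X)
    return np.where(f >= 0.0, 1.0, -1.0)


def model_to_json(model: BinarySELMModel) -> str:
    """Serialise a binary model to JSON; round-trips exactly."""
    payload = {
        "kernel": model.kernel.to_dict(),
        "support_vectors": model.support_vectors.tolist(),
        "weights": model.weights.tolist(),
        "diagnostics": model.diagnostics,
        "positive_label": model.positive_label,
        "negative_label": model.negative_label,
    }
    return json.dumps(payload)


def model_from_json(text: str) -> BinarySELMModel:
    payload = json.loads(text)
    n_sv = len(payload["weights"])
    return BinarySELMModel(
        support_vectors=np.asarray(payload["support_vectors"], dtype=float).reshape(n_sv, -1),
        weights=np.asarray(payload["weights"], dtype=float),
        kernel=KernelSpec.from_dict(payload["kernel"]),
        diagnostics=payload.get("diagnostics", {}),
        positive_label=payload.get("positive_label"),
        negative_label=payload.get("negative_label"),
    )
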