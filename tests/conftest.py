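"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: the wavelet
oracle is direct circular convolution + dyadic decimation with the
closed-form filter pair, and the QP oracles are an exhaustive fine grid
(N <= 2) and multi-start bounded L-BFGS-B with the analytic gradient.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

from eegselm.selm import KernelSpec, gram

SQRT3 = np.sqrt(3.0)
SQRT2 = np.sqrt(2.0)

H = np.array([1.0 + SQRT3, 3.0 + SQRT3, 3.0 - SQRT3, 1.0 - SQRT3]) / (4.0 * SQRT2)
G = np.array([-H[3], H[2], -H[1], H[0]])


def conv_dwt_oracle(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-level db4 analysis by circular convolution + decimation.

    Convention matching the lifting implementation: approximation
    ``a_l = sum_k h_k x[(2l+k) mod L]`` and detail
    ``d_l = sum_k g_k x[(2l+k-2) mod L]`` (two-sample circular delay).
    """
    x = np.asarray(x, dtype=float)
    L = x.size
    idx = (2 * np.arange(L // 2)[:, None] + np.arange(4)[None, :]) % L
    a = (x[idx] * H).sum(axis=1)
    d = (x[(idx - 2) % L] * G).sum(axis=1)
    return a, d


def dual_objective_of(alpha: np.ndarray, Q: np.ndarray) -> float:
    return float(0.5 * alpha @ Q @ alpha - alpha.sum())


def qp_oracle_lbfgsb(Q: np.ndarray, C: float, n_starts: int = 6, seed: int = 0) -> float:
    """Minimum of the box-constrained dual QP by multi-start L-BFGS-B."""
    n = Q.shape[0]
    rng = np.random.default_rng(seed)
    best = np.inf
    for s in range(n_starts):
        a0 = np.zeros(n) if s == 0 else rng.uniform(0.0, C, size=n)
        res = minimize(
            lambda a: dual_objective_of(a, Q),
            a0,
            jac=lambda a: Q @ a - 1.0,
            bounds=[(0.0, C)] * n,
            method="L-BFGS-B",
            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 10_000},
        )
        best = min(best, float(res.fun))
    return best


def qp_oracle_grid(Q: np.ndarray, C: float, step: float = 1e-3) -> float:
    """Exhaustive fine-grid minimum of the dual QP; N <= 2 only."""
    n = Q.shape[0]
    grid = np.arange(0.0, C + step / 2, step)
    if n == 1:
        vals = 0.5 * Q[0, 0] * grid**2 - grid
        return float(vals.min())
    if n == 2:
        best = np.inf
        for a1 in grid:  # chunk along one axis to bound memory
            vals = (
                0.5 * Q[0, 0] * a1**2
                + Q[0, 1] * a1 * grid
                + 0.5 * Q[1, 1] * grid**2
                - a1
                - grid
            )
            best = min(best, float(vals.min()))
        return best
    raise ValueError("grid oracle is exhaustive only for N <= 2")


def make_qp(
    rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray, float, KernelSpec, np.ndarray]:
    """A random tiny SELM training instance and its dual QP matrix."""
    X = rng.normal(size=(n, 2)) * rng.uniform(0.5, 3.0)
    t = rng.choice([-1.0, 1.0], size=n)
    C = float(rng.choice([0.5, 1.0, 5.0]))
    if rng.random() < 0.5:
        spec = KernelSpec.gaussian(float(rng.uniform(0.5, 5.0)))
    else:
        spec = KernelSpec.polynomial(int(rng.choice([2, 3, 4])))
    Q = np.outer(t, t) * gram(X, X, spec)
    return X, t, C, spec, Q


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synth_segments():
    """A small fixed-seed synthetic dataset (8 segments per class)."""
    from eegselm import SynthSpec, generate_synthetic_dataset

    spec = SynthSpec(n_segments_per_class=8, segment_length=4096, seed=1)
    return generate_synthetic_dataset(spec)


@pytest.fixture(scope="session")
def synth_features(synth_segments):
    """Feature matrix and labels for the small synthetic dataset."""
    from eegselm import build_dataset

    feats = build_dataset(synth_segments)
    X = np.array([f.values for f in feats])
    y = np.array([f.label for f in feats], dtype=object)
    return X, y


@pytest.fixture(scope="session")
def separable_clouds(rng):
    """Two well-separated 2-D Gaussian clouds with +-1 labels."""
    n = 50
    Xp = rng.normal(loc=(3.0, 3.0), scale=0.3, size=(n, 2))
    Xn = rng.normal(loc=(-3.0, -3.0), scale=0.3, size=(n, 2))
    X = np.vstack([Xp, Xn])
    t = np.concatenate([np.ones(n), -np.ones(n)])
    return X, t
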