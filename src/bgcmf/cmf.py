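"""Collaborative matrix factorization with similarity regularization.

The association matrix Y (n x m) is factored as Y ~ A B^T with A (n x k),
B (m x k), minimizing

    J(A, B) = ||Y - A B^T||_F^2 + lambda_l (||A||_F^2 + ||B||_F^2)
              + lambda_d ||K_m - A A^T||_F^2 + lambda_t ||K_d - B B^T||_F^2,

so the latent factors both reconstruct the associations and reproduce the
fused miRNA/disease similarities as factor Gram matrices. Factors are
initialized from the truncated SVD of Y and refined by alternating
fixed-point updates derived from the stationarity conditions dJ/dA = 0 and
dJ/dB = 0 (the quartic similarity terms contribute with a factor 2):

    A <- (Y B + 2 lambda_d K_m A) (B^T B + lambda_l I + 2 lambda_d A^T A)^-1
    B <- (Y^T A + 2 lambda_t K_d B) (A^T A + lambda_l I + 2 lambda_t B^T B)^-1

Updates are Gauss-Seidel (the B step uses the fresh A); the k x k systems
are solved as linear systems, never by explicit inversion. The scheme is a
fixed-point iteration, not an exact per-block minimizer, so the objective
can occasionally tick upward; in practice it decreases monotonically on
nearly all instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import DivergenceError, ParameterError

__all__ = ["FactorPair", "CmfParams", "svd_init", "cmf_objective", "als_step", "fit_cmf"]


@dataclass(frozen=True)
class FactorPair:
    """Low-rank factors A (n x k) and B (m x k) with Y ~ A B^T."""

    A: np.ndarray
    B: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float)
        if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
            raise ParameterError("A and B must be 2-D with a shared latent dimension")
        if not (np.isfinite(A).all() and np.isfinite(B).all()):
            raise DivergenceError("factor matrices contain non-finite entries")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)

    @property
    def k(self) -> int:
        return self.A.shape[1]

    def product(self) -> np.ndarray:
        return self.A @ self.B.T


@dataclass(frozen=True)
class CmfParams:
    lambda_l: float = 1.0
    lambda_d: float = 0.25
    lambda_t: float = 0.25
    k: int = 50
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0  # kept for config compatibility; the fit is deterministic

    def __post_init__(self):
        if min(self.lambda_l, self.lambda_d, self.lambda_t) < 0:
            raise ParameterError("regularization weights must be non-negative")
        if self.k < 1:
            raise ParameterError("latent dimension k must be positive")
        if self.max_iter < 0:
            raise ParameterError("max_iter must be non-negative")
        if self.tol <= 0:
            raise ParameterError("tol must be positive")


def svd_init(Y: np.ndarray, k: int) -> FactorPair:
    """Initialize factors from the rank-k truncated SVD of Y.

    A = U_k S_k^(1/2), B = V_k S_k^(1/2), so A B^T is the best rank-k
    approximation of Y in Frobenius norm. For reproducibility each left
    singular vector's largest-magnitude element is made positive.
    """
    Y = np.asarray(Y, dtype=float)
    if k > min(Y.shape):
        raise ParameterError(f"k={k} exceeds min(n, m)={min(Y.shape)}")
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    signs = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U = U * signs
    Vt = Vt * signs[:, None]
    root_s = np.sqrt(s[:k])
    return FactorPair(U[:, :k] * root_s, Vt[:k].T * root_s)


def cmf_objective(
    Y: np.ndarray, A: np.ndarray, B: np.ndarray, Km: np.ndarray, Kd: np.ndarray, params: CmfParams
) -> float:
    """Regularized reconstruction objective J(A, B); non-negative."""
    fit = np.linalg.norm(Y - A @ B.T, "fro") ** 2
    ridge = params.lambda_l * (np.linalg.norm(A, "fro") ** 2 + np.linalg.norm(B, "fro") ** 2)
    sim_m = params.lambda_d * np.linalg.norm(Km - A @ A.T, "fro") ** 2
    sim_d = params.lambda_t * np.linalg.norm(Kd - B @ B.T, "fro") ** 2
    return float(fit + ridge + sim_m + sim_d)


def _solve_right(M: np.ndarray, C: np.ndarray, lam_l: float) -> np.ndarray:
    """Solve X M = C for X with M symmetric (k x k)."""
    try:
        return scipy.linalg.solve(M, C.T, assume_a="sym").T
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError, ValueError) as e:
        if lam_l == 0:
            raise DivergenceError(
                "singular ALS system; set lambda_l > 0 to regularize"
            ) from e
        raise


def als_step(
    Y: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    Km: np.ndarray,
    Kd: np.ndarray,
    params: CmfParams,
) -> FactorPair:
    """One alternating update of (A, B) from the stationarity conditions.

    With lambda_d = lambda_t = 0 the A update reduces to the ridge
    closed form Y B (B^T B + lambda_l I)^-1.
    """
    k = A.shape[1]
    I = np.eye(k)
    M_a = B.T @ B + params.lambda_l * I + 2 * params.lambda_d * (A.T @ A)
    A_new = _solve_right(M_a, Y @ B + 2 * params.lambda_d * (Km @ A), params.lambda_l)
    M_b = A_new.T @ A_new + params.lambda_l * I + 2 * params.lambda_t * (B.T @ B)
    B_new = _solve_right(M_b, Y.T @ A_new + 2 * params.lambda_t * (Kd @ B), params.lambda_l)
    return FactorPair(A_new, B_new)


def fit_cmf(
    Y: np.ndarray, Km: np.ndarray, Kd: np.ndarray, params: CmfParams = CmfParams()
) -> tuple[FactorPair, np.ndarray, list[float]]:
    """Fit the factorization; returns (factors, Y2 = A B^T, objective trace).

    Iterates ``als_step`` from the SVD initialization until the relative
    objective change falls below ``params.tol`` or ``params.max_iter`` is
    reached. The trace holds the objective at initialization and after each
    step.
    """
    Y = np.asarray(Y, dtype=float)
    pair = svd_init(Y, params.k)
    trace = [cmf_objective(Y, pair.A, pair.B, Km, Kd, params)]
    for it in range(params.max_iter):
        pair = als_step(Y, pair.A, pair.B, Km, Kd, params)
        obj = cmf_objective(Y, pair.A, pair.B, Km, Kd, params)
        if not np.isfinite(obj):
            raise DivergenceError(
                f"objective diverged at iteration {it + 1} "
                f"(lambda_l={params.lambda_l}, lambda_d={params.lambda_d}, "
                f"lambda_t={params.lambda_t})"
            )
        prev = trace[-1]
        trace.append(obj)
        if abs(obj - prev) / max(prev, 1.0) < params.tol:
            break
    return pair, pair.product(), trace
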