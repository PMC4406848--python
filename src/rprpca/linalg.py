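"""Principal Component Pursuit: the convex low-rank + sparse decomposition.

The engine solves

    min_{L,S}  ‖L‖_* + λ‖S‖_1   subject to   M = L + S,

separating a stacked trial matrix into a common (low-rank) response ``L`` and
an aberrant (sparse) response ``S``.  The solver is the inexact augmented
Lagrange multiplier scheme: alternating singular-value thresholding on ``L``
and entrywise soft thresholding on ``S`` with a running dual estimate, which is
the standard first-order method for this program.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .matrix import DataMatrix

logger = logging.getLogger("rprpca")

__all__ = [
    "Decomposition",
    "default_lambda",
    "soft_threshold",
    "singular_value_threshold",
    "numerical_rank",
    "pcp_decompose",
    "threshold_sparse_display",
]

#: Default relative Frobenius residual at which the solver stops.
DEFAULT_TOL = 1e-7
#: Default iteration cap for the augmented-Lagrangian loop.
DEFAULT_MAX_ITER = 1000
#: Default relative singular-value cutoff for :func:`numerical_rank`.
RANK_REL_TOL = 1e-6


@dataclass
class Decomposition:
    """Result of Principal Component Pursuit.

    ``L`` is the common low-rank component, ``S`` the sparse aberrant one;
    ``residual`` is the relative Frobenius mismatch ‖M − L − S‖_F / ‖M‖_F at
    exit.  When the decomposition was computed in a projected space and mapped
    back, ``back_projected`` is set (see :func:`rprpca.projection.rp_rpca`).
    """

    L: np.ndarray
    S: np.ndarray
    lam: float
    iterations: int = 0
    residual: float = 0.0
    converged: bool = True
    back_projected: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.L.shape != self.S.shape:
            raise ValueError("L and S must share shape")
        if self.lam <= 0:
            raise ValueError("lam must be positive")

    @property
    def rank(self) -> int:
        """Numerical rank of the low-rank component at the default cutoff."""
        return numerical_rank(self.L)


def default_lambda(q: int, n: int, N_T: int) -> float:
    """Default sparsity weight λ = 1/√(max(q, n·N_T)).

    ``q`` is the number of trials (matrix rows) and ``n·N_T`` the number of
    columns of the stacked matrix.  This is the universal choice from the
    robust-PCA recovery theory; for the 50-trial, 2-species, 10-time-point
    reference instance it evaluates to 1/√50 ≈ 0.141.
    """
    if q < 1 or n < 1 or N_T < 1:
        raise ValueError("q, n and N_T must be positive integers")
    return 1.0 / math.sqrt(max(q, n * N_T))


def soft_threshold(A: np.ndarray, tau: float) -> np.ndarray:
    """Entrywise shrinkage sign(a)·max(|a| − τ, 0): the prox of τ‖·‖₁."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    A = np.asarray(A, dtype=float)
    return np.sign(A) * np.maximum(np.abs(A) - tau, 0.0)


def _fix_svd_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Deterministic convention: largest-|entry| of each left singular vector
    # made positive, so repeated runs are bit-identical across LAPACK drivers.
    if U.shape[1] == 0:
        return U, Vt
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, Vt * signs[:, None]


def singular_value_threshold(A: np.ndarray, tau: float) -> np.ndarray:
    """Shrink the singular values of ``A`` by τ: the prox of τ‖·‖_*."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    A = np.asarray(A, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite entries in input")
    U, s, Vt = sla.svd(A, full_matrices=False)
    U, Vt = _fix_svd_signs(U, Vt)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    if not np.any(keep):
        return np.zeros_like(A)
    return (U[:, keep] * s[keep]) @ Vt[keep]


def numerical_rank(A: np.ndarray, rel_tol: float = RANK_REL_TOL) -> int:
    """Number of singular values above ``rel_tol × σ_max``; 0 for A = 0."""
    if not 0 < rel_tol < 1:
        raise ValueError("rel_tol must lie in (0, 1)")
    A = np.asarray(A, dtype=float)
    if A.size == 0 or not np.any(A):
        return 0
    s = sla.svdvals(A)
    return int(np.sum(s > rel_tol * s[0]))


def _as_array(M) -> np.ndarray:
    if isinstance(M, DataMatrix):
        return M.values
    return np.asarray(M, dtype=float)


def pcp_decompose(
    M,
    lam: float | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> Decomposition:
    """Solve the principal component pursuit program for ``M``.

    Parameters
    ----------
    M
        Input matrix (:class:`~rprpca.matrix.DataMatrix` or plain 2-D array).
    lam
        Sparsity weight λ.  ``None`` uses 1/√(max(rows, cols)).
    tol
        Stop once ‖M − L − S‖_F / ‖M‖_F ≤ tol.
    max_iter
        Iteration cap; on hitting it the result is returned with
        ``converged=False`` and a warning is logged.

    Notes
    -----
    Inexact augmented Lagrangian iteration: with penalty μ (initialised to
    1.25/σ_max(M)) and dual variable Y,

        L ← SVT(M − S + Y/μ, 1/μ)
        S ← soft(M − L + Y/μ, λ/μ)
        Y ← Y + μ(M − L − S),

    with μ grown geometrically (factor 1.5) only once the S-step has
    stabilised (μ·‖S_{k+1} − S_k‖_F/‖M‖_F < 10⁻⁵).  Unconditional growth
    satisfies the constraint quickly but can freeze the L/S split far from
    the optimum, since both proximal steps shrink like 1/μ.
    """
    A = _as_array(M)
    if A.ndim != 2:
        raise ValueError("M must be a 2-D matrix")
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite entries in input matrix")
    if lam is None:
        rows, cols = A.shape
        lam = 1.0 / math.sqrt(max(rows, cols))
    if lam <= 0:
        raise ValueError("lam must be positive")
    if tol <= 0 or max_iter < 1:
        raise ValueError("tol must be positive and max_iter >= 1")

    norm_M = np.linalg.norm(A)
    if norm_M == 0:
        return Decomposition(np.zeros_like(A), np.zeros_like(A), lam,
                             iterations=0, residual=0.0, converged=True)

    sigma_max = sla.svdvals(A)[0]
    # Dual initialisation of Lin et al.: Y0 = M / J(M) keeps both prox steps
    # active from the first iteration.
    J = max(sigma_max, np.abs(A).max() / lam)
    Y = A / J
    mu = 1.25 / sigma_max
    mu_max = mu * 1e7
    rho = 1.5

    S = np.zeros_like(A)
    L = np.zeros_like(A)
    residual = 1.0
    it = 0
    for it in range(1, max_iter + 1):
        L = singular_value_threshold(A - S + Y / mu, 1.0 / mu)
        S_new = soft_threshold(A - L + Y / mu, lam / mu)
        dS = np.linalg.norm(S_new - S) / norm_M
        S = S_new
        gap = A - L - S
        Y = Y + mu * gap
        if mu * dS < 1e-5:
            mu = min(mu * rho, mu_max)
        residual = np.linalg.norm(gap) / norm_M
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug("pcp iter=%d residual=%.3e rank=%d", it, residual,
                         numerical_rank(L))
        if residual <= tol:
            break

    converged = bool(residual <= tol)
    if not converged:
        logger.warning(
            "pcp_decompose: max_iter=%d reached with residual %.3e > tol %.1e",
            max_iter, residual, tol)
    return Decomposition(L, S, lam, iterations=it, residual=float(residual),
                         converged=converged)


def threshold_sparse_display(S: np.ndarray, frac: float = 0.1) -> np.ndarray:
    """Zero entries of ``S`` with |S_ij| below ``frac × max|S|``.

    Display helper for "highly aberrant" sparse-component heat maps; keeps
    only the dominant aberrations.
    """
    if not 0 <= frac < 1:
        raise ValueError("frac must lie in [0, 1)")
    S = np.asarray(S, dtype=float)
    if S.size == 0 or not np.any(S):
        return S.copy()
    cut = frac * np.abs(S).max()
    out = S.copy()
    out[np.abs(out) < cut] = 0.0
    return out
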