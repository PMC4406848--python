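"""Random-projection preprocessing and the composed RP-RPCA pipeline.

Sparse or eccentrically scaled inputs violate the incoherence assumption that
makes the low-rank/sparse split identifiable: a matrix that is itself sparse
can be absorbed into ``S``, and a few large-scale species can dominate the
singular vectors.  Mixing the species blocks with a random matrix ``Ψ``
(expanded over time as ``R = Ψᵀ ⊗ I_{N_T}``) spreads the singular vectors out
while leaving the time axis untouched; the decomposition is then computed on
``Y = X·R`` and, when ``Ψ`` is square and nonsingular, mapped back through
``R⁻¹``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .linalg import Decomposition, pcp_decompose
from .matrix import DataMatrix

logger = logging.getLogger("rprpca")

__all__ = [
    "ProjectionOperator",
    "make_projection",
    "apply_projection",
    "invert_projection",
    "rp_rpca",
]

#: Condition-number ceiling above which inversion warns.
ILL_CONDITIONED = 1e8
_DISTRIBUTIONS = ("gaussian", "identity")


@dataclass
class ProjectionOperator:
    """Ψ (m × n) plus the metadata needed to expand R = Ψᵀ ⊗ I_{N_T}."""

    psi: np.ndarray
    N_T: int
    seed: int | None = None
    distribution: str = "gaussian"

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        if self.psi.ndim != 2:
            raise ValueError("psi must be a matrix")
        if self.N_T < 1:
            raise ValueError("N_T must be positive")

    @property
    def m(self) -> int:
        return self.psi.shape[0]

    @property
    def n(self) -> int:
        return self.psi.shape[1]

    @property
    def invertible(self) -> bool:
        if self.m != self.n:
            return False
        return np.linalg.matrix_rank(self.psi) == self.n

    def dense_operator(self) -> np.ndarray:
        """The explicit (n·N_T) × (m·N_T) matrix Ψᵀ ⊗ I_{N_T}.

        Test oracle only — application is always blockwise.
        """
        return np.kron(self.psi.T, np.eye(self.N_T))


def make_projection(
    n: int,
    m: int,
    N_T: int,
    seed: int | None = None,
    distribution: str = "gaussian",
) -> ProjectionOperator:
    """Draw an ``m × n`` projection matrix Ψ.

    The default law is i.i.d. N(0, 1/m), the scaling under which projected
    vector norms concentrate near the originals (the Johnson–Lindenstrauss
    regime).  ``distribution="identity"`` gives Ψ = I for debugging (requires
    m = n).  In square mode Ψ is resampled with a fresh sub-seed until
    nonsingular, so the operator is always invertible when m = n.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive")
    if m > n:
        raise ValueError(f"m={m} must not exceed n={n}")
    if N_T < 1:
        raise ValueError("N_T must be positive")
    if distribution not in _DISTRIBUTIONS:
        raise ValueError(
            f"unknown distribution {distribution!r}; choose from {_DISTRIBUTIONS}")

    if distribution == "identity":
        if m != n:
            raise ValueError("identity projection requires m = n")
        return ProjectionOperator(np.eye(n), N_T, seed=seed,
                                  distribution=distribution)

    root = np.random.default_rng(seed)
    for attempt in range(100):
        rng = np.random.default_rng(root.integers(0, 2**31)) if attempt else root
        psi = rng.standard_normal((m, n)) / np.sqrt(m)
        if m < n or np.linalg.matrix_rank(psi) == n:
            return ProjectionOperator(psi, N_T, seed=seed,
                                      distribution=distribution)
    raise RuntimeError("failed to draw a nonsingular square projection")


def _blockwise(psi: np.ndarray, X: DataMatrix) -> np.ndarray:
    # Y block j = Σ_i Ψ_{ji} · (block i of X); equals X @ (Ψᵀ ⊗ I_{N_T})
    # without materializing the Kronecker product.
    tensor = X.as_tensor()  # (q, n, N_T)
    out = np.einsum("ji,qit->qjt", psi, tensor)
    return out.reshape(X.n_trials, psi.shape[0] * X.n_timepoints)


def apply_projection(X: DataMatrix, P: ProjectionOperator) -> DataMatrix:
    """Project species blocks: ``Y = X (Ψᵀ ⊗ I_{N_T})``, time order intact."""
    if X.n_species != P.n or X.n_timepoints != P.N_T:
        raise ValueError(
            f"block structure mismatch: X has (n={X.n_species}, N_T="
            f"{X.n_timepoints}), projection expects (n={P.n}, N_T={P.N_T})")
    values = _blockwise(P.psi, X)
    columns = [f"proj{j}_t{t}" for j in range(P.m) for t in range(P.N_T)]
    return X.with_values(values, n_species=P.m, column_labels=columns)


def invert_projection(Y: DataMatrix, P: ProjectionOperator) -> DataMatrix:
    """Undo a square projection: ``X = Y (Ψᵀ)⁻¹ ⊗ I_{N_T} = Y R⁻¹``."""
    if P.m != P.n:
        raise ValueError("projection with m < n is not invertible")
    if Y.n_species != P.m or Y.n_timepoints != P.N_T:
        raise ValueError("block structure mismatch between Y and projection")
    cond = np.linalg.cond(P.psi)
    if not np.isfinite(cond):
        raise ValueError("projection matrix is singular")
    if cond > ILL_CONDITIONED:
        logger.warning("invert_projection: Ψ ill-conditioned (cond=%.2e)", cond)
    psi_inv = np.linalg.inv(P.psi)
    # Y block j = Σ_i Ψ_{ji} X_i  ⇒  X_i = Σ_j (Ψ⁻¹)_{ij} Y_j, i.e. blockwise
    # application of Ψ⁻¹.
    tensor = Y.as_tensor()
    out = np.einsum("ij,qjt->qit", psi_inv, tensor)
    values = out.reshape(Y.n_trials, P.n * P.N_T)
    columns = [f"s{i}_t{t}" for i in range(P.n) for t in range(P.N_T)]
    return Y.with_values(values, n_species=P.n, column_labels=columns)


def rp_rpca(
    X: DataMatrix,
    P: ProjectionOperator,
    lam: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 1000,
) -> Decomposition:
    """Random-projection robust PCA.

    Projects ``X`` to ``Y = X·R``, runs principal component pursuit on ``Y``,
    and — when Ψ is square — maps both components back through ``R⁻¹`` so that
    ``L̄ + S̄ = X`` to solver tolerance.  With ``m < n`` the components are
    returned in projected space and flagged (``back_projected=False``): no
    canonical mapping of the sparse part back to species space exists under
    compression.
    """
    Y = apply_projection(X, P)
    dec = pcp_decompose(Y.values, lam=lam, tol=tol, max_iter=max_iter)
    if P.m != P.n:
        dec.back_projected = False
        dec.meta["projected_space"] = True
        return dec
    L_bar = invert_projection(Y.with_values(dec.L), P)
    S_bar = invert_projection(Y.with_values(dec.S), P)
    out = Decomposition(
        L_bar.values, S_bar.values, dec.lam,
        iterations=dec.iterations, residual=dec.residual,
        converged=dec.converged, back_projected=True,
    )
    out.meta["projected_residual"] = dec.residual
    return out
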