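"""Shared fixtures and the certified-recovery instance constructor."""

from __future__ import annotations

import numpy as np
import pytest

from rprpca import DataMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """A 6-trial, 2-species, 4-time-point data matrix."""
    return DataMatrix(rng.standard_normal((6, 8)), n_species=2, n_timepoints=4)


def _dual_certificate_holds(L0, S0, lam, rank, iters=500, tol=1e-9):
    """Check that (L0, S0) is an optimum of principal component pursuit.

    Searches for a dual witness Y lying in the intersection of the two
    subdifferentials ∂‖L0‖_* and λ·∂‖S0‖₁ by Dykstra alternating projections;
    both sets are convex with cheap projections.  Convergence of the gap to
    zero certifies optimality of the planted pair; the check is conservative
    (failure to converge within the budget is treated as "not certified").
    """
    U, _, Vt = np.linalg.svd(L0, full_matrices=False)
    U, V = U[:, :rank], Vt[:rank].T
    PU, PV = U @ U.T, V @ V.T
    UV = U @ V.T

    def proj_T(Y):
        return PU @ Y + Y @ PV - PU @ Y @ PV

    omega = S0 != 0
    lam_sign = lam * np.sign(S0)

    def proj_nuclear_subgrad(Y):
        W = Y - proj_T(Y)
        Uw, sw, Vtw = np.linalg.svd(W, full_matrices=False)
        W = (Uw * np.minimum(sw, 1.0)) @ Vtw
        return UV + (W - proj_T(W))

    def proj_l1_subgrad(Y):
        Z = np.clip(Y, -lam, lam)
        Z[omega] = lam_sign[omega]
        return Z

    Y = UV.copy()
    p = np.zeros_like(Y)
    q = np.zeros_like(Y)
    for _ in range(iters):
        Ya = proj_nuclear_subgrad(Y + p)
        p = Y + p - Ya
        Yb = proj_l1_subgrad(Ya + q)
        q = Ya + q - Yb
        gap = np.linalg.norm(Yb - Ya) / max(1.0, np.linalg.norm(Yb))
        Y = Yb
        if gap < tol:
            return True
    return False


def make_certified_pcp_instance(seed, shape=(20, 20), rank=2,
                                spike_scale=5.0, max_attempts=30):
    """An incoherent (L0, S0) pair certified to be the pursuit optimum.

    L0 is a Gaussian rank-``rank`` product; S0 places one ±spike per row (a
    random permutation support — 5% of entries on the default 20×20 shape).
    Instances whose planted pair cannot be dual-certified (possible at these
    small sizes) are redrawn with a fresh sub-seed, so recovery up to solver
    tolerance is guaranteed by construction, independently of the solver.
    """
    n1, n2 = shape
    lam = 1.0 / np.sqrt(max(n1, n2))
    root = np.random.default_rng(seed)
    for _ in range(max_attempts):
        rg = np.random.default_rng(root.integers(0, 2**31))
        L0 = rg.standard_normal((n1, rank)) @ rg.standard_normal((rank, n2))
        S0 = np.zeros((n1, n2))
        perm = rg.permutation(n2)[:n1] if n2 >= n1 else None
        assert perm is not None, "constructor expects n2 >= n1"
        S0[np.arange(n1), perm] = (rg.choice([-1.0, 1.0], n1)
                                   * np.abs(L0).mean() * spike_scale)
        if _dual_certificate_holds(L0, S0, lam, rank):
            return L0, S0, lam
    raise RuntimeError("no certifiable instance found")
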