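"""Cholesky-factor parametrization of random-effect covariances.

Covariances are parametrized by the entries of a lower-triangular factor L
(row-major over the lower triangle), with the diagonal box-bounded at zero
during optimization so that boundary (singular) fits are reachable exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["n_theta", "build_lower", "flatten_lower", "theta_bounds",
           "diag_positions", "is_singular_chol", "intercept_slope_to_subgroup",
           "subgroup_to_intercept_slope"]


def n_theta(q: int) -> int:
    return q * (q + 1) // 2


def _tri_indices(q):
    return np.tril_indices(q)


def build_lower(theta, q: int) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (n_theta(q),):
        raise ValueError(f"theta must have length {n_theta(q)} for q={q}")
    L = np.zeros((q, q))
    L[_tri_indices(q)] = theta
    return L


def flatten_lower(L: np.ndarray) -> np.ndarray:
    L = np.asarray(L, dtype=float)
    return L[_tri_indices(L.shape[0])].copy()


def diag_positions(q: int) -> np.ndarray:
    """Indices of diagonal entries inside the row-major lower-triangle vector."""
    rows, cols = _tri_indices(q)
    return np.flatnonzero(rows == cols)


def theta_bounds(q: int):
    """Box bounds: diagonal >= 0, off-diagonals free."""
    diag = set(diag_positions(q).tolist())
    return [(0.0, None) if i in diag else (None, None) for i in range(n_theta(q))]


def is_singular_chol(L: np.ndarray, tol: float = 1e-4) -> bool:
    """Boundary detection on the Cholesky scale.

    True when any diagonal entry of L is below ``tol`` relative to the
    geometric mean of the nonzero diagonals, or when any implied correlation
    is within ``tol`` of +-1.
    """
    L = np.asarray(L, dtype=float)
    d = np.abs(np.diag(L))
    nz = d[d > 0]
    ref = float(np.exp(np.mean(np.log(nz)))) if nz.size else 0.0
    if np.any(d < tol * (ref + tol)):
        return True
    cov = L @ L.T
    sd = np.sqrt(np.diag(cov))
    if np.any(sd <= 0):
        return True
    corr = cov / np.outer(sd, sd)
    off = corr[~np.eye(len(sd), dtype=bool)]
    return bool(np.any(np.abs(off) > 1.0 - tol))


def _T(p: int) -> np.ndarray:
    """Map (intercept, slopes) random effects to subgroup-specific effects."""
    T = np.zeros((p, p))
    T[:, 0] = 1.0
    T[1:, 1:] = np.eye(p - 1)
    return T


def intercept_slope_to_subgroup(cov: np.ndarray) -> np.ndarray:
    """Covariance of (U_0, ..., U_{p-1}) from intercept+slope covariance."""
    T = _T(cov.shape[0])
    return T @ cov @ T.T


def subgroup_to_intercept_slope(cov: np.ndarray) -> np.ndarray:
    T = np.linalg.inv(_T(cov.shape[0]))
    return T @ cov @ T.T
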