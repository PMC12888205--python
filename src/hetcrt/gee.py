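"""Marginal models by GEE with independence working correlation.

With an independence working structure the estimating equations coincide with
the GLM score equations, so the point estimates are the ordinary GLM fit; the
inferential covariance is the cluster-robust sandwich

    V = A^{-1} (sum_i U_i U_i') A^{-1},

with A the model-based information and U_i the cluster-summed score, both
evaluated at the estimate.  Inference uses a z-test when the number of
clusters is moderate to large, or a Wald-type F-test with Fay-Graubard
"d-tilde" denominator degrees of freedom when clusters are few.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .design import Cells, collapse_cells
from .families import get_family
from .results import FitResultsMixin

__all__ = ["ClusterGEE", "GEEResults", "fay_graubard_df"]


class ClusterGEE:
    """GEE with independence working correlation for clustered trial data."""

    def __init__(self, data, family, include_interaction: bool = True):
        frame = data.frame if hasattr(data, "frame") else data
        self.family = get_family(family)
        self.cells: Cells = collapse_cells(frame, family=self.family,
                                           structure="intercept",
                                           include_interaction=include_interaction)
        if self.cells.n_clusters < 2:
            raise ValueError("cluster-robust inference requires at least 2 clusters")

    def fit(self, tol: float = 1e-10, maxiter: int = 100,
            df_adjust: bool = False) -> "GEEResults":
        """Solve the independence estimating equations by Newton scoring.

        ``df_adjust`` applies the optional finite-sample multiplier
        I/(I - k) to the sandwich (off by default).
        """
        c = self.cells
        fam = self.family
        X, m, S = c.X, c.m, c.S
        k = c.k_fixed
        beta = np.zeros(k)

        def deviance_part(b):
            return -float(np.sum(fam.cell_loglik(X @ b, m, S, c.SS, 1.0)))

        obj = deviance_part(beta)
        for it in range(maxiter):
            eta = X @ beta
            r = fam.cell_score(eta, m, S, 1.0)
            W = fam.cell_weight(eta, m, 1.0)
            A = X.T @ (W[:, None] * X)
            try:
                step = np.linalg.solve(A, X.T @ r)
            except np.linalg.LinAlgError as exc:
                raise RuntimeError("singular information matrix in GEE/IRLS") from exc
            lam = 1.0
            for _ in range(30):  # step-halving guards sparse small samples
                cand = beta + lam * step
                obj_new = deviance_part(cand)
                if obj_new <= obj + 1e-12:
                    break
                lam *= 0.5
            beta = beta + lam * step
            obj = obj_new
            if np.max(np.abs(lam * step)) < tol:
                break
        else:
            raise RuntimeError("GEE/IRLS did not converge")

        eta = X @ beta
        r = fam.cell_score(eta, m, S, 1.0)
        W = fam.cell_weight(eta, m, 1.0)
        A = X.T @ (W[:, None] * X)
        A_inv = np.linalg.inv(A)
        # per-cluster score sums and information blocks
        N = c.n_clusters
        U = np.zeros((N, k))
        np.add.at(U, c.cluster, X * r[:, None])
        A_i = np.zeros((N, k, k))
        np.add.at(A_i, c.cluster, W[:, None, None] * np.einsum("ci,cj->cij", X, X))
        meat = np.einsum("ni,nj->ij", U, U)
        vcov_robust = A_inv @ meat @ A_inv
        if df_adjust:
            vcov_robust = vcov_robust * (N / max(N - k, 1))

        # model-based covariance (with estimated dispersion for gaussian)
        if fam.has_scale:
            mu = fam.mean(eta)
            pearson = float(np.sum(c.SS - 2.0 * S * mu + m * mu ** 2))
            scale = pearson / max(c.nobs - k, 1)
        else:
            scale = 1.0
        vcov_model = scale * A_inv

        return GEEResults(model=self, params=pd.Series(beta, index=c.labels),
                          _cov=vcov_robust, vcov_model=vcov_model,
                          cluster_scores=U, cluster_info=A_i, info=A,
                          scale=scale, llf=np.nan, converged=True,
                          separation=c.separated)


@dataclass
class GEEResults(FitResultsMixin):
    """Fitted marginal model with cluster-robust (sandwich) covariance."""

    model: ClusterGEE
    params: pd.Series
    _cov: np.ndarray                 # robust sandwich: the inferential covariance
    vcov_model: np.ndarray
    cluster_scores: np.ndarray       # (N, k) per-cluster summed scores
    cluster_info: np.ndarray         # (N, k, k) per-cluster model-based information
    info: np.ndarray                 # total model-based information
    scale: float
    llf: float
    converged: bool
    separation: bool = False

    @property
    def vcov_robust(self) -> np.ndarray:
        return self._cov

    @property
    def n_clusters(self) -> int:
        return self.model.cells.n_clusters

    @property
    def nobs(self) -> int:
        return self.model.cells.nobs

    def z_test(self, contrast):
        """Two-sided z-test of c'beta = 0 with the robust variance."""
        from .inference import TestResult
        c = self.contrast_vector(contrast)
        var = float(c @ self._cov @ c)
        if var <= 0:
            raise ValueError("robust variance of the contrast is zero")
        z = float(c @ self.params.to_numpy()) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
        return TestResult(statistic=z, df=None, p_value=p,
                          reject_at_005=p < 0.05, method="asymptotic_z")

    def fay_graubard_f_test(self, contrast, b: float = 0.75,
                            adjusted_statistic: bool = False):
        """Wald F-test with Fay-Graubard small-sample denominator df.

        The statistic uses the unadjusted sandwich variance by default; the
        bias-adjusted variant (``adjusted_statistic=True``) is exposed for
        sensitivity analyses.  The d-tilde denominator df is the
        Satterthwaite combination of per-cluster variance contributions
        built from the adjusted scores and the model-based information.
        """
        from .inference import TestResult
        c = self.contrast_vector(contrast)
        N, k = self.cluster_info.shape[0], len(c)
        if N < int(np.sum(self.model.cells.between)) + 1:
            raise ValueError("too few clusters for the Fay-Graubard F-test")
        try:
            A_inv = np.linalg.inv(self.info)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix; the Fay-Graubard "
                             "correction cannot be applied") from exc
        d_tilde, H = fay_graubard_df(c, self.cluster_info, self.info, b=b,
                                     return_H=True)
        if adjusted_statistic:
            G = np.einsum("nij,nj->ni", H, self.cluster_scores)
            meat = np.einsum("ni,nj->ij", G, G)
            var = float(c @ (A_inv @ meat @ A_inv) @ c)
        else:
            var = float(c @ self._cov @ c)
        if var <= 0:
            raise ValueError("robust variance of the contrast is zero")
        F = float(c @ self.params.to_numpy()) ** 2 / var
        p = stats.f.sf(F, 1, d_tilde)
        return TestResult(statistic=F, df=d_tilde, p_value=p,
                          reject_at_005=p < 0.05, method="fay_graubard",
                          extras={"df1": 1.0})


def fay_graubard_df(contrast, cluster_info, info, b: float = 0.75,
                    return_H: bool = False):
    """Fay-Graubard 'd-tilde' denominator degrees of freedom.

    The sandwich quadratic form for c'beta is sum_i z_i^2 with
    z_i = c'A^{-1} H_i U_i, where H_i = diag{(1 - min(b, [A_i A^{-1}]_jj))^{-1/2}}
    is the leverage adjustment with truncation constant ``b``.  Approximating
    E[U_i U_j'] by the model-based blocks (delta_ij A_i - A_i A^{-1} A_j,
    reflecting that the scores are residuals after estimating beta) gives the
    covariance matrix C of the z_i, and the Satterthwaite combination

        d = (tr C)^2 / ||C||_F^2.

    For I identical clusters this yields exactly I - 1.
    """
    c = np.asarray(contrast, dtype=float)
    A_inv = np.linalg.inv(info)
    N = cluster_info.shape[0]
    H = np.empty_like(cluster_info)
    a = np.empty((N, len(c)))
    for i in range(N):
        Q = cluster_info[i] @ A_inv
        adj = 1.0 / np.sqrt(1.0 - np.minimum(b, np.clip(np.diag(Q), 0.0, None)))
        H[i] = np.diag(adj)
        a[i] = H[i] @ A_inv @ c
    t = np.einsum("nij,nj->ni", cluster_info, a)      # t_i = A_i a_i
    diag = np.einsum("ni,ni->n", a, t)                # a_i' A_i a_i
    C = np.diag(diag) - t @ A_inv @ t.T
    denom = float(np.sum(C * C))
    if denom <= 0:
        raise ValueError("degenerate Fay-Graubard weights")
    d = float(np.trace(C)) ** 2 / denom
    return (d, H) if return_H else d
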