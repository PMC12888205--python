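"""Gaussian linear mixed models for cluster-randomized trial data.

The model is y_ij = x_ij' beta + z_ij' u_i + e_ij with u_i ~ N(0, Sigma_u)
independent across clusters and e_ij ~ N(0, sigma2).  The random-effect
design z is either a cluster intercept (``"intercept"``) or an intercept plus
subgroup-dummy slopes with unstructured covariance (``"maximal"``, the
reparametrization of subgroup-specific random intercepts).

Estimation profiles beta and sigma2 out of the (restricted) Gaussian
log-likelihood and optimizes the relative covariance factor Lambda
(Sigma_u = sigma2 * Lambda Lambda') over its Cholesky entries, with the
diagonal bounded at zero so boundary fits are reached exactly.  All
per-cluster quantities are computed from (cluster, subgroup)-cell
cross-products, so the cost per likelihood evaluation is O(N q^3) regardless
of cluster sizes.

Satterthwaite denominator degrees of freedom for Wald t-tests are computed
from finite-difference derivatives of the coefficient covariance and the
observed information of the variance parameters, the standard approach for
mixed-model t-tests with few clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import optimize

from . import _chol
from ._optim import minimize_covariance
from .design import Cells, collapse_cells
from .results import FitResultsMixin

__all__ = ["REStructure", "LinearMixedModel", "LMMResults", "satterthwaite_df"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class REStructure:
    """Random-effect structure: kind and per-cluster dimension."""

    kind: str  # "intercept_only" or "intercept_plus_subgroup_slopes"
    q_re: int

    @classmethod
    def from_name(cls, name: str, p: int) -> "REStructure":
        if name in ("intercept", "intercept_only", "glmm"):
            return cls("intercept_only", 1)
        if name in ("maximal", "intercept_plus_subgroup_slopes", "glmm2"):
            return cls("intercept_plus_subgroup_slopes", p)
        raise ValueError(f"unknown random-effect structure: {name!r}")

    @property
    def cells_key(self) -> str:
        return "intercept" if self.kind == "intercept_only" else "maximal"


class LinearMixedModel:
    """Linear mixed model built from long-format trial data.

    Parameters
    ----------
    data : TrialData or pandas.DataFrame
        Long-format data with columns cluster_id, trt, gr, y.
    re_structure : str
        "intercept" (common cluster intercept) or "maximal" (intercept plus
        subgroup random slopes, unstructured covariance).
    include_interaction : bool
        Drop the trt x gr columns to obtain the null model for LRTs.
    """

    def __init__(self, data, re_structure: str = "maximal",
                 include_interaction: bool = True):
        frame = data.frame if hasattr(data, "frame") else data
        self.frame = frame.reset_index(drop=True)
        self.structure = REStructure.from_name(re_structure, int(frame["gr"].max()) + 1)
        self.cells: Cells = collapse_cells(frame, family="gaussian",
                                           structure=self.structure.cells_key,
                                           include_interaction=include_interaction)
        if self.cells.n_clusters < 2:
            raise ValueError("a mixed model requires at least 2 clusters")
        self._precompute()

    # -- sufficient statistics ---------------------------------------------
    def _precompute(self):
        c = self.cells
        N, k, q = c.n_clusters, c.k_fixed, c.q_re
        self.Cxx = np.zeros((N, k, k))
        self.Cxy = np.zeros((N, k))
        self.Cyy = np.zeros(N)
        self.Czz = np.zeros((N, q, q))
        self.Czx = np.zeros((N, q, k))
        self.Czy = np.zeros((N, q))
        np.add.at(self.Cxx, c.cluster, np.einsum("c,ci,cj->cij", c.m, c.X, c.X))
        np.add.at(self.Cxy, c.cluster, c.X * c.S[:, None])
        np.add.at(self.Cyy, c.cluster, c.SS)
        np.add.at(self.Czz, c.cluster, np.einsum("c,ci,cj->cij", c.m, c.Z, c.Z))
        np.add.at(self.Czx, c.cluster, np.einsum("c,ci,cj->cij", c.m, c.Z, c.X))
        np.add.at(self.Czy, c.cluster, c.Z * c.S[:, None])
        XtX = self.Cxx.sum(axis=0)
        if np.linalg.matrix_rank(XtX) < k:
            raise ValueError("fixed-effect design is rank deficient")

    # -- likelihood machinery ----------------------------------------------
    def _gls_pieces(self, theta):
        """Profile-out quantities for a relative covariance factor."""
        c = self.cells
        q = c.q_re
        Lam = _chol.build_lower(theta, q)
        M = np.eye(q)[None] + np.einsum("ab,nbc,cd->nad", Lam.T, self.Czz, Lam)
        cholM = np.linalg.cholesky(M)
        logdet = 2.0 * np.log(np.einsum("nii->ni", cholM)).sum()
        Wzx = np.einsum("ab,nbk->nak", Lam.T, self.Czx)
        wzy = np.einsum("ab,nb->na", Lam.T, self.Czy)
        MiW = np.linalg.solve(M, Wzx)
        Miw = np.linalg.solve(M, wzy[..., None])[..., 0]
        XtViX = self.Cxx.sum(0) - np.einsum("nak,nal->kl", Wzx, MiW)
        XtViy = self.Cxy.sum(0) - np.einsum("nak,na->k", Wzx, Miw)
        ytViy = self.Cyy.sum() - np.einsum("na,na->", wzy, Miw)
        beta = np.linalg.solve(XtViX, XtViy)
        r2 = max(float(ytViy - XtViy @ beta), 1e-12)
        return Lam, logdet, XtViX, XtViy, ytViy, beta, r2

    def profiled_loglik(self, theta, method: str = "REML"):
        """(loglik, beta, sigma2) at the profiled optimum for given theta."""
        n, k = self.cells.nobs, self.cells.k_fixed
        Lam, logdet, XtViX, XtViy, ytViy, beta, r2 = self._gls_pieces(theta)
        if method == "ML":
            sigma2 = r2 / n
            ll = -0.5 * (logdet + n * (_LOG2PI + np.log(sigma2)) + n)
        elif method == "REML":
            sigma2 = r2 / (n - k)
            sign, ld_x = np.linalg.slogdet(XtViX)
            ll = -0.5 * (logdet + (n - k) * (_LOG2PI + np.log(sigma2)) + (n - k)
                         + ld_x - k * np.log(sigma2))
        else:
            raise ValueError("method must be 'ML' or 'REML'")
        return ll, beta, sigma2

    def loglik(self, theta, sigma2, method: str = "REML") -> float:
        """(Restricted) log-likelihood at arbitrary variance parameters.

        beta is held at its GLS optimum given theta (the standard profiling
        used when differentiating over variance parameters).
        """
        n, k = self.cells.nobs, self.cells.k_fixed
        Lam, logdet, XtViX, XtViy, ytViy, beta, r2 = self._gls_pieces(theta)
        if method == "ML":
            return -0.5 * (logdet + n * (_LOG2PI + np.log(sigma2)) + r2 / sigma2)
        sign, ld_x = np.linalg.slogdet(XtViX)
        return -0.5 * (logdet + (n - k) * (_LOG2PI + np.log(sigma2)) + r2 / sigma2
                       + ld_x - k * np.log(sigma2))

    def cov_beta(self, theta, sigma2) -> np.ndarray:
        _, _, XtViX, _, _, _, _ = self._gls_pieces(theta)
        return sigma2 * np.linalg.inv(XtViX)

    # -- fitting -------------------------------------------------------------
    def _start(self, fraction: float) -> np.ndarray:
        q = self.cells.q_re
        # RE variance = `fraction` of total outcome variance, residual the rest
        d = np.sqrt(fraction / max(1.0 - fraction, 1e-3))
        theta = np.zeros(_chol.n_theta(q))
        theta[_chol.diag_positions(q)] = d
        return theta

    def fit(self, method: str = "REML", start=None, singular_tol: float = 1e-4,
            maxiter: int = 500) -> "LMMResults":
        """Maximize the profiled (restricted) likelihood over theta."""
        q = self.cells.q_re
        bounds = _chol.theta_bounds(q)

        def neg(theta):
            try:
                return -self.profiled_loglik(theta, method)[0]
            except np.linalg.LinAlgError:
                return 1e10

        starts = [np.asarray(start, dtype=float)] if start is not None else \
            [self._start(0.1), self._start(0.5)]
        theta, _, converged = minimize_covariance(
            neg, starts, bounds, _chol.diag_positions(q), maxiter=maxiter)
        ll, beta, sigma2 = self.profiled_loglik(theta, method)
        Lam = _chol.build_lower(theta, q)
        cov_beta = self.cov_beta(theta, sigma2)
        re_cov = sigma2 * Lam @ Lam.T
        singular = _chol.is_singular_chol(np.sqrt(sigma2) * Lam, tol=singular_tol)
        return LMMResults(model=self, method=method,
                          params=pd.Series(beta, index=self.cells.labels),
                          _cov=cov_beta, scale=float(sigma2), re_cov=re_cov,
                          theta=theta, llf=float(ll), converged=bool(converged),
                          singular=bool(singular))


@dataclass
class LMMResults(FitResultsMixin):
    """Fitted linear mixed model."""

    model: LinearMixedModel
    method: str
    params: pd.Series
    _cov: np.ndarray
    scale: float            # residual variance estimate
    re_cov: np.ndarray      # random-effect covariance (intercept+slope scale)
    theta: np.ndarray       # relative Cholesky entries at the optimum
    llf: float
    converged: bool
    singular: bool
    optimizer_message: str = ""

    @property
    def n_clusters(self) -> int:
        return self.model.cells.n_clusters

    @property
    def nobs(self) -> int:
        return self.model.cells.nobs

    @property
    def resid_var_hat(self) -> float:
        return self.scale

    def subgroup_covariance(self) -> np.ndarray:
        """Random-effect covariance on the subgroup-specific scale."""
        if self.model.structure.kind == "intercept_only":
            p = self.model.cells.n_levels
            return float(self.re_cov[0, 0]) * np.ones((p, p))
        return _chol.intercept_slope_to_subgroup(self.re_cov)

    def satterthwaite_df(self, contrast) -> float:
        return satterthwaite_df(self, contrast)

    def _summary_extra(self):
        return [f"method: {self.method}   residual var: {self.scale:.4f}   "
                f"singular: {self.singular}",
                "RE covariance (intercept+slope): "
                + np.array2string(self.re_cov, precision=4)]

    def _json_payload(self):
        d = super()._json_payload()
        d.update({"method": self.method, "resid_var": self.scale,
                  "re_cov": [float(v) for v in self.re_cov.ravel()],
                  "singular": bool(self.singular)})
        return d


def satterthwaite_df(fit: LMMResults, contrast, rel_step: float = 1e-4) -> float:
    """Satterthwaite denominator df for the Wald t-test of c'beta.

    df = 2 (c'C c)^2 / (grad' A grad), where C(gamma) is the fixed-effect
    covariance as a function of the variance parameters gamma = (relative
    Cholesky entries, log sigma2), grad is the finite-difference gradient of
    g(gamma) = c'C(gamma)c, and A is the inverse observed information of the
    (restricted) log-likelihood in gamma.  Bounded below at 1.
    """
    if not fit.converged:
        raise ValueError("Satterthwaite df requires a converged fit")
    model = fit.model
    c = fit.contrast_vector(contrast)
    gamma0 = np.concatenate([fit.theta, [np.log(fit.scale)]])
    d = len(gamma0)

    def g(gamma):
        cov = model.cov_beta(gamma[:-1], np.exp(gamma[-1]))
        return float(c @ cov @ c)

    def ll(gamma):
        return model.loglik(gamma[:-1], np.exp(gamma[-1]), fit.method)

    h = rel_step * np.maximum(np.abs(gamma0), 1.0)
    try:
        return _satterthwaite_core(g, ll, gamma0, h, d)
    except np.linalg.LinAlgError as exc:
        raise ValueError("linear algebra failure in the Satterthwaite "
                         "computation; use a fallback degrees-of-freedom "
                         f"method ({exc})") from exc


def _satterthwaite_core(g, ll, gamma0, h, d) -> float:
    grad = np.empty(d)
    for i in range(d):
        e = np.zeros(d); e[i] = h[i]
        grad[i] = (g(gamma0 + e) - g(gamma0 - e)) / (2.0 * h[i])

    H = np.empty((d, d))
    f0 = ll(gamma0)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        H[i, i] = (ll(gamma0 + ei) - 2.0 * f0 + ll(gamma0 - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = h[j]
            H[i, j] = H[j, i] = (ll(gamma0 + ei + ej) - ll(gamma0 + ei - ej)
                                 - ll(gamma0 - ei + ej) + ll(gamma0 - ei - ej)) \
                / (4.0 * h[i] * h[j])
    info = -H
    if not np.all(np.isfinite(info)):
        raise ValueError("observed information is not finite; use a fallback "
                         "degrees-of-freedom method")
    # boundary fits can make the information singular: use a pseudo-inverse
    A = np.linalg.pinv(info, rcond=1e-10, hermitian=True)
    g0 = g(gamma0)
    denom = float(grad @ A @ grad)
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError("Satterthwaite variance of the variance estimate is "
                         "degenerate; use a fallback degrees-of-freedom method")
    return max(2.0 * g0 ** 2 / denom, 1.0)
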