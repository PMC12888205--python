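"""Poisson and Bernoulli GLMMs via the Laplace approximation.

The marginal likelihood integrates the per-cluster random effects out of the
conditional exponential-family likelihood; with a non-identity link no closed
form exists, and the integral is replaced by its Laplace approximation (a
second-order expansion at the conditional mode), the default strategy of the
standard mixed-model software this package mirrors.  For the Gaussian family
the integrand is quadratic, the approximation is exact, and the fit
reproduces the linear mixed model.

Fitting follows the same profiling strategy as that software: for each value
of the random-effect covariance factor, the fixed effects and conditional
modes solve a penalized iteratively-reweighted least-squares (PIRLS) problem,
and the resulting profiled Laplace objective is optimized over the Cholesky
entries of the covariance factor (diagonal bounded at zero, so boundary
"singular" fits are reached exactly).  The covariance of the fixed effects
conditions on the estimated covariance parameters: it is the inverse Schur
complement of the fixed-effect block of the joint penalized Hessian, matching
the Wald output of the reference implementation.

Random effects are spherically reparametrized, u_i = Lambda v_i with
v_i ~ N(0, I): all computations use the factor Lambda, never Sigma^{-1}, so
boundary covariances are handled without special cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from . import _chol
from ._optim import minimize_covariance
from .design import Cells, collapse_cells
from .families import get_family
from .lmm import REStructure
from .results import FitResultsMixin

__all__ = ["MixedGLM", "GLMMResults", "conditional_mode", "laplace_loglik",
           "is_singular"]

_LOG2PI = np.log(2.0 * np.pi)


class PirlsError(RuntimeError):
    """Inner penalized-IRLS failure (carried to the fit level)."""


def conditional_mode(X, Z, m, S, beta, Sigma, family, scale=None, SS=None,
                     tol: float = 1e-8, max_newton: int = 100,
                     max_halving: int = 30):
    """Conditional mode of one cluster's random effect given (beta, Sigma).

    Maximizes sum_cells loglik(y | u) - u' Sigma^{-1} u / 2 by Newton
    iterations with step-halving; returns ``(u_hat, H)`` where H is the
    negative Hessian at the mode.  ``X, Z, m, S`` are the cluster's cell
    design rows and sufficient statistics.
    """
    fam = get_family(family)
    Sigma = np.asarray(Sigma, dtype=float)
    q = Sigma.shape[0]
    w_eig = np.linalg.eigvalsh(Sigma)
    if w_eig.min() <= 0:
        raise ValueError("Sigma must be positive-definite for the conditional mode")
    Sinv = np.linalg.inv(Sigma)
    if SS is None:
        SS = np.zeros_like(np.asarray(S, dtype=float))
    xb = np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    Z = np.asarray(Z, dtype=float)

    def obj(u):
        eta = xb + Z @ u
        return float(np.sum(fam.cell_loglik(eta, m, S, SS, scale))
                     - 0.5 * u @ Sinv @ u)

    u = np.zeros(q)
    f = obj(u)
    for _ in range(max_newton):
        eta = xb + Z @ u
        grad = Z.T @ fam.cell_score(eta, m, S, scale) - Sinv @ u
        if np.max(np.abs(grad)) < tol:
            break
        W = fam.cell_weight(eta, m, scale)
        H = Z.T @ (W[:, None] * Z) + Sinv
        step = np.linalg.solve(H, grad)
        lam = 1.0
        for _ in range(max_halving):
            f_new = obj(u + lam * step)
            if f_new >= f - 1e-12:
                break
            lam *= 0.5
        else:
            raise PirlsError("step-halving failed in conditional-mode Newton")
        u = u + lam * step
        f = f_new
    else:
        raise PirlsError("conditional-mode Newton did not converge")
    eta = xb + Z @ u
    H = Z.T @ (fam.cell_weight(eta, m, scale)[:, None] * Z) + Sinv
    return u, H


def laplace_loglik(data, beta, Sigma, family, scale=None) -> float:
    """Laplace-approximated marginal log-likelihood at given parameters.

    Sum over clusters of  log f(y|u_hat) - u_hat'Sigma^{-1}u_hat/2
    - log det(Sigma)/2 - log det(H)/2, where H is the negative conditional
    Hessian at the mode (the (q/2) log 2pi factors of the Gaussian prior and
    of the Laplace integral cancel).  Exact for the Gaussian family.
    """
    fam = get_family(family)
    Sigma = np.asarray(Sigma, dtype=float)
    q = Sigma.shape[0]
    if np.linalg.eigvalsh(Sigma).min() <= 0:
        raise ValueError("Sigma is singular; use the boundary-aware factor "
                         "parametrization (MixedGLM) instead")
    frame = data.frame if hasattr(data, "frame") else data
    structure = "intercept" if q == 1 else "maximal"
    cells = collapse_cells(frame, family=fam, structure=structure)
    if cells.q_re != q:
        raise ValueError(f"Sigma dimension {q} does not match the design "
                         f"({cells.q_re} random-effect columns)")
    Sinv = np.linalg.inv(Sigma)
    sign, logdet_S = np.linalg.slogdet(Sigma)
    beta = np.asarray(beta, dtype=float)
    total = cells.loglik_const
    for i in range(cells.n_clusters):
        sel = cells.cluster == i
        u, H = conditional_mode(cells.X[sel], cells.Z[sel], cells.m[sel],
                                cells.S[sel], beta, Sigma, fam, scale=scale,
                                SS=cells.SS[sel])
        eta = cells.X[sel] @ beta + cells.Z[sel] @ u
        ll_cond = float(np.sum(fam.cell_loglik(eta, cells.m[sel], cells.S[sel],
                                               cells.SS[sel], scale)))
        sign_h, logdet_H = np.linalg.slogdet(H)
        total += (ll_cond - 0.5 * u @ Sinv @ u - 0.5 * logdet_S
                  - 0.5 * logdet_H)
    return float(total)


class MixedGLM:
    """GLMM for clustered trial data, fitted by Laplace approximation.

    Parameters
    ----------
    data : TrialData or DataFrame
    family : str
        "poisson", "bernoulli" or "gaussian" (the latter mainly to validate
        against the exact linear-mixed-model path).
    re_structure : str
        "intercept" or "maximal".
    include_interaction : bool
        Drop trt x gr columns for the LRT null model.
    """

    def __init__(self, data, family, re_structure: str = "maximal",
                 include_interaction: bool = True):
        frame = data.frame if hasattr(data, "frame") else data
        self.frame = frame.reset_index(drop=True)
        self.family = get_family(family)
        self.structure = REStructure.from_name(re_structure,
                                               int(frame["gr"].max()) + 1)
        self.cells: Cells = collapse_cells(frame, family=self.family,
                                           structure=self.structure.cells_key,
                                           include_interaction=include_interaction)
        if self.cells.n_clusters < 2:
            raise ValueError("a mixed model requires at least 2 clusters")
        c = self.cells
        # per-cell outer products aggregated into per-cluster u-space blocks
        self._zz = np.einsum("ci,cj->cij", c.Z, c.Z)
        self._xz = np.einsum("ci,cj->cij", c.X, c.Z)
        self._xx = np.einsum("ci,cj->cij", c.X, c.X)
        self._beta0 = self._glm_start()
        self._warm = None
        self._warm_v = None

    # ------------------------------------------------------------------
    def _glm_start(self) -> np.ndarray:
        """Plain GLM coefficients (no random effects) as a starting value."""
        beta, v, _, _, _ = self._pirls(np.zeros((self.cells.q_re, self.cells.q_re)),
                                       np.zeros(self.cells.k_fixed),
                                       np.zeros((self.cells.n_clusters,
                                                 self.cells.q_re)),
                                       scale=1.0)
        return beta

    def _pen_obj(self, eta, v, scale):
        c = self.cells
        return float(np.sum(self.family.cell_loglik(eta, c.m, c.S, c.SS, scale))
                     - 0.5 * np.sum(v * v))

    def _pirls(self, Lam, beta, v, scale=None, tol: float = 1e-8,
               maxiter: int = 100, max_halving: int = 30):
        """Joint penalized Newton over (beta, v) for a fixed factor Lambda.

        Returns (beta, v, eta, A_u, pen) where A_u stacks the per-cluster
        u-space weighted cross-products Z'WZ at the solution.
        """
        c = self.cells
        N, q, k = c.n_clusters, c.q_re, c.k_fixed
        fam = self.family
        X, Z, cl = c.X, c.Z, c.cluster
        beta = beta.copy()
        v = v.copy()

        u = v @ Lam.T
        eta = X @ beta + np.einsum("cq,cq->c", Z, u[cl])
        pen = self._pen_obj(eta, v, scale)
        A_u = None
        for _ in range(maxiter):
            r = fam.cell_score(eta, c.m, c.S, scale)
            gu = np.zeros((N, q))
            np.add.at(gu, cl, Z * r[:, None])
            gv = gu @ Lam - v          # gu @ Lam == Lam.T applied per row
            gb = X.T @ r
            gmax = max(np.max(np.abs(gb)), np.max(np.abs(gv)) if gv.size else 0.0)
            W = fam.cell_weight(eta, c.m, scale)
            A_u = np.zeros((N, q, q))
            np.add.at(A_u, cl, W[:, None, None] * self._zz)
            if gmax < tol:
                break
            B = np.einsum("ab,nbc,cd->nad", Lam.T, A_u, Lam) + np.eye(q)[None]
            Cxu = np.zeros((N, k, q))
            np.add.at(Cxu, cl, W[:, None, None] * self._xz)
            Cb = Cxu @ Lam
            Hbb = np.einsum("c,cij->ij", W, self._xx)
            Binv_gv = np.linalg.solve(B, gv[..., None])[..., 0]
            Binv_Ct = np.linalg.solve(B, Cb.transpose(0, 2, 1))
            Sbb = Hbb - np.einsum("nkq,nql->kl", Cb, Binv_Ct)
            rhs = gb - np.einsum("nkq,nq->k", Cb, Binv_gv)
            db = np.linalg.solve(Sbb, rhs)
            dv = Binv_gv - np.einsum("nqk,k->nq", Binv_Ct, db)
            lam_step = 1.0
            for _ in range(max_halving):
                beta_n = beta + lam_step * db
                v_n = v + lam_step * dv
                u_n = v_n @ Lam.T
                eta_n = X @ beta_n + np.einsum("cq,cq->c", Z, u_n[cl])
                pen_n = self._pen_obj(eta_n, v_n, scale)
                if pen_n >= pen - 1e-12:
                    break
                lam_step *= 0.5
            else:
                raise PirlsError("step-halving failed in PIRLS")
            beta, v, eta, pen = beta_n, v_n, eta_n, pen_n
        else:
            raise PirlsError("PIRLS did not converge")
        return beta, v, eta, A_u, pen

    def profiled_laplace(self, theta, log_scale=None, warm=True):
        """Profiled Laplace log-likelihood at covariance factor theta.

        Returns (loglik, beta, v, A_u, Lam, scale).
        """
        q = self.cells.q_re
        Lam = _chol.build_lower(theta, q)
        scale = None if log_scale is None else float(np.exp(log_scale))
        if warm and self._warm is not None:
            beta, v = self._warm
        else:
            beta = self._beta0.copy()
            v = np.zeros((self.cells.n_clusters, q))
        beta, v, eta, A_u, pen = self._pirls(Lam, beta, v, scale=scale)
        if warm:
            self._warm = (beta.copy(), v.copy())
        B = np.einsum("ab,nbc,cd->nad", Lam.T, A_u, Lam) + np.eye(q)[None]
        sign, logdetB = np.linalg.slogdet(B)
        ll = pen - 0.5 * float(logdetB.sum()) + self.cells.loglik_const
        return ll, beta, v, A_u, Lam, scale

    def _modes(self, Lam, beta, v, scale=None, tol: float = 1e-8,
               maxiter: int = 100, max_halving: int = 30):
        """Conditional modes v (all clusters, vectorized Newton) at fixed beta."""
        c = self.cells
        N, q = c.n_clusters, c.q_re
        X, Z, cl = c.X, c.Z, c.cluster
        xb = X @ beta
        v = v.copy()
        eta = xb + np.einsum("cq,cq->c", Z, (v @ Lam.T)[cl])
        pen = self._pen_obj(eta, v, scale)
        A_u = None
        for _ in range(maxiter):
            r = self.family.cell_score(eta, c.m, c.S, scale)
            gu = np.zeros((N, q))
            np.add.at(gu, cl, Z * r[:, None])
            gv = gu @ Lam - v
            W = self.family.cell_weight(eta, c.m, scale)
            A_u = np.zeros((N, q, q))
            np.add.at(A_u, cl, W[:, None, None] * self._zz)
            if np.max(np.abs(gv)) < tol:
                break
            B = np.einsum("ab,nbc,cd->nad", Lam.T, A_u, Lam) + np.eye(q)[None]
            dv = np.linalg.solve(B, gv[..., None])[..., 0]
            lam_step = 1.0
            for _ in range(max_halving):
                v_n = v + lam_step * dv
                eta_n = xb + np.einsum("cq,cq->c", Z, (v_n @ Lam.T)[cl])
                pen_n = self._pen_obj(eta_n, v_n, scale)
                if pen_n >= pen - 1e-12:
                    break
                lam_step *= 0.5
            else:
                raise PirlsError("step-halving failed in conditional-mode Newton")
            v, eta, pen = v_n, eta_n, pen_n
        else:
            raise PirlsError("conditional-mode Newton did not converge")
        return v, eta, A_u, pen

    def joint_laplace(self, theta, beta, log_scale=None, warm=True):
        """Laplace log-likelihood at (theta, beta) with only the modes profiled.

        Unlike :meth:`profiled_laplace`, the log-determinant term's
        dependence on beta is fully accounted for; this is the objective of
        the final joint optimization stage.
        """
        q = self.cells.q_re
        Lam = _chol.build_lower(theta, q)
        scale = None if log_scale is None else float(np.exp(log_scale))
        v0 = self._warm_v if (warm and self._warm_v is not None) \
            else np.zeros((self.cells.n_clusters, q))
        v, eta, A_u, pen = self._modes(Lam, np.asarray(beta, dtype=float), v0,
                                       scale=scale)
        if warm:
            self._warm_v = v.copy()
        B = np.einsum("ab,nbc,cd->nad", Lam.T, A_u, Lam) + np.eye(q)[None]
        sign, logdetB = np.linalg.slogdet(B)
        return pen - 0.5 * float(logdetB.sum()) + self.cells.loglik_const, v, A_u, Lam, scale

    def _theta_start(self, variance: float) -> np.ndarray:
        q = self.cells.q_re
        theta = np.zeros(_chol.n_theta(q))
        theta[_chol.diag_positions(q)] = np.sqrt(variance)
        return theta

    def fit(self, start=None, singular_tol: float = 1e-4,
            maxiter: int = 500, joint: bool = True) -> "GLMMResults":
        """Maximize the Laplace objective.

        Two stages, mirroring the reference mixed-model software: first the
        covariance factor alone is optimized with the fixed effects profiled
        by PIRLS (which neglects the log-determinant's dependence on beta),
        then — unless ``joint=False`` — (beta, theta) are optimized jointly
        against the exact Laplace objective with only the conditional modes
        profiled.
        """
        q = self.cells.q_re
        gaussian = self.family.has_scale
        nt = _chol.n_theta(q)
        bounds = _chol.theta_bounds(q)
        if gaussian:
            c = self.cells
            var_y = max(float(np.sum(c.SS) / c.nobs
                              - (np.sum(c.S) / c.nobs) ** 2), 1e-6)
            bounds = bounds + [(None, None)]

        history = []

        def neg(x):
            try:
                ll = self.profiled_laplace(x[:nt],
                                           x[nt] if gaussian else None)[0]
            except (PirlsError, np.linalg.LinAlgError):
                return 1e10
            return -ll

        def track(xk):
            history.append(neg(xk))

        if start is not None:
            starts = [np.asarray(start, dtype=float)]
        elif gaussian:
            starts = [np.concatenate([self._theta_start(frac * var_y),
                                      [np.log((1 - frac) * var_y)]])
                      for frac in (0.1, 0.5)]
        else:
            # unit diagonal first: the reference software's default start,
            # whose optimization path defines the boundary-hit (singular-fit)
            # behaviour this package characterizes; a closer-in start is the
            # fallback on failure
            starts = [self._theta_start(1.0), self._theta_start(0.1)]
        self._warm = None
        x_hat, _, converged = minimize_covariance(
            neg, starts, bounds, _chol.diag_positions(q), maxiter=maxiter,
            track=track)
        _, beta1, _, _, _, _ = self.profiled_laplace(
            x_hat[:nt], x_hat[nt] if gaussian else None, warm=False)

        if joint:
            # stage 2: beta joins the outer optimization of the exact
            # Laplace objective (the PIRLS profile neglects the beta
            # dependence of the log-determinant term)
            k = self.cells.k_fixed
            if gaussian:
                x2 = np.concatenate([x_hat[:nt], beta1, [x_hat[nt]]])
            else:
                x2 = np.concatenate([x_hat[:nt], beta1])
            bounds2 = (_chol.theta_bounds(q) + [(None, None)] * k
                       + ([(None, None)] if gaussian else []))

            def neg2(x):
                try:
                    return -self.joint_laplace(
                        x[:nt], x[nt:nt + k],
                        x[nt + k] if gaussian else None)[0]
                except (PirlsError, np.linalg.LinAlgError):
                    return 1e10

            self._warm_v = None
            x2_hat, _, conv2 = minimize_covariance(
                neg2, [x2], bounds2, _chol.diag_positions(q), maxiter=maxiter,
                track=track)
            converged = converged and conv2
            x_hat = np.concatenate([x2_hat[:nt], [x2_hat[nt + k]]]) if gaussian \
                else x2_hat[:nt]
            beta = x2_hat[nt:nt + k]
            self._warm_v = None
            ll, v, A_u, Lam, scale = self.joint_laplace(
                x_hat[:nt], beta, x_hat[nt] if gaussian else None, warm=False)
        else:
            self._warm = None
            ll, beta, v, A_u, Lam, scale = self.profiled_laplace(
                x_hat[:nt], x_hat[nt] if gaussian else None, warm=False)
        final_decrease = abs(history[-2] - history[-1]) if len(history) > 1 else 0.0
        B = np.einsum("ab,nbc,cd->nad", Lam.T, A_u, Lam) + np.eye(q)[None]
        # fixed-effect covariance: inverse Schur complement of the beta block
        c = self.cells
        eta = c.X @ beta + np.einsum("cq,cq->c", c.Z, (v @ Lam.T)[c.cluster])
        W = self.family.cell_weight(eta, c.m, scale)
        Cxu = np.zeros((c.n_clusters, c.k_fixed, q))
        np.add.at(Cxu, c.cluster, W[:, None, None] * self._xz)
        Cb = Cxu @ Lam
        Hbb = np.einsum("c,cij->ij", W, self._xx)
        Sbb = Hbb - np.einsum("nkq,nql->kl", Cb, np.linalg.solve(B, Cb.transpose(0, 2, 1)))
        cov_beta = np.linalg.inv(Sbb)

        re_cov = Lam @ Lam.T
        singular = _chol.is_singular_chol(Lam, tol=singular_tol)
        return GLMMResults(model=self,
                           params=pd.Series(beta, index=c.labels),
                           _cov=cov_beta, re_cov=re_cov, theta=x_hat[:nt],
                           scale=scale, llf=float(ll), converged=bool(converged),
                           singular=bool(singular), ranef_modes=v @ Lam.T,
                           cond_hessians_v=B, chol_factor=Lam,
                           separation=self.cells.separated,
                           final_objective_decrease=float(final_decrease))


@dataclass
class GLMMResults(FitResultsMixin):
    """Fitted Laplace GLMM."""

    model: MixedGLM
    params: pd.Series
    _cov: np.ndarray
    re_cov: np.ndarray          # intercept+slope covariance Lambda Lambda'
    theta: np.ndarray
    scale: Optional[float]      # residual variance (gaussian family only)
    llf: float
    converged: bool
    singular: bool
    ranef_modes: np.ndarray     # conditional modes u_hat (N x q)
    cond_hessians_v: np.ndarray  # spherical-scale conditional Hessians (N,q,q)
    chol_factor: np.ndarray
    separation: bool = False
    final_objective_decrease: float = 0.0
    optimizer_message: str = ""

    @property
    def n_clusters(self) -> int:
        return self.model.cells.n_clusters

    @property
    def nobs(self) -> int:
        return self.model.cells.nobs

    def subgroup_covariance(self) -> np.ndarray:
        if self.model.structure.kind == "intercept_only":
            p = self.model.cells.n_levels
            return float(self.re_cov[0, 0]) * np.ones((p, p))
        return _chol.intercept_slope_to_subgroup(self.re_cov)

    def _summary_extra(self):
        out = [f"family: {self.model.family.name}   singular: {self.singular}",
               "RE covariance (intercept+slope): "
               + np.array2string(self.re_cov, precision=4)]
        if self.separation:
            out.append("warning: complete separation in a design cell; "
                       "estimates may be unstable")
        return out

    def _json_payload(self):
        d = super()._json_payload()
        d.update({"family": self.model.family.name,
                  "re_cov": [float(v) for v in self.re_cov.ravel()],
                  "singular": bool(self.singular),
                  "separation": bool(self.separation)})
        return d


def is_singular(fit, tol: float = 1e-4) -> bool:
    """Boundary test for a fitted mixed model (zero variance or unit correlation)."""
    if hasattr(fit, "chol_factor"):
        return _chol.is_singular_chol(fit.chol_factor, tol=tol)
    # LMM results: rebuild the factor on the absolute covariance scale
    q = fit.re_cov.shape[0]
    L = np.sqrt(fit.scale) * _chol.build_lower(fit.theta, q)
    return _chol.is_singular_chol(L, tol=tol)
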