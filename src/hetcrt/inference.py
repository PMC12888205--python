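"""Hypothesis tests for treatment-effect heterogeneity in CRTs.

The null of interest is no effect modification: the treatment-by-subgroup
interaction coefficient(s) equal zero.  Available decisions:

* Wald t (or z) tests of a single interaction coefficient, with selectable
  denominator degrees of freedom for few-cluster designs: Satterthwaite
  (continuous outcomes), "residual-cluster" df (clusters minus cluster-level
  fixed-effect parameters), or "between-within" df;
* the Fay-Graubard Wald F-test for GEE fits;
* a parametric-bootstrap percentile confidence interval (decision: 0 outside
  the interval);
* the likelihood-ratio chi-square test of the global null when the subgroup
  has more than two levels;
* a two-step procedure that fits the maximal model first and falls back to
  the common-intercept model after a singular fit;
* the correction selector mapping (true model, fitted model, outcome type)
  to the small-sample method that maintained the nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .design import build_design
from .gee import GEEResults
from .glmm import MixedGLM, GLMMResults
from .lmm import LinearMixedModel, LMMResults

__all__ = [
    "DF_METHODS", "TestResult", "wald_t_test", "residual_cluster_df",
    "between_within_df", "parametric_bootstrap_test", "lrt_global",
    "two_step_test", "select_correction", "apply_test",
]

DF_METHODS = ("asymptotic_z", "satterthwaite", "residual_cluster",
              "between_within", "bootstrap", "fay_graubard")


@dataclass
class TestResult:
    """Outcome of one HTE test."""

    statistic: Optional[float]
    df: Optional[float]
    p_value: Optional[float]
    reject_at_005: bool
    method: str
    ci: Optional[tuple] = None
    used_fallback: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.p_value is None and self.ci is None:
            raise ValueError("a test result needs a p-value or a confidence interval")
        if self.p_value is not None:
            self.reject_at_005 = bool(self.p_value < 0.05)
        elif self.ci is not None:
            self.reject_at_005 = not (self.ci[0] <= 0.0 <= self.ci[1])

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df,
                "p_value": self.p_value, "ci": self.ci,
                "reject_at_0.05": self.reject_at_005, "method": self.method,
                "used_fallback": self.used_fallback}


def _single_coefficient(fit, contrast) -> int:
    c = fit.contrast_vector(contrast)
    nz = np.flatnonzero(c)
    if len(nz) != 1:
        raise ValueError("this degrees-of-freedom method needs a contrast "
                         "targeting a single coefficient")
    return int(nz[0])


def residual_cluster_df(n_clusters: int, between_labels) -> int:
    """Clusters minus the number of cluster-level fixed-effect parameters.

    ``between_labels`` may be the count itself or a boolean/between mask.
    """
    q = int(between_labels) if np.isscalar(between_labels) \
        else int(np.sum(np.asarray(between_labels, dtype=bool)))
    df = n_clusters - q
    if df <= 0:
        raise ValueError(f"residual-cluster df is nonpositive ({n_clusters} clusters, "
                         f"{q} cluster-level parameters)")
    return df


def between_within_df(fit, contrast, interaction_as: str = "between") -> float:
    """Between-within denominator df for a single-coefficient contrast.

    Each fixed-effect column is classified as "between" (tested against
    N - q_between df) or "within" (tested against M - N - q_within df, M the
    total number of observations).  Columns constant within every cluster
    (intercept, treatment) are always between; pure within-cluster columns
    (the subgroup dummies) are always within.

    ``interaction_as`` controls the treatment-by-subgroup interaction, whose
    classification differs between implementations of the method:

    * ``"between"`` (default): any term containing the cluster-level
      treatment factor inherits the between-cluster df.  This matches the
      behaviour of the mixed-model helper software whose corrected tests
      this package's few-cluster defaults reproduce, and makes the
      interaction test conservative when clusters are few.
    * ``"within"``: the classical rule — a column that varies inside any
      cluster gets the within df.
    """
    if interaction_as not in ("between", "within"):
        raise ValueError("interaction_as must be 'between' or 'within'")
    cells = fit.model.cells
    j = _single_coefficient(fit, contrast)
    labels = cells.labels
    between = cells.between.copy()
    if interaction_as == "between":
        for idx, lab in enumerate(labels):
            if lab.startswith("trt:"):
                between[idx] = True
    n, M = cells.n_clusters, cells.nobs
    if M == n:
        raise ValueError("within-cluster df undefined: every cluster has size 1")
    q_between = int(between.sum())
    q_within = int((~between).sum())
    if between[j]:
        df = n - q_between
    else:
        df = M - n - q_within
    if df <= 0:
        raise ValueError("nonpositive between-within df")
    return float(df)


def wald_t_test(fit, contrast, df_method: str = "asymptotic_z",
                n_clusters: Optional[int] = None) -> TestResult:
    """Wald test of c'beta = 0 with the requested denominator df."""
    if df_method not in DF_METHODS:
        raise ValueError(f"unknown df method: {df_method!r}")
    if df_method == "fay_graubard":
        if not isinstance(fit, GEEResults):
            raise ValueError("fay_graubard applies to GEE fits only")
        return fit.fay_graubard_f_test(contrast)
    if df_method == "bootstrap":
        raise ValueError("use parametric_bootstrap_test for the bootstrap decision")
    if df_method == "satterthwaite" and not isinstance(fit, LMMResults):
        raise ValueError("Satterthwaite df applies to Gaussian mixed fits only")

    c = fit.contrast_vector(contrast)
    var = float(c @ np.asarray(fit.cov_params()) @ c)
    if var <= 0:
        raise ValueError("variance of the contrast is zero")
    t = float(c @ fit.params.to_numpy()) / np.sqrt(var)
    N = n_clusters if n_clusters is not None else fit.n_clusters

    if df_method == "asymptotic_z":
        return TestResult(statistic=t, df=None, p_value=2 * stats.norm.sf(abs(t)),
                          reject_at_005=False, method="asymptotic_z")
    if df_method == "satterthwaite":
        df = fit.satterthwaite_df(contrast)
    elif df_method == "residual_cluster":
        df = residual_cluster_df(N, fit.model.cells.between)
    else:  # between_within
        df = between_within_df(fit, contrast)
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult(statistic=t, df=float(df), p_value=p,
                      reject_at_005=False, method=df_method)


def lrt_global(fit_full, fit_null) -> TestResult:
    """Likelihood-ratio chi-square test of all interaction terms.

    Both fits must be maximum likelihood; the null model is the same model
    with the treatment-by-subgroup columns removed.
    """
    for f in (fit_full, fit_null):
        if isinstance(f, LMMResults) and f.method != "ML":
            raise ValueError("the LRT requires ML (not REML) fits")
    inter_full = fit_full.interaction_labels()
    inter_null = fit_null.interaction_labels()
    df = len(inter_full) - len(inter_null)
    if df <= 0:
        raise ValueError("the null model does not nest the full model's interactions")
    stat = 2.0 * (fit_full.llf - fit_null.llf)
    if stat < -1e-4:
        raise ValueError(f"negative LRT statistic ({stat:.3g}): refit the models")
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    return TestResult(statistic=stat, df=float(df), p_value=p,
                      reject_at_005=False, method="lrt")


# ---------------------------------------------------------------------------
# Parametric bootstrap
# ---------------------------------------------------------------------------

def _refit_like(fit, frame):
    if isinstance(fit, LMMResults):
        model = LinearMixedModel(frame,
                                 re_structure=fit.model.structure.cells_key,
                                 include_interaction="trt:gr[1]" in fit.labels)
        return model.fit(method=fit.method)
    model = MixedGLM(frame, fit.model.family,
                     re_structure=fit.model.structure.cells_key,
                     include_interaction="trt:gr[1]" in fit.labels)
    return model.fit()


def _re_cov_root(fit) -> np.ndarray:
    cov = fit.re_cov
    vals, vecs = np.linalg.eigh(cov)
    return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T


def simulate_from_fit(fit, rng) -> "pd.DataFrame":
    """Simulate one dataset from a fitted mixed model, keeping the design."""
    frame = fit.model.frame.copy()
    include = "trt:gr[1]" in fit.labels
    X, _ = build_design(frame, include_interaction=include)
    gr = frame["gr"].to_numpy(dtype=np.int64)
    cl_ids, cl = np.unique(frame["cluster_id"].to_numpy(), return_inverse=True)
    q = fit.re_cov.shape[0]
    if q == 1:
        Z = np.ones((len(frame), 1))
    else:
        Z = np.column_stack([np.ones(len(frame))]
                            + [(gr == k).astype(float) for k in range(1, q)])
    root = _re_cov_root(fit)
    u = rng.standard_normal(size=(len(cl_ids), q)) @ root.T
    eta = X @ fit.params.to_numpy() + np.einsum("cq,cq->c", Z, u[cl])
    family = fit.model.family if isinstance(fit, GLMMResults) else None
    if family is None:
        from .families import get_family
        family = get_family("gaussian")
    y = family.simulate(rng, eta, scale=fit.scale)
    frame["y"] = y
    return frame


def parametric_bootstrap_test(fit, B: int = 100, level: float = 0.95,
                              seed=None, contrast=None,
                              max_failure_rate: float = 0.2) -> TestResult:
    """Percentile bootstrap CI for an interaction coefficient.

    Simulates ``B`` datasets from the fitted model (same design, estimated
    fixed effects and random-effect covariance), refits the same model on
    each, and takes the percentile interval of the targeted coefficient.
    Failed refits are dropped and counted; the decision rejects when 0 is
    outside the interval.
    """
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit")
    if contrast is None:
        contrast = fit.interaction_labels()[0]
    j = _single_coefficient(fit, contrast)
    label = fit.labels[j]
    rng = np.random.default_rng(seed)
    draws, failures = [], 0
    for _ in range(B):
        frame = simulate_from_fit(fit, rng)
        try:
            refit = _refit_like(fit, frame)
        except Exception:
            failures += 1
            continue
        if not refit.converged:
            failures += 1
            continue
        draws.append(float(refit.params[label]))
    if failures > max_failure_rate * B:
        raise RuntimeError(f"{failures}/{B} bootstrap refits failed; the "
                           "interval is unreliable")
    alpha = 1.0 - level
    lo, hi = np.percentile(draws, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return TestResult(statistic=float(fit.params[label]), df=None, p_value=None,
                      reject_at_005=False, ci=(float(lo), float(hi)),
                      method="bootstrap",
                      extras={"B": B, "failures": failures, "level": level})


# ---------------------------------------------------------------------------
# Two-step singular-fit procedure and correction selection
# ---------------------------------------------------------------------------

def _fit_mixed(data, family, structure):
    from .families import get_family
    if get_family(family).name == "gaussian":
        return LinearMixedModel(data, re_structure=structure).fit(method="REML")
    return MixedGLM(data, family, re_structure=structure).fit()


def apply_test(fit, contrast, df_method: str, seed=None, B: int = 100) -> TestResult:
    """Dispatch a test result for any df method, including the bootstrap."""
    if df_method == "bootstrap":
        return parametric_bootstrap_test(fit, B=B, seed=seed, contrast=contrast)
    return wald_t_test(fit, contrast, df_method=df_method)


def two_step_test(data, family, df_method_primary: str = "residual_cluster",
                  df_method_fallback: str = "residual_cluster",
                  singular_tol: float = 1e-4, contrast=None, seed=None,
                  B: int = 100):
    """Fit the maximal model; after a singular fit, fall back to the
    common-intercept model for inference.

    Returns ``(TestResult, primary_fit, fallback_fit_or_None)``; the test
    carries ``used_fallback``.
    """
    from .glmm import is_singular
    primary_exc = None
    fit2 = None
    try:
        fit2 = _fit_mixed(data, family, "maximal")
    except Exception as exc:  # noqa: BLE001 - diagnostics carried forward
        primary_exc = exc
    if fit2 is not None and not is_singular(fit2, tol=singular_tol):
        if contrast is None:
            contrast = fit2.interaction_labels()[0]
        result = apply_test(fit2, contrast, df_method_primary, seed=seed, B=B)
        result.used_fallback = False
        return result, fit2, None
    try:
        fit1 = _fit_mixed(data, family, "intercept")
    except Exception as exc:
        raise RuntimeError(
            f"both steps failed: maximal fit {primary_exc!r}, "
            f"intercept fit {exc!r}") from exc
    if contrast is None:
        contrast = fit1.interaction_labels()[0]
    result = apply_test(fit1, contrast, df_method_fallback, seed=seed, B=B)
    result.used_fallback = True
    return result, fit2, fit1


_CORRECTIONS = {
    # (true, fitted, family) -> df method, for few-cluster Wald t-tests
    ("glmm2", "glmm2", "gaussian"): "satterthwaite",
    ("glmm2", "glmm2", "poisson"): "between_within",
    ("glmm2", "glmm2", "bernoulli"): "residual_cluster",
    ("glmm2", "glmm", "gaussian"): "satterthwaite",
    ("glmm2", "glmm", "poisson"): "residual_cluster",
    ("glmm2", "glmm", "bernoulli"): "residual_cluster",
    ("glmm", "glmm2", "gaussian"): "satterthwaite",
    ("glmm", "glmm2", "poisson"): "bootstrap",
    ("glmm", "glmm2", "bernoulli"): "bootstrap",
    ("glmm", "glmm", "gaussian"): "satterthwaite",
    ("glmm", "glmm", "poisson"): "between_within",
    ("glmm", "glmm", "bernoulli"): "between_within",
}


def select_correction(true_model: str, fitted_model: str, family) -> str:
    """Small-sample correction selected for each (true, fitted, outcome) cell.

    GEE fits always use the Fay-Graubard correction; Gaussian mixed fits use
    Satterthwaite df; count/binary mixed fits use the method that maintained
    the nominal level for that model pairing.
    """
    from .families import get_family
    fam = get_family(family).name
    if fitted_model == "gee":
        return "fay_graubard"
    if true_model not in ("glmm", "glmm2") or fitted_model not in ("glmm", "glmm2"):
        raise ValueError(f"unknown model pairing: {(true_model, fitted_model)!r}")
    return _CORRECTIONS[(true_model, fitted_model, fam)]
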