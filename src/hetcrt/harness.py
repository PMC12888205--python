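"""Monte-Carlo harness: scenario x model x correction grids.

Each replicate simulates one trial, fits the requested models (GEE, the
common-intercept GLMM, the maximal GLMM "glmm2", and the two-step
singular-fit procedure) and applies the scenario's designated HTE test:
Wald t with the selected small-sample correction when the design has 12
clusters, z/F tests for GEE depending on the number of clusters, and the
global LRT when the subgroup has three levels.  Per-model performance is
summarized by bias and empirical SD of the interaction estimate, the
rejection rate at the nominal 0.05 level (with its Monte-Carlo standard
error), and singular-fit/failure counts.

Replicate seeds are spawned from the master seed by replicate index, so any
subset of replicates is reproducible independently and results do not depend
on the degree of parallelism.
"""

from __future__ import annotations

import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .gee import ClusterGEE
from .glmm import MixedGLM, is_singular
from .inference import (TestResult, apply_test, lrt_global, select_correction)
from .lmm import LinearMixedModel
from .scenarios import ScenarioSpec
from .simulate import simulate_trial

__all__ = ["ModelRep", "RepResult", "run_replicate", "run_scenario",
           "write_table", "MODEL_NAMES"]

MODEL_NAMES = ("gee", "glmm", "glmm2", "two_step")


@dataclass
class ModelRep:
    """One model's record within a replicate."""

    model: str
    est: Optional[np.ndarray] = None      # interaction coefficient estimate(s)
    test: Optional[TestResult] = None
    singular: bool = False
    used_fallback: bool = False
    converged: bool = False
    error: Optional[str] = None
    seconds: float = 0.0

    @property
    def usable(self) -> bool:
        return self.test is not None


@dataclass
class RepResult:
    """All requested models applied to one simulated trial."""

    replicate: int
    seed_entropy: int
    entries: dict = field(default_factory=dict)


def _interaction_estimates(fit) -> np.ndarray:
    labels = fit.interaction_labels()
    return fit.params[labels].to_numpy()


def _fit_mixed(data, family, structure, method_ml=False):
    if family == "gaussian":
        method = "ML" if method_ml else "REML"
        return LinearMixedModel(data, re_structure=structure).fit(method=method)
    return MixedGLM(data, family, re_structure=structure).fit()


def _lrt_for(data, family, structure) -> tuple:
    """Global LRT: full vs interaction-free fit of the same structure."""
    if family == "gaussian":
        full = LinearMixedModel(data, re_structure=structure).fit(method="ML")
        null = LinearMixedModel(data, re_structure=structure,
                                include_interaction=False).fit(method="ML")
    else:
        full = MixedGLM(data, family, re_structure=structure).fit()
        null = MixedGLM(data, family, re_structure=structure,
                        include_interaction=False).fit()
    return lrt_global(full, null), full


def _small_sample(spec: ScenarioSpec) -> bool:
    return spec.n_clusters < 50


def _mixed_df_method(spec: ScenarioSpec, fitted_model: str) -> str:
    # Gaussian mixed-model t-tests use Satterthwaite df at any cluster count
    # (the default of the reference t-test implementation); this is also the
    # selected few-cluster correction for continuous outcomes
    if spec.family == "gaussian":
        return "satterthwaite"
    if _small_sample(spec):
        return select_correction(spec.true_model, fitted_model, spec.family)
    # moderate-to-large clusters: plain Wald t with N - q df (converges to z)
    return "residual_cluster"


def _run_mixed(rep: ModelRep, data, spec: ScenarioSpec, fitted_model: str,
               boot_seed):
    structure = "intercept" if fitted_model == "glmm" else "maximal"
    if spec.n_levels > 2:
        test, fit = _lrt_for(data, spec.family, structure)
        rep.singular = is_singular(fit)
        rep.converged = fit.converged
        rep.est = _interaction_estimates(fit)
        rep.test = test
        return
    fit = _fit_mixed(data, spec.family, structure)
    rep.singular = is_singular(fit)
    rep.converged = fit.converged
    rep.est = _interaction_estimates(fit)
    contrast = fit.interaction_labels()[0]
    dfm = _mixed_df_method(spec, fitted_model)
    try:
        rep.test = apply_test(fit, contrast, dfm, seed=boot_seed)
    except Exception as exc:  # noqa: BLE001
        if dfm == "satterthwaite":
            # boundary fits can defeat the Satterthwaite information matrix
            rep.test = apply_test(fit, contrast, "residual_cluster")
            rep.test.extras["satterthwaite_fallback"] = str(exc)
        else:
            raise


def _run_two_step(rep: ModelRep, data, spec: ScenarioSpec, boot_seed):
    structure_df = _mixed_df_method(spec, "glmm2")
    fallback_df = _mixed_df_method(spec, "glmm")
    if spec.n_levels > 2:
        fit2 = _fit_mixed(data, spec.family, "maximal", method_ml=True)
        rep.singular = is_singular(fit2)
        chosen = "maximal" if not rep.singular else "intercept"
        test, fit = _lrt_for(data, spec.family, chosen)
        test.used_fallback = rep.singular
        rep.converged = fit.converged
        rep.est = _interaction_estimates(fit)
        rep.test = test
        return
    fit2 = _fit_mixed(data, spec.family, "maximal")
    rep.singular = is_singular(fit2)
    fit = fit2 if not rep.singular else _fit_mixed(data, spec.family, "intercept")
    dfm = structure_df if not rep.singular else fallback_df
    rep.converged = fit.converged
    rep.est = _interaction_estimates(fit)
    contrast = fit.interaction_labels()[0]
    try:
        test = apply_test(fit, contrast, dfm, seed=boot_seed)
    except Exception as exc:  # noqa: BLE001
        if dfm == "satterthwaite":
            test = apply_test(fit, contrast, "residual_cluster")
            test.extras["satterthwaite_fallback"] = str(exc)
        else:
            raise
    test.used_fallback = rep.singular
    rep.used_fallback = rep.singular
    rep.test = test


def run_replicate(spec: ScenarioSpec, models, seed, B: int = 100) -> RepResult:
    """Simulate one trial and apply every requested model and its test."""
    for m in models:
        if m not in MODEL_NAMES:
            raise ValueError(f"unknown model {m!r}; choose from {MODEL_NAMES}")
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    ss_data, ss_boot = ss.spawn(2)
    data = simulate_trial(spec, ss_data)
    entropy = ss.entropy if isinstance(ss.entropy, int) else 0
    out = RepResult(replicate=-1, seed_entropy=entropy)
    boot_seeds = ss_boot.spawn(len(models))
    for m, bs in zip(models, boot_seeds):
        rep = ModelRep(model=m)
        t0 = time.perf_counter()
        try:
            if m == "gee":
                if spec.n_levels > 2:
                    raise ValueError("GEE is not run for global (three-level) "
                                     "LRT designs")
                fit = ClusterGEE(data, spec.family).fit()
                rep.converged = fit.converged
                rep.est = _interaction_estimates(fit)
                contrast = fit.interaction_labels()[0]
                rep.test = (fit.fay_graubard_f_test(contrast)
                            if _small_sample(spec) else fit.z_test(contrast))
            elif m in ("glmm", "glmm2"):
                _run_mixed(rep, data, spec, m, bs)
            else:
                _run_two_step(rep, data, spec, bs)
        except Exception as exc:  # noqa: BLE001 - recorded, never dropped silently
            rep.error = f"{type(exc).__name__}: {exc}"
        rep.seconds = time.perf_counter() - t0
        out.entries[m] = rep
    return out


def _one_rep(args):
    spec, models, master_seed, r, B = args
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(r,))
    rep = run_replicate(spec, models, ss, B=B)
    rep.replicate = r
    return rep


def run_scenario(spec: ScenarioSpec, models, n_reps: int, master_seed: int,
                 n_workers: int = 1, B: int = 100):
    """Run a replicate grid and summarize per-model performance.

    Returns ``(metrics, reps)``: a DataFrame with one row per model (bias,
    empirical SD, rejection rate with Monte-Carlo SE, singular and failure
    counts) and the per-replicate log.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    jobs = [(spec, tuple(models), master_seed, r, B) for r in range(n_reps)]
    if n_workers > 1:
        with ProcessPoolExecutor(max_workers=n_workers) as pool:
            reps = list(pool.map(_one_rep, jobs, chunksize=max(1, n_reps // (4 * n_workers))))
    else:
        reps = [_one_rep(j) for j in jobs]
    reps.sort(key=lambda rr: rr.replicate)

    true_mod = np.asarray(spec.fixed.beta_mod)
    rows = []
    for m in models:
        entries = [rr.entries[m] for rr in reps]
        ests = np.array([e.est[0] for e in entries if e.est is not None])
        rejs = np.array([e.test.reject_at_005 for e in entries if e.usable])
        n_failed = sum(1 for e in entries if e.error is not None)
        rate = float(np.mean(rejs)) if rejs.size else np.nan
        rows.append({
            "scenario": spec.scenario_id, "family": spec.family,
            "model": m, "n_clusters": spec.n_clusters,
            "size_mode": "fixed" if np.isscalar(spec.cluster_sizes) else "varying",
            "bias": float(np.mean(ests) - true_mod[0]) if ests.size else np.nan,
            "esd": float(np.std(ests, ddof=1)) if ests.size > 1 else np.nan,
            "rejection_rate": rate,
            "mc_se": float(np.sqrt(rate * (1 - rate) / rejs.size)) if rejs.size else np.nan,
            "n_singular": int(sum(e.singular for e in entries)),
            "n_fallback": int(sum(e.used_fallback for e in entries)),
            "n_failed": int(n_failed),
            "n_usable": int(rejs.size),
            "n_reps": n_reps,
        })
    return pd.DataFrame(rows), reps


def write_table(metrics: pd.DataFrame, path, format: str = "csv"):
    """Write a metrics table with bit-stable row ordering."""
    if len(metrics) == 0:
        raise ValueError("empty metrics table")
    metrics = metrics.sort_values(
        ["scenario", "family", "n_clusters", "size_mode", "model"],
        kind="mergesort").reset_index(drop=True)
    if format == "csv":
        metrics.to_csv(path, index=False)
    elif format == "markdown":
        cols = list(metrics.columns)
        lines = ["| " + " | ".join(cols) + " |",
                 "|" + "|".join("---" for _ in cols) + "|"]
        for _, row in metrics.iterrows():
            cells = [f"{v:.4g}" if isinstance(v, float) else str(v) for v in row]
            lines.append("| " + " | ".join(cells) + " |")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError("format must be 'csv' or 'markdown'")
    return path
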