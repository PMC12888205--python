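"""Design construction and sufficient-statistic collapse.

The fixed-effect design is (intercept, trt, gr dummies, trt x gr dummies);
the per-cluster random-effect design is a column of ones (common intercept)
or ones plus the subgroup dummies (random intercept + subgroup slopes, the
reparametrization of subgroup-specific random intercepts).

Because every covariate is constant within a (cluster, subgroup) cell, all
likelihoods depend on the data only through per-cell sizes, outcome sums and
sums of squares; :func:`collapse_cells` computes these once per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .families import Family, get_family

__all__ = ["Cells", "build_design", "collapse_cells", "fixed_effect_labels"]


def fixed_effect_labels(p: int, include_interaction: bool = True) -> list:
    labels = ["Intercept", "trt"]
    labels += [f"gr[{k}]" for k in range(1, p)]
    if include_interaction:
        labels += [f"trt:gr[{k}]" for k in range(1, p)]
    return labels


def _validate(frame: pd.DataFrame):
    for col in ("cluster_id", "trt", "gr", "y"):
        if col not in frame.columns:
            raise ValueError(f"trial data must contain a {col!r} column")
    trt_levels = frame.groupby("cluster_id")["trt"].nunique()
    if (trt_levels > 1).any():
        bad = trt_levels[trt_levels > 1].index.tolist()
        raise ValueError(f"treatment varies within cluster(s) {bad}: not a "
                         "cluster-randomized design")
    gr = frame["gr"].to_numpy()
    levels = np.unique(gr)
    if levels.min() != 0 or not np.array_equal(levels, np.arange(len(levels))):
        raise ValueError("subgroup levels must be a contiguous integer set containing 0")


@dataclass
class Cells:
    """(cluster, subgroup)-cell sufficient statistics for one dataset."""

    cluster: np.ndarray          # (ncells,) dense cluster index 0..N-1
    subgroup: np.ndarray         # (ncells,) subgroup level
    X: np.ndarray                # (ncells, k) fixed-effect design rows
    Z: np.ndarray                # (ncells, q) random-effect design rows
    m: np.ndarray                # (ncells,) cell sizes
    S: np.ndarray                # (ncells,) cell outcome sums
    SS: np.ndarray               # (ncells,) cell outcome sums of squares
    labels: list                 # fixed-effect column labels
    between: np.ndarray          # (k,) True for columns constant within every cluster
    n_clusters: int
    nobs: int
    n_levels: int
    structure: str               # "intercept" or "maximal"
    cluster_ids: np.ndarray      # original cluster labels in dense order
    cluster_trt: np.ndarray      # (N,) arm per cluster
    loglik_const: float = 0.0    # parameter-free additive log-likelihood term
    separated: bool = False      # binary outcomes: a fixed-design cell all 0 or all 1

    @property
    def k_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def q_re(self) -> int:
        return self.Z.shape[1]

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.cluster, weights=self.m, minlength=self.n_clusters)


def build_design(frame: pd.DataFrame, include_interaction: bool = True):
    """Fixed-effect design matrix and labels for long-format trial data.

    Returns ``(X, labels)`` with columns ordered (intercept, trt,
    gr[1..p-1], trt:gr[1..p-1]).
    """
    _validate(frame)
    trt = frame["trt"].to_numpy(dtype=float)
    gr = frame["gr"].to_numpy(dtype=np.int64)
    p = int(gr.max()) + 1
    cols = [np.ones(len(frame)), trt]
    for k in range(1, p):
        cols.append((gr == k).astype(float))
    if include_interaction:
        for k in range(1, p):
            cols.append(trt * (gr == k))
    return np.column_stack(cols), fixed_effect_labels(p, include_interaction)


def _design_rows(trt, gr, p, include_interaction):
    row = [1.0, trt] + [float(gr == k) for k in range(1, p)]
    if include_interaction:
        row += [trt * float(gr == k) for k in range(1, p)]
    return row


def collapse_cells(frame: pd.DataFrame, family=None, structure: str = "maximal",
                   include_interaction: bool = True) -> Cells:
    """Collapse long-format data to per-(cluster, subgroup) cells."""
    _validate(frame)
    if structure not in ("intercept", "maximal"):
        raise ValueError("structure must be 'intercept' or 'maximal'")
    fam: Optional[Family] = None if family is None else get_family(family)

    cl_raw = frame["cluster_id"].to_numpy()
    cluster_ids, cl = np.unique(cl_raw, return_inverse=True)
    n_clusters = len(cluster_ids)
    gr = frame["gr"].to_numpy(dtype=np.int64)
    p = int(gr.max()) + 1
    y = frame["y"].to_numpy(dtype=float)
    trt_obs = frame["trt"].to_numpy(dtype=np.int64)
    if fam is not None:
        fam.validate_outcome(y)

    cell_key = cl * p + gr
    keys, inv = np.unique(cell_key, return_inverse=True)
    ncells = len(keys)
    m = np.bincount(inv, minlength=ncells).astype(float)
    S = np.bincount(inv, weights=y, minlength=ncells)
    SS = np.bincount(inv, weights=y * y, minlength=ncells)
    cell_cluster = keys // p
    cell_gr = keys % p

    cluster_trt = np.zeros(n_clusters, dtype=np.int64)
    cluster_trt[cl] = trt_obs
    cell_trt = cluster_trt[cell_cluster]

    X = np.array([_design_rows(float(t), int(g), p, include_interaction)
                  for t, g in zip(cell_trt, cell_gr)])
    if structure == "intercept":
        Z = np.ones((ncells, 1))
    else:
        Z = np.column_stack([np.ones(ncells)]
                            + [(cell_gr == k).astype(float) for k in range(1, p)])

    labels = fixed_effect_labels(p, include_interaction)
    # between/within classification: a column is "between" when it is constant
    # within every cluster
    between = np.array([
        all(np.ptp(X[cell_cluster == i, j]) == 0.0 for i in range(n_clusters))
        for j in range(X.shape[1])
    ])

    const = 0.0 if fam is None else fam.loglik_constant(y)
    separated = False
    if fam is not None and fam.name == "bernoulli":
        # aggregate over the distinct fixed-design rows (trt x gr crossings)
        agg = {}
        for j in range(ncells):
            key = (int(cell_trt[j]),) + tuple(int(v) for v in (cell_gr[j],))
            mm, ss = agg.get(key, (0.0, 0.0))
            agg[key] = (mm + m[j], ss + S[j])
        separated = any(s == 0.0 or s == mm for mm, s in agg.values())

    return Cells(cluster=cell_cluster, subgroup=cell_gr, X=X, Z=Z, m=m, S=S, SS=SS,
                 labels=labels, between=between, n_clusters=n_clusters,
                 nobs=len(frame), n_levels=p, structure=structure,
                 cluster_ids=cluster_ids, cluster_trt=cluster_trt,
                 loglik_const=const, separated=separated)
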