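"""Simulation of two-arm cluster-randomized trials.

One master seed drives five independent substreams (cluster randomization,
cluster sizes, subgroup labels, latent random effects, outcomes), so changing
one component of the generator does not perturb the draws of the others.
Identical ``(spec, seed)`` always yield bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .families import get_family
from .scenarios import ScenarioSpec

__all__ = [
    "TrialData", "randomize_clusters", "assign_cluster_sizes",
    "draw_random_effects", "simulate_trial",
]

_COLUMNS = ["cluster_id", "trt", "gr", "y"]


@dataclass
class TrialData:
    """Long-format CRT data: one row per participant.

    ``frame`` has columns ``cluster_id`` (integer), ``trt`` (0/1, constant
    within cluster), ``gr`` (subgroup level, 0 = reference) and ``y``.
    ``latent_u`` optionally records the drawn per-cluster random effects
    (n_clusters x p, one column per subgroup level) for testing.
    """

    frame: pd.DataFrame
    latent_u: Optional[np.ndarray] = None
    spec: Optional[ScenarioSpec] = None

    @property
    def n_clusters(self) -> int:
        return self.frame["cluster_id"].nunique()

    @property
    def nobs(self) -> int:
        return len(self.frame)

    @property
    def n_levels(self) -> int:
        return int(self.frame["gr"].max()) + 1

    def to_csv(self, path):
        self.frame.to_csv(path, index=False, columns=_COLUMNS)

    @classmethod
    def from_csv(cls, path) -> "TrialData":
        frame = pd.read_csv(path)
        missing = set(_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"trial data file is missing columns: {sorted(missing)}")
        return cls(frame=frame[_COLUMNS])


def _rng_from(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def randomize_clusters(n_clusters: int, seed) -> np.ndarray:
    """1:1 randomization of clusters to arms; returns a 0/1 vector.

    Exactly half the clusters are assigned to the intervention arm (coded 1).
    """
    if n_clusters % 2 != 0:
        raise ValueError("1:1 randomization requires an even number of clusters")
    rng = _rng_from(seed)
    arms = np.zeros(n_clusters, dtype=np.int64)
    arms[rng.permutation(n_clusters)[: n_clusters // 2]] = 1
    return arms


def assign_cluster_sizes(spec: ScenarioSpec, seed=None) -> np.ndarray:
    """Cluster sizes in cluster-id order.

    Fixed mode returns a constant vector.  A size list is cycled over clusters
    ordered by id, which balances sizes across arms in expectation under the
    randomization; the realized sizes are recorded in the output data.
    """
    if np.isscalar(spec.cluster_sizes):
        sizes = np.full(spec.n_clusters, int(spec.cluster_sizes), dtype=np.int64)
    else:
        pool = np.asarray(spec.cluster_sizes, dtype=np.int64)
        reps = int(np.ceil(spec.n_clusters / len(pool)))
        sizes = np.tile(pool, reps)[: spec.n_clusters]
    if sizes.min() <= 0:
        raise ValueError("cluster sizes must be positive")
    return sizes


def draw_random_effects(spec: ScenarioSpec, arms: np.ndarray, seed) -> np.ndarray:
    """Latent per-cluster random effects, one row per cluster.

    Returns an (n_clusters x p) matrix whose k-th column applies to subgroup
    k.  Under a common intercept all columns are identical.  With
    arm-heterogeneous covariance the row for cluster i is drawn from
    MVN(0, arm_scale[arm_i] * Sigma).
    """
    rng = _rng_from(seed)
    p = spec.n_levels
    n = spec.n_clusters
    if spec.ranef.structure == "common_intercept":
        u = rng.normal(0.0, np.sqrt(spec.ranef.sigma2), size=n)
        return np.repeat(u[:, None], p, axis=1)
    out = np.empty((n, p))
    z = rng.standard_normal(size=(n, p))
    # per-arm Cholesky factors so each cluster uses its arm's covariance
    for arm in (0, 1):
        cov = spec.ranef.covariance(p, arm=arm)
        w = np.linalg.eigvalsh(cov)
        if w.min() < -1e-10:
            raise ValueError("random-effect covariance is not positive semi-definite")
        # PSD square root via eigendecomposition (supports boundary covariances)
        vals, vecs = np.linalg.eigh(cov)
        root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T
        mask = arms == arm
        out[mask] = z[mask] @ root.T
    return out


def simulate_trial(spec: ScenarioSpec, seed) -> TrialData:
    """Simulate one complete trial from a scenario configuration.

    The linear predictor for participant j of cluster i in subgroup k is

        eta_ij = b0 + trt_i*b_trt + b_gr[k] + trt_i*b_mod[k] + U_{i,k}

    (with b_gr[0] = b_mod[0] = 0 for the reference level), and outcomes are
    drawn conditionally independently given the latent effects.
    """
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    s_rand, s_size, s_gr, s_u, s_y = [np.random.default_rng(c) for c in ss.spawn(5)]

    arms = randomize_clusters(spec.n_clusters, s_rand)
    sizes = assign_cluster_sizes(spec, s_size)
    u = draw_random_effects(spec, arms, s_u)

    p = spec.n_levels
    cluster_id = np.repeat(np.arange(spec.n_clusters), sizes)
    trt = arms[cluster_id]
    gr = s_gr.choice(p, size=sizes.sum(), p=np.asarray(spec.subgroup_probs))

    beta_gr = np.concatenate([[0.0], spec.fixed.beta_gr])
    beta_mod = np.concatenate([[0.0], spec.fixed.beta_mod])
    eta = (spec.fixed.beta0 + trt * spec.fixed.beta_trt
           + beta_gr[gr] + trt * beta_mod[gr] + u[cluster_id, gr])

    fam = get_family(spec.family)
    scale = None if spec.family_spec.residual_sd is None else spec.family_spec.residual_sd ** 2
    y = fam.simulate(s_y, eta, scale=scale)

    frame = pd.DataFrame({
        "cluster_id": cluster_id.astype(np.int64),
        "trt": trt.astype(np.int64),
        "gr": gr.astype(np.int64),
        "y": y,
    })
    return TrialData(frame=frame, latent_u=u, spec=spec)
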