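"""Data-generating scenario configurations for two-arm CRT simulations.

A :class:`ScenarioSpec` fully describes one data-generating process: outcome
family and link, fixed-effect coefficients of the treatment-by-subgroup model

    g(E[Y_ij | U_i]) = b0 + trt_i*b_trt + gr_ij'b_gr + (trt_i x gr_ij)'b_mod + RE,

the random-effect structure (a common cluster intercept U_i ~ N(0, sigma2), or
a subgroup-specific vector U_i ~ MVN(0, Sigma) so that within-cluster
correlation differs across subgroups), the number of clusters and their sizes,
and the subgroup mixing probabilities.

Seven numbered presets cover the simulation study conditions this package is
built to reproduce: moderate subgroup-specific random effects with many
clusters (1), the same downscaled by 1/10 (2), few clusters (3), a
common-intercept truth so the maximal model is overfitted (4), a three-level
subgroup (5), arm-heterogeneous random-effect covariance (6), and a non-null
interaction for power comparison (7).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .families import FAMILY_ALIASES, get_family

__all__ = [
    "FamilySpec", "FixedEffects", "RandomEffectSpec", "ScenarioSpec",
    "make_scenario", "SCENARIO_LAYOUTS", "VARYING_SIZES",
]

#: cluster-size list used by the varying-size designs
VARYING_SIZES = (25, 50, 100, 150, 300)

#: residual variance for continuous outcomes in all presets
GAUSSIAN_RESIDUAL_VAR = 0.64


class ConfigurationError(ValueError):
    """A scenario configuration that names no valid preset cell."""


@dataclass
class FamilySpec:
    """Outcome family, canonical link, and Gaussian residual SD."""

    family: str
    residual_sd: Optional[float] = None

    def __post_init__(self):
        key = FAMILY_ALIASES.get(str(self.family).lower())
        if key is None:
            raise ConfigurationError(f"unknown family: {self.family!r}")
        self.family = key
        if key == "gaussian":
            if self.residual_sd is None:
                raise ConfigurationError("gaussian family requires residual_sd")
            self.residual_sd = float(self.residual_sd)
            if self.residual_sd < 0:
                raise ConfigurationError("residual_sd must be nonnegative")
        elif self.residual_sd is not None:
            raise ConfigurationError("residual_sd is only meaningful for gaussian outcomes")

    @property
    def link(self) -> str:
        return get_family(self.family).link


@dataclass
class FixedEffects:
    """Coefficients (b0, b_trt, b_gr[1..p-1], b_mod[1..p-1])."""

    beta0: float
    beta_trt: float
    beta_gr: tuple
    beta_mod: tuple

    def __post_init__(self):
        self.beta_gr = tuple(float(b) for b in np.atleast_1d(self.beta_gr))
        self.beta_mod = tuple(float(b) for b in np.atleast_1d(self.beta_mod))
        if len(self.beta_gr) != len(self.beta_mod):
            raise ConfigurationError("beta_gr and beta_mod must have equal length (p-1)")

    @property
    def n_levels(self) -> int:
        return len(self.beta_gr) + 1

    def as_vector(self) -> np.ndarray:
        """Coefficients in design-column order (intercept, trt, gr, trt:gr)."""
        return np.array([self.beta0, self.beta_trt, *self.beta_gr, *self.beta_mod])


@dataclass
class RandomEffectSpec:
    """Cluster random-effect law.

    ``common_intercept``: scalar U_i ~ N(0, sigma2) shared by every subgroup.
    ``subgroup_specific``: vector U_i ~ MVN(0, Sigma) (p x p), participant in
    subgroup k receives component U_{i,k}; ``arm_scale`` multiplies Sigma by a
    per-arm constant (control, intervention scaling), used by designs with
    arm-heterogeneous covariance.
    """

    structure: str
    sigma2: Optional[float] = None
    Sigma: Optional[np.ndarray] = None
    arm_scale: tuple = (1.0, 1.0)

    def __post_init__(self):
        if self.structure not in ("common_intercept", "subgroup_specific"):
            raise ConfigurationError(f"unknown random-effect structure: {self.structure!r}")
        if self.structure == "common_intercept":
            if self.sigma2 is None or self.sigma2 < 0:
                raise ConfigurationError("common_intercept requires sigma2 >= 0")
            self.sigma2 = float(self.sigma2)
        else:
            if self.Sigma is None:
                raise ConfigurationError("subgroup_specific requires Sigma")
            self.Sigma = np.asarray(self.Sigma, dtype=float)
            if self.Sigma.ndim != 2 or self.Sigma.shape[0] != self.Sigma.shape[1]:
                raise ConfigurationError("Sigma must be square")
            if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-10):
                raise ConfigurationError("Sigma must be symmetric")
            if np.linalg.eigvalsh(self.Sigma).min() < -1e-10:
                raise ConfigurationError("Sigma must be positive semi-definite")
        self.arm_scale = (float(self.arm_scale[0]), float(self.arm_scale[1]))
        if min(self.arm_scale) <= 0:
            raise ConfigurationError("arm_scale entries must be positive")

    def covariance(self, p: int, arm: int = 0) -> np.ndarray:
        """Effective p x p covariance of the subgroup-specific latent vector.

        The common intercept is the special case Sigma = sigma2 * J.
        """
        if self.structure == "common_intercept":
            return self.sigma2 * np.ones((p, p))
        if self.Sigma.shape[0] != p:
            raise ConfigurationError(f"Sigma is {self.Sigma.shape[0]}x{self.Sigma.shape[0]}, "
                                     f"but the design has p={p} subgroup levels")
        return self.arm_scale[arm] * self.Sigma


@dataclass
class ScenarioSpec:
    """A complete data-generating configuration for one simulated CRT."""

    scenario_id: Union[int, str]
    family_spec: FamilySpec
    fixed: FixedEffects
    ranef: RandomEffectSpec
    n_clusters: int
    cluster_sizes: Union[int, Sequence[int]]
    subgroup_probs: tuple = (0.5, 0.5)

    def __post_init__(self):
        if self.n_clusters <= 0:
            raise ConfigurationError("n_clusters must be positive")
        if self.n_clusters % 2 != 0:
            raise ConfigurationError("n_clusters must be even for 1:1 cluster randomization")
        probs = np.asarray(self.subgroup_probs, dtype=float)
        if probs.min() <= 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("subgroup_probs must be positive and sum to 1")
        self.subgroup_probs = tuple(float(v) for v in probs)
        if len(self.subgroup_probs) != self.fixed.n_levels:
            raise ConfigurationError("subgroup_probs length must equal the number of "
                                     "subgroup levels implied by the fixed effects")
        if not np.isscalar(self.cluster_sizes):
            self.cluster_sizes = tuple(int(s) for s in self.cluster_sizes)
            if min(self.cluster_sizes) <= 0:
                raise ConfigurationError("cluster sizes must be positive")
        elif int(self.cluster_sizes) <= 0:
            raise ConfigurationError("cluster sizes must be positive")
        else:
            self.cluster_sizes = int(self.cluster_sizes)

    @property
    def n_levels(self) -> int:
        return self.fixed.n_levels

    @property
    def family(self) -> str:
        return self.family_spec.family

    @property
    def true_model(self) -> str:
        """'glmm' when the truth has a common intercept, else 'glmm2'."""
        return "glmm" if self.ranef.structure == "common_intercept" else "glmm2"

    # -- flat serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        if self.ranef.Sigma is not None:
            d["ranef"]["Sigma"] = [list(map(float, row)) for row in self.ranef.Sigma]
        return d

    def to_yaml(self, path=None):
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = dict(d)
        d["family_spec"] = FamilySpec(**d["family_spec"])
        d["fixed"] = FixedEffects(**d["fixed"])
        d["ranef"] = RandomEffectSpec(**d["ranef"])
        d["subgroup_probs"] = tuple(d.get("subgroup_probs", (0.5, 0.5)))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Preset tables
# ---------------------------------------------------------------------------

_SIGMA_S1 = {
    "gaussian": [[0.2, 0.13], [0.13, 0.1]],
    "poisson": [[0.5, 0.25], [0.25, 0.5]],
    "bernoulli": [[0.25, 0.18], [0.18, 0.5]],
}

# arm-heterogeneous design: binary shares the count matrix (only two matrices
# are defined for three families; count and binary share variances in the
# common-intercept presets, and the same convention is used here)
_SIGMA_S6 = {
    "gaussian": [[0.2, 0.13], [0.13, 0.1]],
    "poisson": [[0.5, 0.25], [0.25, 0.5]],
    "bernoulli": [[0.5, 0.25], [0.25, 0.5]],
}

_SIGMA2_COMMON = {"gaussian": 0.2, "poisson": 0.5, "bernoulli": 0.5}

# null binary-subgroup fixed effects (b0, b_trt, b_gr, b_mod)
_BETA_NULL_P2 = {
    "gaussian": (0.0, 0.5, (0.3,), (0.0,)),
    "poisson": (-1.0, -0.07, (-0.5,), (0.0,)),
    "bernoulli": (-1.66, -0.32, (-0.08,), (0.0,)),
}

# three-level subgroup, null interaction
_BETA_NULL_P3 = {
    "gaussian": (0.0, 0.5, (0.3, 0.15), (0.0, 0.0)),
    "poisson": (-1.0, -0.07, (-0.5, -0.3), (0.0, 0.0)),
    "bernoulli": (-1.66, -0.32, (-0.08, -0.05), (0.0, 0.0)),
}

# non-null interaction for power comparison
_BETA_POWER_P2 = {
    "gaussian": (0.0, 0.5, (0.3,), (0.2,)),
    "poisson": (-1.0, -0.07, (-0.5,), (0.1,)),
    "bernoulli": (-1.66, -0.32, (-0.08,), (0.15,)),
}

#: valid (n_clusters, size_mode) cells per numbered scenario
SCENARIO_LAYOUTS = {
    1: {(50, "fixed"), (100, "fixed")},
    2: {(50, "fixed"), (100, "fixed")},
    3: {(12, "fixed"), (12, "varying")},
    4: {(50, "fixed"), (12, "varying")},
    5: {(50, "fixed"), (12, "varying")},
    6: {(50, "fixed"), (12, "varying")},
    7: {(50, "fixed"), (12, "varying")},
}

_FIXED_SIZE = 100


def make_scenario(scenario_id: int, family, n_clusters: int,
                  size_mode: str = "fixed") -> ScenarioSpec:
    """Build the fully populated preset for one simulation-study cell.

    Parameters
    ----------
    scenario_id : int
        Preset number, 1-7.
    family : str
        ``gaussian``/``continuous``, ``poisson``/``count`` or
        ``bernoulli``/``binary``.
    n_clusters : int
        Number of clusters; must be a combination the preset defines.
    size_mode : {"fixed", "varying"}
        Fixed size 100 per cluster, or sizes cycled from (25,50,100,150,300).
    """
    fam = FAMILY_ALIASES.get(str(family).lower())
    if fam is None:
        raise ConfigurationError(f"unknown family: {family!r}")
    if scenario_id not in SCENARIO_LAYOUTS:
        raise ConfigurationError(f"unknown scenario_id: {scenario_id!r} (expected 1-7)")
    if size_mode not in ("fixed", "varying"):
        raise ConfigurationError(f"size_mode must be 'fixed' or 'varying', got {size_mode!r}")
    if (n_clusters, size_mode) not in SCENARIO_LAYOUTS[scenario_id]:
        raise ConfigurationError(
            f"n_clusters={n_clusters} with size_mode={size_mode!r} is not a design cell "
            f"of scenario {scenario_id}; valid cells: {sorted(SCENARIO_LAYOUTS[scenario_id])}")

    residual_sd = np.sqrt(GAUSSIAN_RESIDUAL_VAR) if fam == "gaussian" else None
    family_spec = FamilySpec(fam, residual_sd)

    if scenario_id == 5:
        fixed = FixedEffects(*_BETA_NULL_P3[fam])
        probs = (1 / 3, 1 / 3, 1 / 3)
    elif scenario_id == 7:
        fixed = FixedEffects(*_BETA_POWER_P2[fam])
        probs = (0.5, 0.5)
    else:
        fixed = FixedEffects(*_BETA_NULL_P2[fam])
        probs = (0.5, 0.5)

    if scenario_id in (1, 3):
        ranef = RandomEffectSpec("subgroup_specific", Sigma=np.array(_SIGMA_S1[fam]))
    elif scenario_id == 2:
        ranef = RandomEffectSpec("subgroup_specific", Sigma=0.1 * np.array(_SIGMA_S1[fam]))
    elif scenario_id == 6:
        # c_t = 1 for the intervention arm, 1.4 for control
        ranef = RandomEffectSpec("subgroup_specific", Sigma=np.array(_SIGMA_S6[fam]),
                                 arm_scale=(1.4, 1.0))
    else:  # 4, 5, 7: common random intercept
        ranef = RandomEffectSpec("common_intercept", sigma2=_SIGMA2_COMMON[fam])

    sizes = _FIXED_SIZE if size_mode == "fixed" else VARYING_SIZES
    return ScenarioSpec(scenario_id=scenario_id, family_spec=family_spec, fixed=fixed,
                        ranef=ranef, n_clusters=n_clusters, cluster_sizes=sizes,
                        subgroup_probs=probs)
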