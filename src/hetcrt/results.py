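"""Shared behaviour for fitted-model results objects."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

__all__ = ["FitResultsMixin"]


class FitResultsMixin:
    """Common surface of LMM / GLMM / GEE results.

    Subclasses set ``params`` (pd.Series labelled by design column),
    ``_cov`` (the inferential covariance of the fixed effects), ``llf``,
    ``converged`` and expose the originating model as ``model``.
    """

    params: pd.Series
    _cov: np.ndarray
    llf: float
    converged: bool

    @property
    def labels(self) -> list:
        return list(self.params.index)

    @property
    def k_fixed(self) -> int:
        return len(self.params)

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self._cov, index=self.labels, columns=self.labels)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self._cov)), index=self.labels)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def contrast_vector(self, name_or_vector) -> np.ndarray:
        """Resolve a coefficient name or explicit vector to a contrast."""
        if isinstance(name_or_vector, str):
            c = np.zeros(self.k_fixed)
            c[self.labels.index(name_or_vector)] = 1.0
            return c
        c = np.asarray(name_or_vector, dtype=float)
        if c.shape != (self.k_fixed,):
            raise ValueError(f"contrast must have length {self.k_fixed}")
        if not c.any():
            raise ValueError("contrast must be nonzero")
        return c

    def interaction_labels(self) -> list:
        return [lab for lab in self.labels if lab.startswith("trt:gr")]

    def _json_payload(self) -> dict:
        return {
            "labels": self.labels,
            "estimates": [float(v) for v in self.params],
            "vcov": [float(v) for v in np.asarray(self._cov).ravel()],
            "loglik": float(self.llf),
            "converged": bool(self.converged),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self._json_payload(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def _summary_rows(self):
        rows = pd.DataFrame({"coef": self.params, "se": self.bse,
                             "t": self.tvalues})
        return rows

    def summary(self) -> str:
        head = [f"{type(self).__name__}",
                f"  log-likelihood: {self.llf:.4f}   converged: {self.converged}"]
        for extra in self._summary_extra():
            head.append("  " + extra)
        body = self._summary_rows().to_string(float_format=lambda v: f"{v:.4f}")
        return "\n".join(head) + "\n" + body

    def _summary_extra(self):
        return []
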