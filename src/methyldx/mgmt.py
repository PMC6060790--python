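"""Three-state MGMT promoter methylation call.

A logistic model over the M-values of two promoter probes predicts the
probability of MGMT promoter methylation; an indeterminate probability band
yields the third readout.  Coefficients are configuration-driven — this
package ships no clinical defaults, and clinically validated values must be
taken from a validated source for the array platform in use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

__all__ = ["MgmtModel", "MgmtCall", "mgmt_call", "load_mgmt_model", "beta_to_m"]

_BETA_CLAMP = 1e-6


@dataclass(frozen=True)
class MgmtModel:
    """Two-probe logistic model with an indeterminate band on p."""

    probe_ids: tuple
    intercept: float
    weights: tuple  # one per probe, M-value scale
    cutoff_low: float
    cutoff_high: float

    def __post_init__(self) -> None:
        if len(self.probe_ids) != 2 or len(self.weights) != 2:
            raise ValueError("MGMT model uses exactly two probes")
        if not (0 < self.cutoff_low <= self.cutoff_high < 1):
            raise ValueError("cutoffs must satisfy 0 < low <= high < 1")

    def predict(self, betas) -> float:
        m = beta_to_m(np.asarray(betas, dtype=np.float64))
        z = self.intercept + float(np.dot(self.weights, m))
        return float(1.0 / (1.0 + np.exp(-z)))


@dataclass
class MgmtCall:
    status: str  # methylated | unmethylated | not_determinable
    probability: float | None = None
    missing_data: bool = False


def beta_to_m(beta):
    """M-value transform log2(beta / (1 − beta)), beta clamped to (0, 1)."""
    b = np.clip(np.asarray(beta, dtype=np.float64), _BETA_CLAMP, 1 - _BETA_CLAMP)
    return np.log2(b / (1 - b))


def mgmt_call(betas: dict, model: MgmtModel) -> MgmtCall:
    """Call MGMT status from per-probe beta values.

    ``betas`` maps probe id → beta.  Missing or non-finite probes yield
    not_determinable with the missing-data flag set.  Otherwise p below the
    band is unmethylated, above is methylated, inside is not_determinable.
    """
    vals = []
    for pid in model.probe_ids:
        b = betas.get(pid)
        if b is None or not np.isfinite(b):
            return MgmtCall("not_determinable", None, missing_data=True)
        vals.append(float(b))
    p = model.predict(vals)
    if p < model.cutoff_low:
        return MgmtCall("unmethylated", p)
    if p > model.cutoff_high:
        return MgmtCall("methylated", p)
    return MgmtCall("not_determinable", p)


def load_mgmt_model(path) -> MgmtModel:
    """Load a model file: probes, intercept, weights, cutoff_low/high (YAML)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return MgmtModel(
        probe_ids=tuple(doc["probes"]),
        intercept=float(doc["intercept"]),
        weights=tuple(float(w) for w in doc["weights"]),
        cutoff_low=float(doc["cutoff_low"]),
        cutoff_high=float(doc["cutoff_high"]),
    )
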