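"""Tissue-level injury metrics from per-element field summaries.

The inputs are per-element maxima over the impact: the 1st principal
Green-Lagrange strain in the brain and the von-Mises stress in the skull.
The brain metric (MPS) is the 95th percentile over elements — rather than
the raw maximum — to avoid single-element numerical artefacts; the skull
metric is the plain field maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .constants import MTBI_STRAIN_THRESHOLD
from .errors import InvalidParameterError

__all__ = ["ElementField", "RiskFlag", "mps_95", "peak_stress", "mtbi_risk_flag"]


@dataclass(frozen=True)
class ElementField:
    """Per-element scalar maxima over time (strain, dimensionless, or stress, Pa)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 1:
            raise InvalidParameterError("an ElementField needs at least one element")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("field values must all be finite")

    @property
    def element_count(self) -> int:
        return int(self.values.size)


def _as_field(field: ElementField | np.ndarray) -> ElementField:
    return field if isinstance(field, ElementField) else ElementField(np.asarray(field))


def mps_95(strain: ElementField | np.ndarray) -> float:
    """95th-percentile maximum principal strain over brain elements (MPS).

    Uses linear interpolation between closest ranks: the percentile sits at
    rank ``1 + 0.95 (n - 1)`` on the sorted values (unweighted by element
    volume).
    """
    field = _as_field(strain)
    if np.any(field.values < 0):
        raise InvalidParameterError("strain field values must be >= 0")
    return float(np.percentile(field.values, 95.0, method="linear"))


def peak_stress(stress: ElementField | np.ndarray) -> float:
    """Maximum von-Mises stress over skull elements during the impact, Pa."""
    field = _as_field(stress)
    return float(np.max(field.values))


class RiskFlag(str, Enum):
    BELOW = "below"
    AT_OR_ABOVE = "at_or_above"


def mtbi_risk_flag(mps: float, threshold: float = MTBI_STRAIN_THRESHOLD) -> RiskFlag:
    """Compare an MPS value against the mild-TBI strain threshold (0.3 ~ 50% risk)."""
    if mps < 0:
        raise InvalidParameterError(f"MPS must be >= 0, got {mps}")
    if not threshold > 0:
        raise InvalidParameterError("threshold must be > 0")
    return RiskFlag.AT_OR_ABOVE if mps >= threshold else RiskFlag.BELOW
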