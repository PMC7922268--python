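"""Gap distances and imbalance metrics.

A gap is the sum of the femoral and tibial resected thicknesses of one
compartment in one pose. Two imbalance functionals are derived from the four
gaps of a knee:

* MLI (medio-lateral imbalance) = lateral gap - medial gap, per pose;
* FEI (flexion-extension imbalance) = extension gap - flexion gap, per
  compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .resection import ThicknessPair

__all__ = [
    "GapSet",
    "ImbalanceRecord",
    "gap_distances",
    "mli",
    "fei",
    "classify_alignment",
    "balanced_both_compartments",
]


@dataclass(frozen=True)
class GapSet:
    """Four per-compartment gap distances (mm) for one knee and one posterior
    reference method."""

    ext_med: float
    ext_lat: float
    flex_med: float
    flex_lat: float
    method: Optional[str] = None

    def __post_init__(self):
        for name in ("ext_med", "ext_lat", "flex_med", "flex_lat"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"gap {name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class ImbalanceRecord:
    """Per-knee, per-method imbalance summary feeding the cohort statistics."""

    knee_id: str
    group: str  # varus | valgus
    hka: float
    method: str
    gaps: GapSet
    mli_ext: float = field(init=False)
    mli_flex: float = field(init=False)
    fei_med: float = field(init=False)
    fei_lat: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "mli_ext", mli(self.gaps, "extension"))
        object.__setattr__(self, "mli_flex", mli(self.gaps, "flexion"))
        object.__setattr__(self, "fei_med", fei(self.gaps, "medial"))
        object.__setattr__(self, "fei_lat", fei(self.gaps, "lateral"))


def gap_distances(
    femoral_ext: ThicknessPair,
    femoral_flex: ThicknessPair,
    tibial: ThicknessPair,
    method: Optional[str] = None,
) -> GapSet:
    """Assemble the four gaps as femoral + tibial resected thickness sums."""
    return GapSet(
        ext_med=femoral_ext.medial + tibial.medial,
        ext_lat=femoral_ext.lateral + tibial.lateral,
        flex_med=femoral_flex.medial + tibial.medial,
        flex_lat=femoral_flex.lateral + tibial.lateral,
        method=method,
    )


def mli(gaps: GapSet, pose: str) -> float:
    """Medio-lateral imbalance (lateral - medial) in the given pose."""
    if pose == "extension":
        return gaps.ext_lat - gaps.ext_med
    if pose == "flexion":
        return gaps.flex_lat - gaps.flex_med
    raise ValueError(f"pose must be 'extension' or 'flexion', got {pose!r}")


def fei(gaps: GapSet, compartment: str) -> float:
    """Flexion-extension imbalance (extension - flexion) in the given compartment."""
    if compartment == "medial":
        return gaps.ext_med - gaps.flex_med
    if compartment == "lateral":
        return gaps.ext_lat - gaps.flex_lat
    raise ValueError(f"compartment must be 'medial' or 'lateral', got {compartment!r}")


def classify_alignment(hka: float) -> str:
    """Alignment group from the signed HKA: > 0 varus, <= 0 valgus."""
    if math.isnan(hka):
        raise ValueError("HKA is NaN")
    return "varus" if hka > 0 else "valgus"


def balanced_both_compartments(record: ImbalanceRecord, threshold: float) -> bool:
    """True when both compartments' |FEI| are simultaneously within ``threshold`` mm."""
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    return abs(record.fei_med) <= threshold and abs(record.fei_lat) <= threshold
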