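"""Closed-form scores: IHC H-score, elliptical wound area, percent wound
closure, and ddCt qPCR fold change.

* H-score = 3*(% of 3+ cells) + 2*(% of 2+ cells) + 1*(% of 1+ cells),
  range 0-300; the remainder to 100% is unstained (intensity 0).
* Wound area treats the caliper length/width pair as ellipse axes:
  area = (length/2) * (width/2) * pi.
* Percent closure = 100 * (1 - area_t / area_0) relative to the initial
  wound; wounds that expand yield negative values, reported with a warning
  rather than clipped.
* ddCt fold change = 2^-[(Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_control];
  replicate Ct values should be averaged before calling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import UsageError, ValidationError

__all__ = [
    "StainFractions",
    "WoundMeasurement",
    "CtQuad",
    "h_score",
    "wound_area",
    "percent_closure",
    "ddct_fold_change",
    "mean_ct",
]


@dataclass(frozen=True)
class StainFractions:
    """Percentages of cells at staining intensities 1+, 2+ and 3+."""

    pct1: float
    pct2: float
    pct3: float

    def __post_init__(self) -> None:
        for name, v in (("pct1", self.pct1), ("pct2", self.pct2), ("pct3", self.pct3)):
            if not 0 <= v <= 100:
                raise ValidationError(f"{name}={v} outside [0, 100]")
        total = self.pct1 + self.pct2 + self.pct3
        if total > 100 + 1e-9:
            raise ValidationError(f"stain fractions sum to {total} > 100")


@dataclass(frozen=True)
class WoundMeasurement:
    """One caliper measurement of a wound (cm) on a given day."""

    length: float
    width: float
    day: int = 0

    def __post_init__(self) -> None:
        if self.length < 0 or self.width < 0:
            raise ValidationError("wound dimensions must be non-negative")


@dataclass(frozen=True)
class CtQuad:
    """Mean Ct values for target/reference genes in sample and control."""

    ct_target_sample: float
    ct_ref_sample: float
    ct_target_control: float
    ct_ref_control: float

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(f"{name}={v} must be finite and > 0")


def h_score(f: StainFractions) -> float:
    """Semiquantitative staining score in [0, 300]."""
    return 3.0 * f.pct3 + 2.0 * f.pct2 + 1.0 * f.pct1


def wound_area(w: WoundMeasurement) -> float:
    """Elliptical wound area in cm^2 from caliper length and width."""
    return (w.length / 2.0) * (w.width / 2.0) * math.pi


def percent_closure(area_t: float, area_0: float) -> float:
    """Percent closure relative to the initial wound area."""
    if area_0 <= 0:
        raise UsageError(f"initial wound area must be > 0, got {area_0}")
    if area_t < 0:
        raise UsageError(f"wound area must be >= 0, got {area_t}")
    pct = 100.0 * (1.0 - area_t / area_0)
    if pct < 0:
        warnings.warn(f"wound expanded: closure {pct:.1f}% < 0 (reported unclipped)")
    return pct


def mean_ct(replicates: list[float]) -> float:
    """Average replicate Ct values (triplicates, typically) before ddCt."""
    if not replicates:
        raise UsageError("mean_ct needs at least one replicate")
    return sum(replicates) / len(replicates)


def ddct_fold_change(q: CtQuad) -> float:
    """Relative expression of target vs reference, sample vs control."""
    ddct = (q.ct_target_sample - q.ct_ref_sample) - (
        q.ct_target_control - q.ct_ref_control
    )
    return 2.0 ** (-ddct)
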