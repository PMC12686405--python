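"""Single-cell stable-isotope-probing quantification from ion counts.

Secondary-ion mass spectrometry reports per-plane counts of the
12C14N- and 12C15N- ions for each region of interest (ROI, one cell).
The cell's 15N/(14N+15N) ratio is accumulated over all planes, passed
through counting-statistics and background quality control, converted
to atom-percent excess over natural abundance and to an N-based growth
rate given the labeling strength of the substrate pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError

#: Natural abundance of 15N/(14N+15N).
NATURAL_ABUNDANCE_RATIO = 3.7e-3

#: Default background acceptance window for the accumulated ratio.
BACKGROUND_WINDOW = (3.4e-3, 4.0e-3)

GROUPS = ("Nitrosopumilus", "Nitrosopelagicus_WCA", "other")
SIP_TREATMENTS = ("NH4_15N", "UREA_15N", "UREA_15N_PLUS_NH4")

__all__ = [
    "RoiIonCounts",
    "SipContext",
    "CellEnrichment",
    "GroupSummary",
    "accumulate_ratio",
    "poisson_relative_error",
    "background_qc",
    "lod_ratio",
    "atom_percent_excess",
    "growth_rate",
    "evaluate_cell",
    "summarize_group",
    "NATURAL_ABUNDANCE_RATIO",
    "BACKGROUND_WINDOW",
]


@dataclass
class RoiIonCounts:
    """Per-plane 12C14N- / 12C15N- ion counts for one ROI."""

    roi_id: str
    group: str
    treatment: str
    counts_14N: np.ndarray
    counts_15N: np.ndarray
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts_14N = np.asarray(self.counts_14N)
        self.counts_15N = np.asarray(self.counts_15N)
        if self.counts_14N.size < 1:
            raise ValidationError("an ROI needs at least one plane")
        if self.counts_14N.shape != self.counts_15N.shape:
            raise ValidationError("14N and 15N plane counts differ in length")
        if np.any(self.counts_14N < 0) or np.any(self.counts_15N < 0):
            raise ValidationError("ion counts must be non-negative")

    @property
    def n_planes(self) -> int:
        return int(self.counts_14N.size)


@dataclass
class SipContext:
    """Constants of one SIP experiment.

    ``substrate_at_percent`` is the 15N at% of the substrate pool after
    tracer addition (>97 in the experiments this models);
    ``lod_ratio`` maps (group, treatment) to the ratio detection limit,
    or holds a single float applied to every cell.
    """

    natural_abundance_ratio: float = NATURAL_ABUNDANCE_RATIO
    substrate_at_percent: float = 97.0
    incubation_time_days: float = 1.0
    lod_ratio: dict | float | None = None
    poisson_error_max: float = 0.05
    background_window: tuple[float, float] = BACKGROUND_WINDOW
    growth_model: str = "linear"

    def __post_init__(self):
        if not (0.0 < self.natural_abundance_ratio < 0.01):
            raise ValidationError("natural_abundance_ratio out of (0, 0.01)")
        nat_at = 100.0 * self.natural_abundance_ratio
        if not (nat_at < self.substrate_at_percent <= 100.0):
            raise ValidationError(
                "substrate_at_percent must exceed natural abundance")
        if self.incubation_time_days <= 0:
            raise ValidationError("incubation_time_days must be > 0")
        if self.growth_model not in ("linear", "exponential"):
            raise ValidationError(f"unknown growth model {self.growth_model!r}")

    def lod_for(self, group: str, treatment: str) -> float | None:
        if self.lod_ratio is None:
            return None
        if isinstance(self.lod_ratio, dict):
            return self.lod_ratio.get((group, treatment))
        return float(self.lod_ratio)


@dataclass
class CellEnrichment:
    """Derived quantities and QC flags for one cell."""

    roi_id: str
    group: str
    treatment: str
    ratio: float
    poisson_rel_error: float
    error_ok: bool
    background_ok: bool
    above_lod: bool
    ape: float
    ape_negative: bool
    growth_rate: float

    @property
    def qc_ok(self) -> bool:
        return self.error_ok and self.background_ok


@dataclass
class GroupSummary:
    group: str
    treatment: str
    n: int
    n_above_lod: int
    mean_ape: float
    sd_ape: float
    mean_growth_rate: float          # mean of per-cell growth rates
    growth_rate_of_mean_ape: float   # growth rate computed from the mean APE


def accumulate_ratio(roi: RoiIonCounts) -> float:
    """15N/(14N+15N) from counts summed over all planes.

    Invariant to how counts are partitioned into planes.
    """
    s15 = float(np.sum(roi.counts_15N))
    s14 = float(np.sum(roi.counts_14N))
    total = s14 + s15
    if total <= 0:
        raise ValidationError(f"ROI {roi.roi_id}: zero total ion counts")
    return s15 / total


def poisson_relative_error(roi: RoiIonCounts) -> float:
    """Counting-statistics relative error of the accumulated ratio.

    ``sqrt(1/sum(15N) + 1/sum(14N))``; infinite (automatic QC failure)
    when either channel has zero accumulated counts.
    """
    s15 = float(np.sum(roi.counts_15N))
    s14 = float(np.sum(roi.counts_14N))
    if s15 <= 0 or s14 <= 0:
        return math.inf
    return math.sqrt(1.0 / s15 + 1.0 / s14)


def background_qc(background_ratios: Sequence[float],
                  window: tuple[float, float] = BACKGROUND_WINDOW) -> bool:
    """Pass iff the mean background ratio lies inside the closed window."""
    r = np.asarray(background_ratios, dtype=float)
    if r.size == 0:
        raise ValidationError("no background measurements")
    lo, hi = window
    return bool(lo <= r.mean() <= hi)


def lod_ratio(background_ratios: Sequence[float], k: float = 3.0) -> float:
    """Ratio detection limit: mean of the background plus k standard deviations."""
    r = np.asarray(background_ratios, dtype=float)
    if r.size < 2:
        raise ValidationError("need >= 2 background measurements for an LOD")
    return float(r.mean() + k * r.std(ddof=1))


def atom_percent_excess(ratio: float, ctx: SipContext) -> float:
    """``100 * (ratio - natural abundance)``; may be negative."""
    if not (0.0 <= ratio <= 1.0):
        raise ValidationError("ratio must be in [0, 1]")
    return 100.0 * (ratio - ctx.natural_abundance_ratio)


def growth_rate(ape_cell: float, ctx: SipContext) -> float:
    """N-based growth rate from a cell's atom-percent excess.

    Linear incorporation: the newly assimilated N fraction is
    ``f_new = APE_cell / (substrate at% - natural-abundance at%)`` and
    ``mu = f_new / t``.  The exponential alternative
    ``mu = -ln(1 - f_new) / t`` is selected by ``ctx.growth_model``.
    Negative APE maps to a rate of zero.
    """
    if ape_cell <= 0:
        return 0.0
    ape_substrate = ctx.substrate_at_percent - 100.0 * ctx.natural_abundance_ratio
    f_new = ape_cell / ape_substrate
    if ctx.growth_model == "exponential":
        if f_new >= 1.0:
            raise ValidationError("new-N fraction >= 1; exponential model undefined")
        return -math.log(1.0 - f_new) / ctx.incubation_time_days
    return f_new / ctx.incubation_time_days


def evaluate_cell(roi: RoiIonCounts, ctx: SipContext,
                  background_ok: bool = True) -> CellEnrichment:
    """QC, enrichment and growth rate for a single ROI."""
    ratio = accumulate_ratio(roi)
    err = poisson_relative_error(roi)
    ape = atom_percent_excess(ratio, ctx)
    lod = ctx.lod_for(roi.group, roi.treatment)
    above = bool(lod is not None and ratio > lod)
    return CellEnrichment(
        roi_id=roi.roi_id, group=roi.group, treatment=roi.treatment,
        ratio=ratio, poisson_rel_error=err,
        error_ok=err < ctx.poisson_error_max,
        background_ok=background_ok, above_lod=above,
        ape=ape, ape_negative=ape < 0,
        growth_rate=growth_rate(ape, ctx))


def summarize_group(cells: Iterable[CellEnrichment],
                    ctx: SipContext | None = None) -> GroupSummary:
    """Summary statistics over the QC-passing cells of one (group, treatment).

    Cells failing the counting-error or background QC are excluded
    regardless of their enrichment.  Both growth-rate conventions are
    reported: the mean of per-cell rates and the rate recomputed from
    the mean APE (identical under the linear model, not under the
    exponential one).
    """
    kept = [c for c in cells if c.qc_ok]
    if not kept:
        raise ValidationError("no QC-passing cells to summarize")
    keys = {(c.group, c.treatment) for c in kept}
    if len(keys) > 1:
        raise ValidationError(f"mixed (group, treatment) in summary: {keys}")
    group, treatment = keys.pop()
    apes = np.array([c.ape for c in kept])
    rates = np.array([c.growth_rate for c in kept])
    mean_ape = float(apes.mean())
    if ctx is not None:
        from_mean = growth_rate(mean_ape, ctx) if mean_ape > 0 else 0.0
    else:
        from_mean = math.nan
    return GroupSummary(
        group=group, treatment=treatment, n=len(kept),
        n_above_lod=sum(c.above_lod for c in kept),
        mean_ape=mean_ape,
        sd_ape=float(apes.std(ddof=1)) if len(kept) > 1 else 0.0,
        mean_growth_rate=float(rates.mean()),
        growth_rate_of_mean_ape=from_mean)
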