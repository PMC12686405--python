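"""Seeded generators for every input table the analysis stages consume.

Each generator carries its ground truth along (as ``truth`` metadata on
the domain objects, or a separate truth table), so estimator bias and
classifier accuracy can be measured without external data.  Random
streams are derived per table from ``(seed, stream-name)`` so adding a
generator never perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .kinetics import HOURS_PER_DAY, IncubationSeries, labeling_fraction
from .sip import NATURAL_ABUNDANCE_RATIO, RoiIonCounts

__all__ = [
    "IncubationScenario",
    "CellPopulationScenario",
    "HitTableScenario",
    "RegionNutrientConfig",
    "DEFAULT_NUTRIENT_REGIONS",
    "gen_incubation",
    "gen_cells",
    "gen_hits",
    "gen_nutrients",
]


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one named stream of one seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stream.encode("utf-8"))]))


# ---------------------------------------------------------------------------
# incubation time series

@dataclass
class IncubationScenario:
    """Design of a simulated tracer incubation experiment.

    ``true_rate`` is the process rate in nM-N per day; the generated
    15N-product series accumulates at ``true_rate * f_label`` where the
    labeling fraction follows from ambient substrate, tracer addition
    and tracer purity.  Gaussian measurement noise of SD ``noise_sd``
    (nM-N) is added per sample and truncated at zero.
    """

    true_rate: float
    ambient_substrate: float
    tracer_added: float
    tracer_purity: float
    noise_sd: float
    timepoints: Sequence[float]
    n_replicates: int = 1
    seed: int = 0
    urea_to_ammonium_leak_rate: float = 0.0
    #: 15N-product present at t = 0 (natural-abundance background); the
    #: regression intercept absorbs it.  With a baseline above the noise
    #: floor the zero-truncation of concentrations never distorts the series.
    baseline_product_nM: float = 0.0
    region: str = "synthetic"
    station: str = "S1"
    depth_m: float = 10.0
    treatment: str = "NH4_15N"

    def __post_init__(self):
        t = np.asarray(self.timepoints, dtype=float)
        if t.size < 3 or np.any(np.diff(t) <= 0):
            raise ValidationError(
                "timepoints must be strictly increasing with >= 3 points")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.true_rate < 0:
            raise ValidationError("true_rate must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.baseline_product_nM < 0:
            raise ValidationError("baseline_product_nM must be >= 0")
        # validates ambient/added/purity domains as a side effect
        self.f_label = labeling_fraction(
            self.ambient_substrate, self.tracer_added, self.tracer_purity)


def gen_incubation(scenario: IncubationScenario) -> list[IncubationSeries]:
    """Simulate one incubation series per replicate.

    The noiseless expectation at time t (hours) is
    ``true_rate * f_label * t / 24``; with a non-zero urea-to-ammonium
    leak rate a combined 15N-ammonium + 15N-nitrite series is attached.
    """
    rng = stream_rng(scenario.seed, "incubation")
    t = np.asarray(scenario.timepoints, dtype=float)
    t_days = t / HOURS_PER_DAY
    f = scenario.f_label
    out = []
    for rep in range(scenario.n_replicates):
        clean = scenario.baseline_product_nM + scenario.true_rate * f * t_days
        noisy = clean + rng.normal(0.0, scenario.noise_sd, size=t.size) \
            if scenario.noise_sd > 0 else clean.copy()
        truncated = noisy < 0
        product = np.where(truncated, 0.0, noisy)
        combined = None
        if scenario.urea_to_ammonium_leak_rate > 0:
            ammonium = scenario.urea_to_ammonium_leak_rate * f * t_days
            if scenario.noise_sd > 0:
                ammonium = ammonium + rng.normal(
                    0.0, scenario.noise_sd, size=t.size)
            combined = np.clip(ammonium, 0.0, None) + product
        out.append(IncubationSeries(
            region=scenario.region, station=scenario.station,
            depth_m=scenario.depth_m, treatment=scenario.treatment,
            replicate=f"r{rep + 1}", time_h=t.copy(),
            product_15N_nM=product, combined_15N_nM=combined,
            labeling_fraction=f,
            truth={"true_rate": scenario.true_rate, "f_label": f,
                   "noise_sd": scenario.noise_sd,
                   "truncated": truncated,
                   "leak_rate": scenario.urea_to_ammonium_leak_rate}))
    return out


# ---------------------------------------------------------------------------
# SIMS ion counts

@dataclass
class CellPopulationScenario:
    """Population of enriched cells plus natural-abundance background cells."""

    n_cells: int
    true_ape_mean: float
    true_ape_sd: float
    mean_total_counts_per_plane: float
    n_planes: int = 30
    n_background_cells: int = 0
    seed: int = 0
    group: str = "other"
    treatment: str = "NH4_15N"
    natural_abundance_ratio: float = NATURAL_ABUNDANCE_RATIO

    def __post_init__(self):
        if self.n_cells < 0 or self.n_background_cells < 0:
            raise ValidationError("cell counts must be >= 0")
        if self.n_planes < 1:
            raise ValidationError("n_planes must be >= 1")
        if self.mean_total_counts_per_plane <= 0:
            raise ValidationError("mean counts per plane must be > 0")
        if self.true_ape_sd < 0:
            raise ValidationError("true_ape_sd must be >= 0")


def gen_cells(scenario: CellPopulationScenario) -> list[RoiIonCounts]:
    """Simulate per-plane ion counts for every ROI.

    The total N ion count of each plane is Poisson with the configured
    mean; the 15N share is binomial at the cell's true ratio — the
    counting statistics of a SIMS detector.  Background cells sit at
    the natural-abundance ratio.
    """
    rng = stream_rng(scenario.seed, "cells")
    nat = scenario.natural_abundance_ratio
    rois = []

    def make_roi(idx: int, true_ratio: float, is_background: bool):
        totals = rng.poisson(scenario.mean_total_counts_per_plane,
                             size=scenario.n_planes)
        c15 = rng.binomial(totals, true_ratio)
        c14 = totals - c15
        return RoiIonCounts(
            roi_id=f"roi{idx:04d}", group=scenario.group,
            treatment=scenario.treatment, counts_14N=c14, counts_15N=c15,
            truth={"true_ratio": true_ratio,
                   "true_ape": 100.0 * (true_ratio - nat),
                   "is_background": is_background})

    idx = 0
    for _ in range(scenario.n_cells):
        ape = max(0.0, rng.normal(scenario.true_ape_mean, scenario.true_ape_sd)
                  if scenario.true_ape_sd > 0 else scenario.true_ape_mean)
        ratio = min(1.0, nat + ape / 100.0)
        rois.append(make_roi(idx, ratio, False))
        idx += 1
    for _ in range(scenario.n_background_cells):
        rois.append(make_roi(idx, nat, True))
        idx += 1
    return rois


# ---------------------------------------------------------------------------
# alignment hit tables

_BLAST_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                  "gapopen", "qstart", "qend", "sstart", "send",
                  "evalue", "bitscore"]


@dataclass
class HitTableScenario:
    """Class-conditional score/identity distributions for simulated hits.

    Scores and identities are normal with the given (location, scale),
    clipped to their domains; ``scale = 0`` makes a class
    deterministic.  ``p_global_hit`` is the probability that a read has
    any global-database hit at all.
    """

    n_true: int
    n_false: int
    custom_score_true: tuple[float, float] = (200.0, 15.0)
    custom_score_false: tuple[float, float] = (150.0, 30.0)
    global_score_true: tuple[float, float] = (160.0, 15.0)
    global_score_false: tuple[float, float] = (300.0, 40.0)
    identity_true: tuple[float, float] = (96.0, 2.0)
    identity_false: tuple[float, float] = (85.0, 5.0)
    p_global_hit: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_true < 0 or self.n_false < 0:
            raise ValidationError("hit counts must be >= 0")
        if not (0.0 <= self.p_global_hit <= 1.0):
            raise ValidationError("p_global_hit must be in [0, 1]")


def _draw(rng, loc_scale, size, lo, hi):
    loc, scale = loc_scale
    if scale == 0:
        return np.full(size, float(loc))
    return np.clip(rng.normal(loc, scale, size=size), lo, hi)


def gen_hits(scenario: HitTableScenario
             ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate best-hit tables for the custom and global databases.

    Returns ``(custom_hits, global_hits, truth)``; the truth table
    records each read's generating class (``is_true``).  Hit tables use
    outfmt-6-style columns; coordinate columns are filled with
    placeholder values.
    """
    rng = stream_rng(scenario.seed, "hits")
    n = scenario.n_true + scenario.n_false
    read_ids = np.array([f"read{idx:06d}" for idx in range(n)])
    is_true = np.array([True] * scenario.n_true + [False] * scenario.n_false)

    cscore = np.where(
        is_true,
        _draw(rng, scenario.custom_score_true, n, 1.0, np.inf),
        _draw(rng, scenario.custom_score_false, n, 1.0, np.inf))
    gscore = np.where(
        is_true,
        _draw(rng, scenario.global_score_true, n, 1.0, np.inf),
        _draw(rng, scenario.global_score_false, n, 1.0, np.inf))
    ident = np.where(
        is_true,
        _draw(rng, scenario.identity_true, n, 0.0, 100.0),
        _draw(rng, scenario.identity_false, n, 0.0, 100.0))
    has_global = rng.random(n) < scenario.p_global_hit

    def table(ids, subjects, scores, idents):
        m = len(ids)
        return pd.DataFrame({
            "qseqid": ids, "sseqid": subjects, "pident": idents,
            "length": np.full(m, 50), "mismatch": np.zeros(m, dtype=int),
            "gapopen": np.zeros(m, dtype=int),
            "qstart": np.ones(m, dtype=int), "qend": np.full(m, 150),
            "sstart": np.ones(m, dtype=int), "send": np.full(m, 50),
            "evalue": np.full(m, 1e-20), "bitscore": scores,
        }, columns=_BLAST_COLUMNS)

    custom = table(read_ids, np.array([f"gene{'T' if t else 'F'}1"
                                       for t in is_true]), cscore, ident)
    keep = has_global
    glob = table(read_ids[keep],
                 np.array(["global_ref"] * int(keep.sum())),
                 gscore[keep], _draw(rng, (80.0, 5.0), int(keep.sum()),
                                     0.0, 100.0))
    truth = pd.DataFrame({"read_id": read_ids, "is_true": is_true,
                          "has_global_hit": has_global})
    return custom, glob, truth


# ---------------------------------------------------------------------------
# nutrient profiles

@dataclass
class RegionNutrientConfig:
    """Log-normal nutrient regime of one region.

    ``sigma`` is the log-scale spread; the configured medians are the
    medians of the generated log-normal samples.  Values below the
    analytical LODs are stored at the LOD and flagged below-detection.
    """

    median_ammonium_nM: float
    median_urea_nM: float
    sigma: float = 0.6
    ammonium_lod_nM: float = 1.0
    urea_lod_nM: float = 10.0
    n_samples: int = 40
    depth_range_m: tuple[float, float] = (2.0, 150.0)
    median_nitrite_nM: float = 50.0
    median_nitrate_nM: float = 2000.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if min(self.median_ammonium_nM, self.median_urea_nM) <= 0:
            raise ValidationError("medians must be > 0")


#: Regimes loosely parameterized to the three study regions
#: (median ammonium-N 320 / 51 / 11 nM, urea-N 138 / 130 / 52 nM).
DEFAULT_NUTRIENT_REGIONS: dict[str, RegionNutrientConfig] = {
    "Gulf_of_Mexico": RegionNutrientConfig(
        median_ammonium_nM=320.0, median_urea_nM=138.0,
        ammonium_lod_nM=10.0, urea_lod_nM=27.6,
        depth_range_m=(2.0, 18.5)),
    "Black_Sea": RegionNutrientConfig(
        median_ammonium_nM=51.0, median_urea_nM=130.0,
        ammonium_lod_nM=42.7, urea_lod_nM=27.6,
        depth_range_m=(5.0, 145.0)),
    "Angola_Gyre": RegionNutrientConfig(
        median_ammonium_nM=11.0, median_urea_nM=52.0,
        ammonium_lod_nM=1.0, urea_lod_nM=40.0,
        depth_range_m=(5.0, 150.0)),
}


def gen_nutrients(regions: Mapping[str, RegionNutrientConfig] | None = None,
                  seed: int = 0) -> pd.DataFrame:
    """Simulate a depth-resolved nutrient concentration table.

    One row per sample with ammonium-N, urea-N, nitrite and nitrate
    concentrations (nM); below-detection values are stored at the LOD
    with their flag set, and the pre-censoring truth is kept in
    ``truth_``-prefixed columns.
    """
    if regions is None:
        regions = DEFAULT_NUTRIENT_REGIONS
    rng = stream_rng(seed, "nutrients")
    rows = []
    for region, cfg in regions.items():
        depths = np.sort(rng.uniform(*cfg.depth_range_m, size=cfg.n_samples))
        for i, depth in enumerate(depths):
            def lognorm(median):
                if cfg.sigma == 0:
                    return float(median)
                return float(median * np.exp(rng.normal(0.0, cfg.sigma)))

            amm = lognorm(cfg.median_ammonium_nM)
            urea = lognorm(cfg.median_urea_nM)
            amm_below = amm < cfg.ammonium_lod_nM
            urea_below = urea < cfg.urea_lod_nM
            rows.append({
                "region": region, "station": f"st{i % 4 + 1}",
                "depth_m": round(float(depth), 2),
                "ammonium_nM": cfg.ammonium_lod_nM if amm_below else amm,
                "ammonium_below_lod": amm_below,
                "ammonium_lod_nM": cfg.ammonium_lod_nM,
                "urea_nM": cfg.urea_lod_nM if urea_below else urea,
                "urea_below_lod": urea_below,
                "urea_lod_nM": cfg.urea_lod_nM,
                "nitrite_nM": lognorm(cfg.median_nitrite_nM),
                "nitrate_nM": lognorm(cfg.median_nitrate_nM),
                "truth_ammonium_nM": amm,
                "truth_urea_nM": urea,
            })
    return pd.DataFrame(rows)
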