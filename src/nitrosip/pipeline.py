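"""End-to-end orchestration: simulate -> rates -> sip -> genes -> stats.

Each stage reads the tables the previous stage wrote inside the run's
output directory, so stages can also be run individually from the CLI.
A run writes all files into a temporary sibling directory first and
renames them into place only on success, so partial outputs are never
left behind.  The run report records per-stage row counts and every QC
exclusion with its triggering rule.
"""

from __future__ import annotations

import itertools
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import genes as _genes
from . import io as _io
from . import kinetics as _kin
from . import sip as _sip
from . import stats as _stats
from . import synthetic as _syn
from .config import RunConfig
from .errors import ValidationError

log = logging.getLogger("nitrosip")

INPUT_FILES = {
    "incubations": "incubations.tsv",
    "nutrients": "nutrients.tsv",
    "rois": "rois.tsv",
    "custom_hits": "custom_hits.tsv",
    "global_hits": "global_hits.tsv",
    "gene_meta": "gene_meta.tsv",
}

OUTPUT_FILES = {
    "rates": "rates.tsv",
    "sip_cells": "sip_cells.tsv",
    "sip_groups": "sip_groups.tsv",
    "gene_rpkm": "gene_rpkm.tsv",
    "stats": "stats.json",
}


@dataclass
class RunReport:
    config_hash: str
    version: str
    seed: int
    row_counts: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)

    def exclude(self, stage: str, item: str, rule: str) -> None:
        self.exclusions.append({"stage": stage, "item": item, "rule": rule})
        log.info("excluded %s at stage %s: %s", item, stage, rule)

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "version": self.version,
                "seed": self.seed, "row_counts": self.row_counts,
                "exclusions": self.exclusions}


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: RunConfig, outdir: Path, report: RunReport) -> None:
    """Generate every pipeline input with ground truth sidecars."""
    out = Path(outdir)
    series = list(itertools.chain.from_iterable(
        _syn.gen_incubation(s) for s in config.incubations))
    _io.write_incubations(series, out / INPUT_FILES["incubations"])
    truth_rows = [{"region": s.region, "station": s.station,
                   "depth_m": s.depth_m, "treatment": s.treatment,
                   "replicate": s.replicate,
                   "truth_rate": s.truth.get("true_rate"),
                   "truth_f_label": s.truth.get("f_label"),
                   "truth_noise_sd": s.truth.get("noise_sd")}
                  for s in series]
    _io.write_tsv(pd.DataFrame(truth_rows), out / "incubations_truth.tsv")

    nutrients = _syn.gen_nutrients(config.nutrient_regions, seed=config.seed)
    truth_cols = [c for c in nutrients.columns if c.startswith("truth_")]
    _io.write_tsv(nutrients.drop(columns=truth_cols),
                  out / INPUT_FILES["nutrients"])
    _io.write_tsv(nutrients[["region", "station", "depth_m"] + truth_cols],
                  out / "nutrients_truth.tsv")

    rois = list(itertools.chain.from_iterable(
        _syn.gen_cells(s) for s in config.cells))
    _io.write_rois(rois, out / INPUT_FILES["rois"])
    _io.write_tsv(pd.DataFrame(
        [{"roi_id": r.roi_id, "truth_ratio": r.truth.get("true_ratio"),
          "truth_ape": r.truth.get("true_ape"),
          "truth_is_background": r.truth.get("is_background")}
         for r in rois]), out / "rois_truth.tsv")

    hits_scn = config.hits or _syn.HitTableScenario(
        n_true=200, n_false=100, seed=config.seed)
    custom, glob, truth = _syn.gen_hits(hits_scn)
    _io.write_blast_tabular(custom, out / INPUT_FILES["custom_hits"])
    _io.write_blast_tabular(glob, out / INPUT_FILES["global_hits"])
    _io.write_tsv(truth.rename(columns={"is_true": "truth_is_true"}),
                  out / "hits_truth.tsv")
    # toy gene metadata matching the subjects the hit generator emits
    _io.write_tsv(pd.DataFrame({
        "gene_id": ["geneT1", "geneF1"],
        "family": ["amoA", "ureC"],
        "group": ["Nitrosopelagicus_WCA", "other"],
        "length_bp": [600, 1700]}), out / INPUT_FILES["gene_meta"])

    report.row_counts["simulate"] = {
        "incubation_series": len(series), "nutrient_samples": len(nutrients),
        "rois": len(rois), "custom_hits": len(custom),
        "global_hits": len(glob)}


def stage_rates(config: RunConfig, outdir: Path, report: RunReport) -> None:
    """Slope fitting, censoring and duplicate reconciliation per region."""
    out = Path(outdir)
    series = _io.read_incubations(out / INPUT_FILES["incubations"])
    by_batch: dict = {}
    for s in series:
        by_batch.setdefault((s.region, s.treatment), []).append(s)

    estimates: list[_kin.RateEstimate] = []
    for (region, treatment), batch in sorted(by_batch.items()):
        fits = [_kin.fit_slope(s) for s in batch]
        pooled = _kin.pooled_residual_sd(fits)
        noise = pooled if pooled > 0 else None
        for s in batch:
            estimates.append(_kin.estimate_rate(s, noise_sd=noise,
                                                alpha=config.alpha))

    finals: list[_kin.RateEstimate] = []
    grouped: dict = {}
    for e in estimates:
        grouped.setdefault(e.key(), []).append(e)
    for key, group in sorted(grouped.items()):
        rcfg = config.region_rate_config(key[0])
        if rcfg.reconcile_duplicates and len(group) == 2:
            final = _kin.reconcile_duplicates(group[0], group[1])
            if final.censored:
                report.exclude("rates", str(key),
                               "non-significant replicate censored during "
                               "duplicate reconciliation")
            finals.append(final)
        else:
            for e in group:
                c = _kin.censor_estimate(e, rcfg.censoring_policy)
                if c.censored:
                    report.exclude(
                        "rates", f"{key}/{e.replicate}",
                        f"non-significant slope set to "
                        f"{rcfg.censoring_policy}")
                finals.append(c)

    _io.write_rates(finals, out / OUTPUT_FILES["rates"])
    report.row_counts["rates"] = {"input_series": len(series),
                                  "output_rates": len(finals)}


def stage_sip(config: RunConfig, outdir: Path, report: RunReport) -> None:
    """ROI counts -> QC-filtered enrichment and per-group summaries."""
    out = Path(outdir)
    rois = _io.read_rois(out / INPUT_FILES["rois"])
    scfg = config.sip

    backgrounds = [r for r in rois if r.group == scfg.background_group]
    cells = [r for r in rois if r.group != scfg.background_group]
    if scfg.lod_ratio is not None:
        lod = scfg.lod_ratio
        background_ok = True
    elif len(backgrounds) >= 2:
        bg_ratios = [_sip.accumulate_ratio(r) for r in backgrounds]
        lod = _sip.lod_ratio(bg_ratios, k=scfg.lod_k)
        background_ok = _sip.background_qc(
            bg_ratios, tuple(scfg.background_window))
        if not background_ok:
            report.exclude("sip", "<all cells>",
                           "mean background ratio outside window")
    else:
        lod, background_ok = None, True
    ctx = scfg.context(lod_ratio=lod)

    enriched = []
    for roi in cells:
        cell = _sip.evaluate_cell(roi, ctx, background_ok=background_ok)
        if not cell.error_ok:
            report.exclude("sip", roi.roi_id,
                           f"poisson relative error "
                           f"{cell.poisson_rel_error:.3g} >= "
                           f"{ctx.poisson_error_max}")
        enriched.append(cell)

    _io.write_tsv(_io.cells_to_frame(enriched),
                  out / OUTPUT_FILES["sip_cells"])
    summaries = []
    by_group: dict = {}
    for c in enriched:
        by_group.setdefault((c.group, c.treatment), []).append(c)
    for group_cells in by_group.values():
        if any(c.qc_ok for c in group_cells):
            summaries.append(_sip.summarize_group(group_cells, ctx))
    _io.write_tsv(_io.group_summaries_to_frame(summaries),
                  out / OUTPUT_FILES["sip_groups"])
    report.row_counts["sip"] = {
        "rois": len(rois), "background_rois": len(backgrounds),
        "cells": len(enriched),
        "qc_passed": sum(c.qc_ok for c in enriched),
        "lod_ratio": lod}


def stage_genes(config: RunConfig, outdir: Path, report: RunReport) -> None:
    """BSR classification, per-gene RPKM and group gene:amoA ratios."""
    out = Path(outdir)
    custom = _io.read_blast_tabular(out / INPUT_FILES["custom_hits"])
    glob = _io.read_blast_tabular(out / INPUT_FILES["global_hits"])
    meta = _io.read_gene_meta(out / INPUT_FILES["gene_meta"])

    cls = _genes.bsr_classify(custom, glob, config.classifier)
    for _, row in cls[~cls["accepted"]].iterrows():
        report.exclude("genes", row["read_id"],
                       "failed score/identity/BSR thresholds")
    abundance = _genes.abundance_table(cls, meta, config.library_size_reads)
    _io.write_tsv(abundance, out / OUTPUT_FILES["gene_rpkm"])

    ratio_rows = []
    for group in sorted(meta["group"].unique()):
        for fam in ("ureC", "dur3"):
            r = _genes.group_gene_ratio(abundance, group, fam)
            ratio_rows.append({"group": group, "numerator_family": fam,
                               "denominator_family": "amoA", "ratio": r})
    _io.write_tsv(pd.DataFrame(ratio_rows), out / "gene_ratios.tsv")
    report.row_counts["genes"] = {
        "reads_classified": len(cls),
        "reads_accepted": int(cls["accepted"].sum())}


def stage_stats(config: RunConfig, outdir: Path, report: RunReport) -> None:
    """Urea-N fractions, box summaries and pairwise rank-sum tests."""
    out = Path(outdir)
    nut = _io.read_nutrients(out / INPUT_FILES["nutrients"])
    policy = config.stats.lod_policy
    fractions = {}
    result: dict = {"regions": {}, "comparisons": []}
    for region, grp in nut.groupby("region", sort=True):
        fr = [
            _stats.urea_fraction(
                row.urea_nM, row.ammonium_nM,
                urea_below_lod=bool(row.urea_below_lod),
                ammonium_below_lod=bool(row.ammonium_below_lod),
                urea_lod_nM=row.urea_lod_nM,
                ammonium_lod_nM=row.ammonium_lod_nM,
                lod_policy=policy)
            for row in grp.itertuples()
        ]
        fr = [f for f in fr if not np.isnan(f)]
        fractions[region] = fr
        mean, se = _stats.mean_with_se(fr)
        box = _stats.box_summary(grp["urea_nM"], config.stats.whisker_mode)
        result["regions"][region] = {
            "n": len(grp),
            "urea_fraction_mean": mean, "urea_fraction_se": se,
            "median_ammonium_nM": float(grp["ammonium_nM"].median()),
            "median_urea_nM": float(grp["urea_nM"].median()),
            "urea_box": vars(box),
        }
    for r1, r2 in itertools.combinations(sorted(fractions), 2):
        test = _stats.mann_whitney(fractions[r1], fractions[r2])
        result["comparisons"].append({
            "comparison": f"urea_fraction:{r1}_vs_{r2}",
            "W": test.W, "p_value": test.p_value,
            "n1": test.n1, "n2": test.n2, "method": test.method})

    with open(out / OUTPUT_FILES["stats"], "w", encoding="utf-8") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
    report.row_counts["stats"] = {"nutrient_samples": len(nut),
                                  "comparisons": len(result["comparisons"])}


STAGES = {
    "simulate": stage_simulate,
    "rates": stage_rates,
    "sip": stage_sip,
    "genes": stage_genes,
    "stats": stage_stats,
}


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage; outputs appear atomically in ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.parent.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.hash(), version=__version__,
                       seed=config.seed)
    tmp = Path(tempfile.mkdtemp(prefix=".nitrosip-",
                                dir=outdir.parent or "."))
    try:
        for name, stage in STAGES.items():
            log.info("running stage %s", name)
            stage(config, tmp, report)
        with open(tmp / "run_report.json", "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        outdir.mkdir(parents=True, exist_ok=True)
        for item in sorted(tmp.iterdir()):
            shutil.move(str(item), str(outdir / item.name))
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
    return report


def run_stage(name: str, config: RunConfig) -> RunReport:
    """Run a single stage in place (inputs must already exist)."""
    if name not in STAGES:
        raise ValidationError(f"unknown stage {name!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.hash(), version=__version__,
                       seed=config.seed)
    STAGES[name](config, outdir, report)
    return report
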