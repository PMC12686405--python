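"""Readers and writers for the tabular and sequence formats of the pipeline.

All tables are TSV with a header row, UTF-8, '.' decimal separator and
empty fields for missing values; below-detection values are encoded as
value = LOD plus a boolean flag column.  BLAST tabular input is the
12-column outfmt-6 layout without a header.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import SchemaError
from .kinetics import IncubationSeries, RateEstimate
from .sip import CellEnrichment, GroupSummary, RoiIonCounts

BLAST6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                  "gapopen", "qstart", "qend", "sstart", "send",
                  "evalue", "bitscore"]

INCUBATION_COLUMNS = ["region", "station", "depth_m", "treatment",
                      "replicate", "time_h", "product_15N_nM",
                      "combined_15N_nM", "labeling_fraction"]

ROI_COLUMNS = ["roi_id", "group", "treatment", "plane",
               "counts_14N", "counts_15N"]

NUTRIENT_COLUMNS = ["region", "station", "depth_m",
                    "ammonium_nM", "ammonium_below_lod", "ammonium_lod_nM",
                    "urea_nM", "urea_below_lod", "urea_lod_nM",
                    "nitrite_nM", "nitrate_nM"]

GENE_META_COLUMNS = ["gene_id", "family", "group", "length_bp"]

RATE_COLUMNS = ["region", "station", "depth_m", "treatment", "replicate",
                "slope", "slope_se", "t_statistic", "p_one_sided",
                "rate", "lod", "significant", "censored", "n_points"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_tsv(path, required: Sequence[str] | None = None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed TSV: {exc}") from exc
    if required is not None:
        _require_columns(df, required, path)
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# incubation series

def incubations_to_frame(series: Iterable[IncubationSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for i in range(s.n_points):
            rows.append({
                "region": s.region, "station": s.station,
                "depth_m": s.depth_m, "treatment": s.treatment,
                "replicate": s.replicate, "time_h": s.time_h[i],
                "product_15N_nM": s.product_15N_nM[i],
                "combined_15N_nM": (s.combined_15N_nM[i]
                                    if s.combined_15N_nM is not None
                                    else np.nan),
                "labeling_fraction": s.labeling_fraction,
            })
    return pd.DataFrame(rows, columns=INCUBATION_COLUMNS)


def frame_to_incubations(df: pd.DataFrame) -> list[IncubationSeries]:
    _require_columns(df, INCUBATION_COLUMNS, "<frame>")
    out = []
    keys = ["region", "station", "depth_m", "treatment", "replicate"]
    for key, grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_h")
        fvals = grp["labeling_fraction"].unique()
        if len(fvals) != 1:
            raise SchemaError(
                f"series {key}: inconsistent labeling_fraction values")
        combined = grp["combined_15N_nM"].to_numpy(dtype=float)
        out.append(IncubationSeries(
            region=key[0], station=key[1], depth_m=float(key[2]),
            treatment=key[3], replicate=key[4],
            time_h=grp["time_h"].to_numpy(dtype=float),
            product_15N_nM=grp["product_15N_nM"].to_numpy(dtype=float),
            combined_15N_nM=None if np.isnan(combined).all() else combined,
            labeling_fraction=float(fvals[0])))
    return out


def write_incubations(series: Iterable[IncubationSeries], path) -> None:
    write_tsv(incubations_to_frame(series), path)


def read_incubations(path) -> list[IncubationSeries]:
    return frame_to_incubations(read_tsv(path, INCUBATION_COLUMNS))


# ---------------------------------------------------------------------------
# rate estimates

def rates_to_frame(estimates: Iterable[RateEstimate]) -> pd.DataFrame:
    rows = [{c: getattr(e, c) for c in RATE_COLUMNS} for e in estimates]
    return pd.DataFrame(rows, columns=RATE_COLUMNS)


def write_rates(estimates: Iterable[RateEstimate], path) -> None:
    write_tsv(rates_to_frame(estimates), path)


def read_rates(path) -> pd.DataFrame:
    return read_tsv(path, RATE_COLUMNS)


# ---------------------------------------------------------------------------
# SIMS ROI tables

def rois_to_frame(rois: Iterable[RoiIonCounts]) -> pd.DataFrame:
    rows = []
    for r in rois:
        for plane in range(r.n_planes):
            rows.append({
                "roi_id": r.roi_id, "group": r.group,
                "treatment": r.treatment, "plane": plane + 1,
                "counts_14N": int(r.counts_14N[plane]),
                "counts_15N": int(r.counts_15N[plane]),
            })
    return pd.DataFrame(rows, columns=ROI_COLUMNS)


def frame_to_rois(df: pd.DataFrame) -> list[RoiIonCounts]:
    _require_columns(df, ROI_COLUMNS, "<frame>")
    out = []
    for (roi_id, group, treatment), grp in df.groupby(
            ["roi_id", "group", "treatment"], sort=True):
        grp = grp.sort_values("plane")
        out.append(RoiIonCounts(
            roi_id=roi_id, group=group, treatment=treatment,
            counts_14N=grp["counts_14N"].to_numpy(dtype=np.int64),
            counts_15N=grp["counts_15N"].to_numpy(dtype=np.int64)))
    return out


def write_rois(rois: Iterable[RoiIonCounts], path) -> None:
    write_tsv(rois_to_frame(rois), path)


def read_rois(path) -> list[RoiIonCounts]:
    return frame_to_rois(read_tsv(path, ROI_COLUMNS))


def cells_to_frame(cells: Iterable[CellEnrichment]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in cells])


def group_summaries_to_frame(summaries: Iterable[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


# ---------------------------------------------------------------------------
# nutrients, gene metadata

def read_nutrients(path) -> pd.DataFrame:
    return read_tsv(path, NUTRIENT_COLUMNS)


def read_gene_meta(path) -> pd.DataFrame:
    return read_tsv(path, GENE_META_COLUMNS)


# ---------------------------------------------------------------------------
# BLAST tabular

def read_blast_tabular(path) -> pd.DataFrame:
    """Parse 12-column outfmt-6 output; wrong column counts are errors."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise SchemaError(
                    f"{path}: expected 12 tab-separated columns, "
                    f"got {len(parts)}", line=lineno)
            rows.append(parts)
    df = pd.DataFrame(rows, columns=BLAST6_COLUMNS)
    if len(df) == 0:
        return df
    for col in ("pident", "evalue", "bitscore"):
        df[col] = df[col].astype(float)
    for col in ("length", "mismatch", "gapopen", "qstart", "qend",
                "sstart", "send"):
        df[col] = df[col].astype(int)
    return df


def write_blast_tabular(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[BLAST6_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(records, fh, "fasta")
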