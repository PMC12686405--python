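"""Marker-gene read classification and abundance quantification.

Reads are searched against a curated marker-gene database and against a
large global protein database; the ratio of the two best bitscores (the
BLAST score ratio, BSR) separates true hits to the curated genes from
reads that merely resemble them.  Accepted reads are counted per gene,
normalised to RPKM, aggregated per taxon group and family, and related
through gene:marker ratios.  A probe-coverage scorer checks what
fraction of a group's reference diversity an oligonucleotide probe
matches exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import ValidationError

GENE_FAMILIES = ("amoA", "ureC", "dur3", "16S")

#: Acceptance thresholds for a true-positive hit.
DEFAULT_MIN_SCORE = 100.0
DEFAULT_MIN_IDENTITY = 90.0
DEFAULT_MIN_BSR = 0.9

__all__ = [
    "BsrThresholds",
    "best_hit",
    "best_hits",
    "bsr_classify",
    "subset_reassign",
    "rpkm",
    "abundance_table",
    "group_gene_ratio",
    "probe_coverage",
    "ProbeCoverage",
]


@dataclass(frozen=True)
class BsrThresholds:
    min_score: float = DEFAULT_MIN_SCORE
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_bsr: float = DEFAULT_MIN_BSR
    #: how to treat reads with no global-database hit: "accept" treats the
    #: BSR criterion as satisfied, "strict" rejects the read.
    missing_global: str = "accept"

    def __post_init__(self):
        if self.missing_global not in ("accept", "strict"):
            raise ValidationError(
                f"missing_global must be 'accept' or 'strict', "
                f"got {self.missing_global!r}")
        if not (0 <= self.min_identity <= 100):
            raise ValidationError("min_identity must be in [0, 100]")
        if self.min_score < 0 or self.min_bsr < 0:
            raise ValidationError("thresholds must be non-negative")


def best_hit(hits: pd.DataFrame) -> pd.Series:
    """Best hit among the rows for one read within one database.

    Maximum bitscore; ties broken by higher percent identity, then by
    lexicographically smallest subject id, so the result is invariant
    to input row order.
    """
    if len(hits) == 0:
        raise ValidationError("empty hit list")
    df = hits.sort_values(["bitscore", "pident", "sseqid"],
                          ascending=[False, False, True], kind="mergesort")
    return df.iloc[0]


def best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-read best hits for a whole table (same tie rule as best_hit)."""
    if len(hits) == 0:
        return hits.copy()
    df = hits.sort_values(["qseqid", "bitscore", "pident", "sseqid"],
                          ascending=[True, False, False, True],
                          kind="mergesort")
    return df.drop_duplicates("qseqid", keep="first").reset_index(drop=True)


def bsr_classify(custom_hits: pd.DataFrame,
                 global_hits: pd.DataFrame | None = None,
                 thresholds: BsrThresholds = BsrThresholds()) -> pd.DataFrame:
    """Accept or reject each read by score, identity and BSR thresholds.

    Parameters
    ----------
    custom_hits, global_hits:
        Tabular alignment hits (outfmt-6 style columns ``qseqid``,
        ``sseqid``, ``pident``, ``bitscore`` at minimum).  Only reads
        with at least one custom-database hit are classified.

    Returns
    -------
    One row per read: ``read_id``, best custom ``subject`` / ``score`` /
    ``identity``, best ``global_score`` (NaN if absent), ``bsr`` and the
    boolean ``accepted``.
    """
    if len(custom_hits) == 0:
        raise ValidationError("no custom-database hits to classify")
    best_c = best_hits(custom_hits)
    out = pd.DataFrame({
        "read_id": best_c["qseqid"].to_numpy(),
        "subject": best_c["sseqid"].to_numpy(),
        "score": best_c["bitscore"].to_numpy(dtype=float),
        "identity": best_c["pident"].to_numpy(dtype=float),
    })
    if global_hits is not None and len(global_hits) > 0:
        best_g = best_hits(global_hits)[["qseqid", "bitscore"]].rename(
            columns={"qseqid": "read_id", "bitscore": "global_score"})
        out = out.merge(best_g, on="read_id", how="left")
    else:
        out["global_score"] = np.nan

    out["bsr"] = out["score"] / out["global_score"]
    has_global = out["global_score"].notna()
    bsr_ok = (out["bsr"] >= thresholds.min_bsr).fillna(False)
    if thresholds.missing_global == "accept":
        bsr_ok = bsr_ok | ~has_global
    out["accepted"] = ((out["score"] >= thresholds.min_score)
                       & (out["identity"] >= thresholds.min_identity)
                       & bsr_ok)
    return out.sort_values("read_id", kind="mergesort").reset_index(drop=True)


def subset_reassign(accepted: pd.DataFrame,
                    subset_hits: pd.DataFrame,
                    subset_global_hits: pd.DataFrame | None = None,
                    thresholds: BsrThresholds = BsrThresholds()
                    ) -> tuple[pd.DataFrame, float]:
    """Second BSR pass against a lineage-subset database.

    ``accepted`` is a classification table (only rows with
    ``accepted == True`` are considered).  Returns the per-read subset
    flag table and the fraction of accepted reads assigned to the
    subset lineage.
    """
    acc = accepted.loc[accepted["accepted"], ["read_id"]].copy()
    if len(acc) == 0:
        return acc.assign(in_subset=pd.Series(dtype=bool)), 0.0
    if len(subset_hits) > 0:
        sub_cls = bsr_classify(subset_hits, subset_global_hits, thresholds)
        sub_ok = sub_cls.loc[sub_cls["accepted"],
                             ["read_id"]].assign(in_subset=True)
        acc = acc.merge(sub_ok, on="read_id", how="left")
        acc["in_subset"] = acc["in_subset"].notna() & acc["in_subset"].eq(True)
    else:
        acc["in_subset"] = False
    return acc, float(acc["in_subset"].mean())


def rpkm(count: float, gene_length_bp: float, library_size_reads: float) -> float:
    """Reads per kilobase of gene per million library reads."""
    if gene_length_bp <= 0:
        raise ValidationError("gene length must be > 0")
    if library_size_reads <= 0:
        raise ValidationError("library size must be > 0")
    return count / ((gene_length_bp / 1e3) * (library_size_reads / 1e6))


def abundance_table(classification: pd.DataFrame,
                    gene_meta: pd.DataFrame,
                    library_size_reads: float,
                    sample_id: str = "sample") -> pd.DataFrame:
    """Per-gene read counts and RPKM from accepted classifications.

    Each accepted read is assigned to its best custom-database subject
    only.  ``gene_meta`` must carry ``gene_id``, ``family``, ``group``
    and ``length_bp``; genes with zero accepted reads appear with count
    and RPKM of 0 so aggregates stay complete.
    """
    required = {"gene_id", "family", "group", "length_bp"}
    missing = required - set(gene_meta.columns)
    if missing:
        raise ValidationError(f"gene metadata missing columns {sorted(missing)}")
    if (gene_meta["length_bp"] <= 0).any():
        raise ValidationError("gene lengths must be > 0")
    counts = (classification.loc[classification["accepted"], "subject"]
              .value_counts())
    out = gene_meta.copy()
    out["sample_id"] = sample_id
    out["read_count"] = out["gene_id"].map(counts).fillna(0).astype(int)
    out["rpkm"] = [
        rpkm(c, l, library_size_reads)
        for c, l in zip(out["read_count"], out["length_bp"])
    ]
    cols = ["sample_id", "gene_id", "family", "group", "length_bp",
            "read_count", "rpkm"]
    return out[cols]


def group_gene_ratio(abundance: pd.DataFrame, group: str,
                     numerator_family: str,
                     denominator_family: str = "amoA") -> float:
    """Ratio of summed group RPKM of one gene family to another.

    NaN (reported missing) when the denominator aggregate is zero.
    """
    sub = abundance[abundance["group"] == group]
    num = float(sub.loc[sub["family"] == numerator_family, "rpkm"].sum())
    den = float(sub.loc[sub["family"] == denominator_family, "rpkm"].sum())
    if den == 0:
        return math.nan
    return num / den


@dataclass
class ProbeCoverage:
    """Coverage of a probe over group reference sequences.

    ``sequence_percent`` weights every reference equally;
    ``read_weighted_percent`` weights each reference by the number of
    reads mapped to it (equal to sequence_percent under uniform
    weights).
    """
    n_references: int
    n_matching: int
    sequence_percent: float
    read_weighted_percent: float


def probe_coverage(references: Mapping[str, str], probe: str,
                   read_weights: Mapping[str, float] | None = None
                   ) -> ProbeCoverage:
    """Percent of reference diversity carrying a perfect probe match.

    The reverse complement of the probe must occur as an exact,
    case-insensitive substring of the reference sequence.  Degenerate
    bases are not expanded.
    """
    if len(references) == 0:
        raise ValidationError("no reference sequences")
    if len(probe) < 15:
        raise ValidationError("probe must be >= 15 nt")
    target = str(Seq(probe).reverse_complement()).upper()
    matches = {rid: target in str(seq).upper()
               for rid, seq in references.items()}
    n_match = sum(matches.values())
    seq_pct = 100.0 * n_match / len(references)
    if read_weights is None:
        weighted_pct = seq_pct
    else:
        total = sum(read_weights.get(rid, 0.0) for rid in references)
        if total <= 0:
            raise ValidationError("read weights sum to zero")
        hit = sum(w for rid, w in read_weights.items()
                  if matches.get(rid, False))
        weighted_pct = 100.0 * hit / total
    return ProbeCoverage(n_references=len(references), n_matching=n_match,
                         sequence_percent=seq_pct,
                         read_weighted_percent=weighted_pct)
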