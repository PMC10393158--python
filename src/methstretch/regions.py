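"""Site- and region-level methylation summaries.

Aggregates per-read calls into per-site counts (optionally split by
parental allele), applies the coverage and informative-site filters used
for bulk WGBS summaries, computes 10-kb-bin and region/ICR methylation
levels, and classifies per-embryo ICR states to flag stochastic
methylation loss.

Site tables are pandas DataFrames with columns
(chrom, pos, context, allele, n_meth, n_unmeth); pos is 0-based.
Levels are read-weighted (summed methylated calls over summed calls), the
common WGBS convention; a site-averaged mode is available for sensitivity
checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .readstats import MethRead

logger = logging.getLogger(__name__)

__all__ = [
    "Region",
    "SITE_COLUMNS",
    "aggregate_site_counts",
    "filter_sites_by_coverage",
    "global_methylation",
    "bin_methylation",
    "region_methylation",
    "split_by_allele",
    "classify_icr_state",
]

SITE_COLUMNS = ["chrom", "pos", "context", "allele", "n_meth", "n_unmeth"]

REGION_CLASSES = ("maternal_ICR", "paternal_ICR", "CpG_island", "bin10kb", "other")

_ALLELE_NAMES = {"M": "maternal", "P": "paternal"}


@dataclass(frozen=True)
class Region:
    """A named genomic interval (0-based half-open) with a class label."""

    chrom: str
    start: int
    end: int
    name: str
    region_class: str = "other"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.name}: start must be < end")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"{self.name}: unknown region class {self.region_class!r}")


def aggregate_site_counts(reads: Iterable[MethRead], by_allele: bool = False) -> pd.DataFrame:
    """Pile up per-read calls into per-site methylated/unmethylated counts.

    Always emits the combined pileup (all reads regardless of tag); with
    by_allele=True additionally emits maternal and paternal pileups from
    tagged reads only (untagged reads contribute to combined only).
    """
    rows: dict[tuple, list[int]] = {}

    def add(chrom: str, pos: int, ctx: str, allele: str, call: int) -> None:
        key = (chrom, pos, ctx, allele)
        entry = rows.setdefault(key, [0, 0])
        entry[0 if call else 1] += 1

    for read in reads:
        ctxs = read.contexts if read.contexts is not None else None
        for i in range(read.cg_positions.size):
            ctx = "CG" if ctxs is None or ctxs[i] == "C" else "non-CG"
            pos = int(read.cg_positions[i])
            call = int(read.calls[i])
            add(read.chrom, pos, ctx, "combined", call)
            if by_allele and read.allele in _ALLELE_NAMES:
                add(read.chrom, pos, ctx, _ALLELE_NAMES[read.allele], call)

    records = [
        {"chrom": c, "pos": p, "context": x, "allele": a,
         "n_meth": nm, "n_unmeth": nu}
        for (c, p, x, a), (nm, nu) in rows.items()
    ]
    df = pd.DataFrame(records, columns=SITE_COLUMNS)
    return df.sort_values(["allele", "chrom", "pos", "context"], ignore_index=True)


def filter_sites_by_coverage(sites: pd.DataFrame, min_cov: int = 4,
                             max_cov: int = 100) -> pd.DataFrame:
    """Keep sites with min_cov <= n_meth + n_unmeth <= max_cov.

    Defaults match combined analysis (4-100 reads); allelic analysis uses
    (1, 100).
    """
    if not 1 <= min_cov <= max_cov:
        raise ValueError("require 1 <= min_cov <= max_cov")
    cov = sites["n_meth"] + sites["n_unmeth"]
    return sites[(cov >= min_cov) & (cov <= max_cov)].reset_index(drop=True)


def global_methylation(sites: pd.DataFrame) -> dict[str, float]:
    """Read-weighted global level per context: sum(n_meth) / sum(coverage)."""
    out = {}
    for ctx, sub in sites.groupby("context"):
        cov = int(sub["n_meth"].sum() + sub["n_unmeth"].sum())
        out[str(ctx)] = float(sub["n_meth"].sum() / cov) if cov else float("nan")
    return out


def bin_methylation(sites: pd.DataFrame, bin_size_bp: int = 10_000,
                    min_informative: int = 5) -> pd.DataFrame:
    """Fixed-window methylation levels; sparse windows excluded.

    Bins tile each chromosome from 0 in half-open windows of bin_size_bp.
    A bin's informative-site count pools CG and non-CG sites (any site with
    coverage > 0); bins with fewer than min_informative are dropped.  Levels
    are then reported per context within the surviving bins.
    """
    if sites.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "context",
                                     "level", "n_sites", "n_meth", "n_unmeth"])
    df = sites.copy()
    df["bin_start"] = (df["pos"] // bin_size_bp) * bin_size_bp
    informative = df.groupby(["allele", "chrom", "bin_start"])["pos"].nunique()
    keep = informative[informative >= min_informative].index
    idx = pd.MultiIndex.from_frame(df[["allele", "chrom", "bin_start"]])
    df = df[idx.isin(keep)]
    grouped = df.groupby(["allele", "chrom", "bin_start", "context"], as_index=False).agg(
        n_sites=("pos", "nunique"), n_meth=("n_meth", "sum"), n_unmeth=("n_unmeth", "sum"))
    grouped["level"] = grouped["n_meth"] / (grouped["n_meth"] + grouped["n_unmeth"])
    grouped["start"] = grouped["bin_start"]
    grouped["end"] = grouped["bin_start"] + bin_size_bp
    return grouped[["allele", "chrom", "start", "end", "context",
                    "level", "n_sites", "n_meth", "n_unmeth"]]


def region_methylation(sites: pd.DataFrame, regions: Sequence[Region],
                       min_cumulative_calls: int = 10,
                       site_averaged: bool = False) -> pd.DataFrame:
    """Per-region methylation levels with a cumulative-call threshold.

    cumulative_calls counts every per-read CG call overlapping the region
    (with multiplicity, i.e. summed coverage); regions with
    cumulative_calls <= min_cumulative_calls are reported with status
    "no_data" and a NaN level.  Levels are read-weighted unless
    site_averaged is set.
    """
    out = []
    for allele, sub in (sites.groupby("allele") if not sites.empty
                        else [("combined", sites)]):
        for reg in regions:
            hit = sub[(sub["chrom"] == reg.chrom) & (sub["pos"] >= reg.start)
                      & (sub["pos"] < reg.end) & (sub["context"] == "CG")]
            cumulative = int(hit["n_meth"].sum() + hit["n_unmeth"].sum())
            if cumulative > min_cumulative_calls:
                if site_averaged:
                    level = float((hit["n_meth"] / (hit["n_meth"] + hit["n_unmeth"])).mean())
                else:
                    level = float(hit["n_meth"].sum() / cumulative)
                status = "ok"
            else:
                level, status = float("nan"), "no_data"
            out.append({
                "region": reg.name, "region_class": reg.region_class,
                "allele": allele, "level": level,
                "n_informative_cg": int(hit["pos"].nunique()),
                "cumulative_calls": cumulative, "status": status,
            })
    return pd.DataFrame(out, columns=["region", "region_class", "allele", "level",
                                      "n_informative_cg", "cumulative_calls", "status"])


def split_by_allele(reads: Sequence[MethRead]) -> tuple[list[MethRead], list[MethRead], int]:
    """Partition reads by parental tag: (maternal, paternal, untagged count)."""
    maternal = [r for r in reads if r.allele == "M"]
    paternal = [r for r in reads if r.allele == "P"]
    untagged = len(reads) - len(maternal) - len(paternal)
    logger.info("split_by_allele: %d maternal, %d paternal, %d untagged",
                len(maternal), len(paternal), untagged)
    return maternal, paternal, untagged


def classify_icr_state(region_levels: pd.DataFrame, full_min: float = 0.75,
                       lost_max: float = 0.25) -> pd.DataFrame:
    """Call each region full / partial / lost / no_data from its methylation level.

    full if level >= full_min, lost if level <= lost_max, partial between;
    no_data rows stay no_data.  A stochastic_loss flag marks maternal-ICR
    calls that are lost or partial on the maternal allele (or on combined
    data, as in uniparental samples where every read is maternal).
    """
    if not lost_max < full_min:
        raise ValueError("require lost_max < full_min")
    df = region_levels.copy()

    def call(row) -> str:
        if row["status"] == "no_data" or not np.isfinite(row["level"]):
            return "no_data"
        if row["level"] >= full_min:
            return "full"
        if row["level"] <= lost_max:
            return "lost"
        return "partial"

    df["state"] = df.apply(call, axis=1) if len(df) else pd.Series(dtype=object)
    df["stochastic_loss"] = (
        (df.get("region_class", "other") == "maternal_ICR")
        & df["allele"].isin(["maternal", "combined"])
        & df["state"].isin(["lost", "partial"])
    ) if len(df) else pd.Series(dtype=bool)
    return df
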