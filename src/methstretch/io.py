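"""File formats: Bismark-coverage-style site tables and BED region files.

Bismark coverage files are 1-based inclusive TSVs
(chrom, start, end, percent, count_methylated, count_unmethylated);
internally positions are 0-based, so readers/writers convert.  Regions
travel as 6-column BED with the region class appended to the name field
as "name|class" (plain names parse with class "other").
"""

from __future__ import annotations

import pandas as pd

from .regions import REGION_CLASSES, Region

__all__ = [
    "write_bismark_cov",
    "read_bismark_cov",
    "write_bed",
    "read_bed",
    "BedFormatError",
]

_COV_COLUMNS = ["chrom", "start", "end", "percent", "count_methylated", "count_unmethylated"]


class BedFormatError(ValueError):
    """Malformed BED line; message names the 1-based line number."""


def write_bismark_cov(sites: pd.DataFrame, path, allele: str = "combined") -> None:
    """Write a site table (one allele slice) as Bismark-style coverage."""
    sub = sites[sites["allele"] == allele] if "allele" in sites.columns else sites
    cov = sub["n_meth"] + sub["n_unmeth"]
    out = pd.DataFrame({
        "chrom": sub["chrom"],
        "start": sub["pos"] + 1,
        "end": sub["pos"] + 1,
        "percent": (100.0 * sub["n_meth"] / cov.where(cov > 0)).round(6),
        "count_methylated": sub["n_meth"],
        "count_unmethylated": sub["n_unmeth"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bismark_cov(path, context: str = "CG", allele: str = "combined") -> pd.DataFrame:
    """Read Bismark-style coverage into the internal 0-based site table."""
    raw = pd.read_csv(path, sep="\t", header=None, names=_COV_COLUMNS)
    return pd.DataFrame({
        "chrom": raw["chrom"].astype(str),
        "pos": raw["start"].astype(int) - 1,
        "context": context,
        "allele": allele,
        "n_meth": raw["count_methylated"].astype(int),
        "n_unmeth": raw["count_unmethylated"].astype(int),
    })


def write_bed(regions, path) -> None:
    with open(path, "w") as handle:
        for r in regions:
            name = r.name if r.region_class == "other" else f"{r.name}|{r.region_class}"
            handle.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t+\n")


def read_bed(path) -> list[Region]:
    regions: list[Region] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise BedFormatError(f"line {lineno}: expected >= 4 BED columns")
            try:
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            except ValueError as exc:
                raise BedFormatError(f"line {lineno}: {exc}") from exc
            if "|" in name:
                name, cls = name.rsplit("|", 1)
                if cls not in REGION_CLASSES:
                    raise BedFormatError(f"line {lineno}: unknown region class {cls!r}")
            else:
                cls = "other"
            try:
                regions.append(Region(chrom, start, end, name, cls))
            except ValueError as exc:
                raise BedFormatError(f"line {lineno}: {exc}") from exc
    return regions
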