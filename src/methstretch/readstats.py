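"""Per-read methylation statistics.

One sequencing read's CG methylation calls are the unit of analysis here:
per-read methylation level, the longest stretch of consecutively
methylated CGs (the processivity statistic), composition strata (reads
sharing the same number of CG sites k and the same number of methylated
CGs m, hence the same methylation ratio m/k), and the empirical
distribution of the longest stretch within a stratum.

The per-read TSV dialect (header required) is:
read_id, chrom, start, end, allele(M|P|U), cg_positions (comma-separated
0-based integers), calls (string over {0,1}), contexts (optional string
over {C,N}; defaults to all C).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from fractions import Fraction
from typing import Iterable, Mapping, NamedTuple, Sequence, TextIO

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MethRead",
    "StratumKey",
    "RunDistribution",
    "ReadFormatError",
    "parse_read_calls",
    "write_read_calls",
    "per_read_level",
    "filter_reads_min_cg",
    "longest_methylated_run",
    "longest_runs_matrix",
    "strata_from_ratio_window",
    "stratify_by_composition",
    "empirical_run_distribution",
    "read_level_distribution",
]

_ALLELES = ("M", "P", "U")


class ReadFormatError(ValueError):
    """Malformed per-read record; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class MethRead:
    """One sequencing read's CG sites and binary methylation calls.

    Coordinates are 0-based half-open; cg_positions must be strictly
    increasing and inside [start, end).  allele is M (maternal), P
    (paternal) or U (untagged).  contexts marks each site C (CG) or N
    (non-CG); k and m count CG-context sites only.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    cg_positions: np.ndarray
    calls: np.ndarray
    allele: str = "U"
    contexts: np.ndarray | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.cg_positions, dtype=np.int64)
        calls = np.asarray(self.calls, dtype=np.uint8)
        object.__setattr__(self, "cg_positions", pos)
        object.__setattr__(self, "calls", calls)
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"{self.read_id}: invalid interval [{self.start}, {self.end})")
        if pos.size != calls.size:
            raise ValueError(f"{self.read_id}: {pos.size} positions but {calls.size} calls")
        if pos.size:
            if pos[0] < self.start or pos[-1] >= self.end:
                raise ValueError(f"{self.read_id}: CG positions outside read interval")
            if pos.size > 1 and np.diff(pos).min() <= 0:
                raise ValueError(f"{self.read_id}: CG positions must be strictly increasing")
            if not np.isin(calls, (0, 1)).all():
                raise ValueError(f"{self.read_id}: calls must be 0/1")
        if self.allele not in _ALLELES:
            raise ValueError(f"{self.read_id}: allele must be one of {_ALLELES}")
        if self.contexts is not None:
            ctx = np.asarray(self.contexts)
            object.__setattr__(self, "contexts", ctx)
            if ctx.size != pos.size:
                raise ValueError(f"{self.read_id}: contexts length mismatch")
            if ctx.size and not np.isin(ctx, ("C", "N")).all():
                raise ValueError(f"{self.read_id}: contexts must be C or N")

    @property
    def cg_mask(self) -> np.ndarray:
        if self.contexts is None:
            return np.ones(self.cg_positions.size, dtype=bool)
        return self.contexts == "C"

    @property
    def cg_calls(self) -> np.ndarray:
        """Calls restricted to CG-context sites."""
        return self.calls[self.cg_mask]

    @property
    def k(self) -> int:
        return int(self.cg_mask.sum())

    @property
    def m(self) -> int:
        return int(self.cg_calls.sum())


class StratumKey(NamedTuple):
    """A read composition: k CG sites of which m are methylated."""

    k: int
    m: int

    @property
    def ratio(self) -> Fraction:
        return Fraction(self.m, self.k)


@dataclass(frozen=True)
class RunDistribution:
    """Probability distribution of the longest methylated run at fixed (k, m).

    pmf is indexed by run length 0..m.  kind is "exact" for the analytic
    null, "empirical" for observed reads (n_reads set) or "simulated".
    The support is confined to [ceil(m / (k - m + 1)), m] when m >= 1
    (pigeonhole: m ones among k - m + 1 zero-separated slots).
    """

    k: int
    m: int
    pmf: np.ndarray
    kind: str = "empirical"
    n_reads: int | None = None

    def __post_init__(self) -> None:
        pmf = np.asarray(self.pmf, dtype=float)
        object.__setattr__(self, "pmf", pmf)
        if not 0 <= self.m <= self.k:
            raise ValueError("need 0 <= m <= k")
        if pmf.size != self.m + 1:
            raise ValueError("pmf must have length m + 1 (run lengths 0..m)")
        if (pmf < -1e-12).any() or abs(pmf.sum() - 1.0) > 1e-9:
            raise ValueError("pmf entries must be non-negative and sum to 1")

    @property
    def min_run(self) -> int:
        return 0 if self.m == 0 else math.ceil(self.m / (self.k - self.m + 1))


def per_read_level(read: MethRead) -> tuple[int, int, float]:
    """(k, m, percent) for one read; percent = 100 m/k, half-even to one decimal.

    k = 0 has no defined level and yields percent = nan (the read is
    flagged, not dropped).
    """
    k, m = read.k, read.m
    if k == 0:
        return 0, 0, math.nan
    exact = Fraction(100 * m, k)
    percent = float((Decimal(exact.numerator) / Decimal(exact.denominator)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_EVEN))
    return k, m, percent


def filter_reads_min_cg(reads: Sequence[MethRead], min_cg_exclusive: int = 4) -> list[MethRead]:
    """Keep reads with more than min_cg_exclusive CG sites (k > threshold)."""
    if min_cg_exclusive < 0:
        raise ValueError("min_cg_exclusive must be >= 0")
    kept = [r for r in reads if r.k > min_cg_exclusive]
    logger.info("filter_reads_min_cg: kept %d of %d reads (removed %d with k <= %d)",
                len(kept), len(reads), len(reads) - len(kept), min_cg_exclusive)
    return kept


def longest_methylated_run(calls: Sequence[int] | np.ndarray) -> int:
    """Length of the longest block of consecutive 1s (0 for empty/all-zero)."""
    arr = np.asarray(calls, dtype=np.int64)
    if arr.size == 0:
        return 0
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("calls must be binary")
    edges = np.diff(np.concatenate(([0], arr, [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return int((ends - starts).max(initial=0))


def longest_runs_matrix(calls: np.ndarray) -> np.ndarray:
    """Row-wise longest run of 1s for an (n, k) binary matrix."""
    calls = np.asarray(calls, dtype=np.int64)
    if calls.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    acc = np.zeros(calls.shape[0], dtype=np.int64)
    best = np.zeros(calls.shape[0], dtype=np.int64)
    for j in range(calls.shape[1]):
        acc = (acc + calls[:, j]) * calls[:, j]
        np.maximum(best, acc, out=best)
    return best


def strata_from_ratio_window(
    low: Fraction = Fraction(5, 12),
    high: Fraction = Fraction(6, 11),
    k_max: int = 15,
    k_min: int = 5,
) -> list[StratumKey]:
    """All compositions (k, m), k_min <= k <= k_max, with m/k in [low, high]."""
    if low > high:
        raise ValueError("empty ratio window")
    out = []
    for k in range(max(k_min, 1), k_max + 1):
        for m in range(1, k + 1):
            if low <= Fraction(m, k) <= high:
                out.append(StratumKey(k, m))
    return out


def stratify_by_composition(
    reads: Iterable[MethRead],
    strata: Sequence[StratumKey],
) -> tuple[dict[StratumKey, list[MethRead]], int]:
    """Partition reads by exact (k, m) into the given strata.

    Returns (mapping stratum -> reads, count of reads matching no stratum).
    """
    if not strata:
        raise ValueError("strata must be non-empty")
    keys = [StratumKey(*s) for s in strata]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate strata keys")
    groups: dict[StratumKey, list[MethRead]] = {s: [] for s in keys}
    discarded = 0
    for read in reads:
        key = StratumKey(read.k, read.m)
        if key in groups:
            groups[key].append(read)
        else:
            discarded += 1
    for s, g in groups.items():
        logger.info("stratum (k=%d, m=%d): %d reads", s.k, s.m, len(g))
    logger.info("stratify_by_composition: %d reads matched no stratum", discarded)
    return groups, discarded


def empirical_run_distribution(group: Sequence[MethRead]) -> RunDistribution:
    """Empirical pmf of the longest methylated run over one (k, m) stratum."""
    if not group:
        raise ValueError("empty read group")
    k, m = group[0].k, group[0].m
    for r in group:
        if (r.k, r.m) != (k, m):
            raise ValueError(
                f"mixed compositions in group: ({r.k}, {r.m}) vs ({k}, {m})")
    counts = np.zeros(m + 1, dtype=np.int64)
    for r in group:
        counts[longest_methylated_run(r.cg_calls)] += 1
    return RunDistribution(k, m, counts / counts.sum(), kind="empirical", n_reads=len(group))


def run_distribution_from_lengths(k: int, m: int, lengths: np.ndarray) -> RunDistribution:
    """Empirical RunDistribution from precomputed longest-run lengths."""
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("no lengths given")
    counts = np.bincount(lengths, minlength=m + 1)
    if counts.size > m + 1:
        raise ValueError("run length exceeds m")
    return RunDistribution(k, m, counts / counts.sum(), kind="empirical",
                           n_reads=int(lengths.size))


def read_level_distribution(
    reads: Sequence[MethRead],
    regions: Sequence | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-read methylation levels, optionally restricted to regions.

    Returns (levels, matrices): levels has one row per read (and per
    overlapping region when regions are given) with columns read_id,
    region, k, m, percent; matrices maps each region name to a per-read
    call matrix (rows = reads, columns = CG positions, entries 1 =
    methylated, 0 = unmethylated, NaN = uncovered) in the style of a
    single-molecule mosaic alignment plot.
    """
    rows = []
    matrices: dict[str, pd.DataFrame] = {}
    if regions is None:
        for r in reads:
            k, m, pct = per_read_level(r)
            rows.append({"read_id": r.read_id, "region": "genome-wide",
                         "k": k, "m": m, "percent": pct})
        return pd.DataFrame(rows, columns=["read_id", "region", "k", "m", "percent"]), matrices

    for reg in regions:
        hits = [r for r in reads
                if r.chrom == reg.chrom and r.start < reg.end and r.end > reg.start]
        if not hits:
            logger.warning("region %s overlaps no reads", reg.name)
            matrices[reg.name] = pd.DataFrame()
            continue
        all_pos = sorted({int(p) for r in hits for p in r.cg_positions
                          if reg.start <= p < reg.end})
        mat = pd.DataFrame(np.nan, index=[r.read_id for r in hits], columns=all_pos)
        for r in hits:
            k, m, pct = per_read_level(r)
            rows.append({"read_id": r.read_id, "region": reg.name,
                         "k": k, "m": m, "percent": pct})
            inside = (r.cg_positions >= reg.start) & (r.cg_positions < reg.end)
            for p, c in zip(r.cg_positions[inside], r.calls[inside]):
                mat.loc[r.read_id, int(p)] = float(c)
        matrices[reg.name] = mat
    return pd.DataFrame(rows, columns=["read_id", "region", "k", "m", "percent"]), matrices


# ---------------------------------------------------------------------------
# per-read TSV dialect

_HEADER = ["read_id", "chrom", "start", "end", "allele", "cg_positions", "calls", "contexts"]


def write_read_calls(reads: Iterable[MethRead], path_or_handle) -> None:
    """Write reads in the per-read TSV dialect (always includes the contexts column)."""
    own = isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__")
    handle: TextIO = open(path_or_handle, "w") if own else path_or_handle
    try:
        handle.write("\t".join(_HEADER) + "\n")
        for r in reads:
            ctx = "".join(r.contexts) if r.contexts is not None else "C" * r.cg_positions.size
            handle.write("\t".join([
                r.read_id, r.chrom, str(r.start), str(r.end), r.allele,
                ",".join(str(int(p)) for p in r.cg_positions),
                "".join(str(int(c)) for c in r.calls),
                ctx,
            ]) + "\n")
    finally:
        if own:
            handle.close()


def parse_read_calls(path_or_handle) -> list[MethRead]:
    """Parse the per-read TSV dialect; malformed lines raise ReadFormatError with the line number."""
    own = isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__")
    handle: TextIO = open(path_or_handle) if own else path_or_handle
    try:
        header_line = handle.readline()
        if not header_line:
            raise ReadFormatError("missing header", 1)
        header = header_line.rstrip("\n").split("\t")
        if header[:7] != _HEADER[:7]:
            raise ReadFormatError(f"unexpected header {header!r}", 1)
        has_ctx = len(header) >= 8 and header[7] == "contexts"
        reads: list[MethRead] = []
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise ReadFormatError(f"expected >= 7 fields, got {len(fields)}", lineno)
            try:
                read_id, chrom, start, end, allele = fields[:5]
                pos_str, call_str = fields[5], fields[6]
                positions = (np.array([int(p) for p in pos_str.split(",")], dtype=np.int64)
                             if pos_str else np.empty(0, dtype=np.int64))
                if call_str and set(call_str) - {"0", "1"}:
                    raise ValueError(f"calls must be over {{0,1}}, got {call_str!r}")
                calls = np.array([int(c) for c in call_str], dtype=np.uint8)
                contexts = None
                if has_ctx and len(fields) >= 8 and fields[7]:
                    contexts = np.array(list(fields[7]))
                reads.append(MethRead(read_id, chrom, int(start), int(end),
                                      positions, calls, allele, contexts))
            except ReadFormatError:
                raise
            except (ValueError, TypeError) as exc:
                raise ReadFormatError(str(exc), lineno) from exc
        return reads
    finally:
        if own:
            handle.close()
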