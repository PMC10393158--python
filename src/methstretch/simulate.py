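"""Synthetic WGBS data generation.

Simulates the substrate of read-level methylation analysis: CG-site
landscapes, single-molecule methylation templates laid down either
distributively (each CG independent) or processively (tracts of
consecutive CGs methylated per enzyme engagement), mosaic pools of
molecules emulating pooled oocytes, bisulfite reads sampled from those
pools with configurable conversion error, and a stage-resolved model of
stochastic imprint loss and regain in early embryos.

All simulators are pure functions of their parameters including the
seed; per-entity streams are derived by hashing (master_seed, entity_id)
so pools are reproducible molecule by molecule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .readstats import MethRead

__all__ = [
    "CgLandscape",
    "MethTemplate",
    "SimConfig",
    "ImprintSimConfig",
    "derive_seed",
    "generate_cg_landscape",
    "simulate_distributive",
    "simulate_processive",
    "processive_calls_matrix",
    "processive_coverage_level",
    "solve_alpha_for_level",
    "simulate_oocyte_pool",
    "sample_reads",
    "simulate_imprint_trajectory",
]


def derive_seed(master_seed: int, entity_id: int) -> int:
    """Deterministically hash (master_seed, entity_id) into a child seed < 2**32."""
    ss = np.random.SeedSequence((int(master_seed) & 0xFFFFFFFF, int(entity_id) & 0xFFFFFFFF))
    return int(ss.generate_state(1, np.uint32)[0])


@dataclass(frozen=True)
class CgLandscape:
    """CG dinucleotide positions along one simulated chromosome.

    Positions are 0-based plus-strand C coordinates, strictly increasing,
    at least 2 bp apart (CG dinucleotides cannot overlap) and within
    [0, length_bp - 2].
    """

    chrom_name: str
    length_bp: int
    cg_positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.cg_positions, dtype=np.int64)
        object.__setattr__(self, "cg_positions", pos)
        if self.length_bp < 2:
            raise ValueError("length_bp must be >= 2")
        if pos.size:
            if pos[0] < 0 or pos[-1] > self.length_bp - 2:
                raise ValueError("cg_positions must lie in [0, length_bp - 2]")
            if pos.size > 1 and np.diff(pos).min() < 2:
                raise ValueError("adjacent CG positions must differ by >= 2")

    @property
    def n_sites(self) -> int:
        return int(self.cg_positions.size)


@dataclass(frozen=True)
class MethTemplate:
    """Methylation state of a single DNA molecule over a landscape."""

    landscape: CgLandscape
    calls: np.ndarray
    molecule_id: int = 0

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=np.uint8)
        object.__setattr__(self, "calls", calls)
        if calls.size != self.landscape.n_sites:
            raise ValueError("calls length must equal number of CG positions")
        if calls.size and not np.isin(calls, (0, 1)).all():
            raise ValueError("calls must be binary")

    @property
    def level(self) -> float:
        return float(self.calls.mean()) if self.calls.size else math.nan


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the molecule/read simulator.

    model selects the methylation mechanism: "distributive" methylates each
    CG independently with probability theta; "processive" initiates a tract
    at each CG with probability alpha and extends it site-to-site with
    probability rho (geometric tract length), stopping early when the next
    CG lies more than max_gap_bp away.  eps_over is the probability that an
    unmethylated site is read as methylated (bisulfite conversion failure);
    eps_under the reverse.
    """

    model: str = "distributive"
    theta: float = 0.5
    alpha: float = 0.1
    rho: float = 0.0
    max_gap_bp: int | None = None
    n_molecules: int = 200
    read_length_bp: int = 100
    mean_depth: float = 30.0
    eps_over: float = 0.003
    eps_under: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("distributive", "processive"):
            raise ValueError(f"unknown model {self.model!r}")
        for name in ("theta", "alpha", "eps_over", "eps_under"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1) (rho = 1 gives non-terminating tracts)")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.read_length_bp < 1:
            raise ValueError("read_length_bp must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.max_gap_bp is not None and self.max_gap_bp < 1:
            raise ValueError("max_gap_bp must be positive or None")


@dataclass(frozen=True)
class ImprintSimConfig:
    """Parameters of the imprint loss/regain trajectory simulator.

    Each ICR draws its length from icr_length_range (bp; defaults match the
    size range of maternally methylated ICRs, 0.7-6.7 kb).  n_anchors key
    CG sites per ICR act as all-or-nothing protectors (a ZFP57-site proxy):
    if at least one anchor is methylated in the oocyte the ICR is protected
    through cleavage and restored to full methylation after implantation;
    otherwise unprotected methylation is passively diluted and ultimately
    lost.
    """

    n_icrs: int = 12
    icr_length_range: tuple[float, float] = (700.0, 6700.0)
    mean_cg_spacing_bp: float = 25.0
    n_anchors: int = 1
    oocyte_level: float = 0.5
    erasure_rate: float = 0.15
    n_cleavage_divisions: int = 4
    n_embryos: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("oocyte_level", "erasure_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_icrs", "n_anchors", "n_cleavage_divisions", "n_embryos"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.icr_length_range
        if not 2 <= lo <= hi:
            raise ValueError("icr_length_range must satisfy 2 <= lo <= hi")


def generate_cg_landscape(
    length_bp: int,
    mean_spacing_bp: float,
    min_spacing_bp: int = 2,
    seed: int = 0,
    chrom_name: str = "chrSim",
) -> CgLandscape:
    """Place CG sites by a renewal process.

    Each inter-site gap is min_spacing_bp plus a geometric excess whose mean
    brings the total gap mean to mean_spacing_bp.  The first site sits at the
    end of a gap drawn from the same law, so the site density is
    approximately 1 / mean_spacing_bp.
    """
    if length_bp < min_spacing_bp or min_spacing_bp < 2:
        raise ValueError("require length_bp >= min_spacing_bp >= 2")
    if mean_spacing_bp < min_spacing_bp:
        raise ValueError("mean_spacing_bp must be >= min_spacing_bp")
    rng = np.random.default_rng(seed)
    excess_mean = mean_spacing_bp - min_spacing_bp
    max_pos = length_bp - 2
    positions: list[int] = []
    pos = 0
    expected_n = max(16, int(2 * length_bp / mean_spacing_bp) + 16)
    while True:
        if excess_mean > 0:
            # geometric on {0,1,...} with mean excess_mean
            p = 1.0 / (1.0 + excess_mean)
            gaps = min_spacing_bp + rng.geometric(p, size=expected_n) - 1
        else:
            gaps = np.full(expected_n, min_spacing_bp, dtype=np.int64)
        for g in gaps:
            pos += int(g)
            if pos > max_pos:
                return CgLandscape(chrom_name, length_bp, np.array(positions, dtype=np.int64))
            positions.append(pos)


def _distributive_calls(n_sites: int, theta: float, rng: np.random.Generator) -> np.ndarray:
    return (rng.random(n_sites) < theta).astype(np.uint8)


def _gap_block_limits(positions: np.ndarray, max_gap_bp: int | None) -> np.ndarray:
    """For each site, the last index reachable without crossing a gap > max_gap_bp."""
    k = positions.size
    if max_gap_bp is None or k == 0:
        return np.full(k, k - 1, dtype=np.int64)
    breaks = np.flatnonzero(np.diff(positions) > max_gap_bp)
    if breaks.size == 0:
        return np.full(k, k - 1, dtype=np.int64)
    idx = np.searchsorted(breaks, np.arange(k))
    return np.where(idx < breaks.size, breaks[np.minimum(idx, breaks.size - 1)], k - 1)


def processive_calls_matrix(
    positions: np.ndarray,
    alpha: float,
    rho: float,
    max_gap_bp: int | None,
    rng: np.random.Generator,
    n_molecules: int = 1,
) -> np.ndarray:
    """Vectorised tract model: (n_molecules, n_sites) binary call matrix.

    A tract initiates independently at each site with probability alpha and
    covers a geometric number of onward sites (P(reach >= g further sites) =
    rho**g), truncated at the first inter-site gap exceeding max_gap_bp.
    Overlapping tracts merge: a site is methylated iff covered by >= 1 tract.
    """
    k = positions.size
    if k == 0:
        return np.zeros((n_molecules, 0), dtype=np.uint8)
    init = rng.random((n_molecules, k)) < alpha
    if rho > 0.0:
        extra = rng.geometric(1.0 - rho, size=(n_molecules, k)).astype(np.int64) - 1
    else:
        extra = np.zeros((n_molecules, k), dtype=np.int64)
    limit = _gap_block_limits(positions, max_gap_bp)
    idx = np.arange(k, dtype=np.int64)
    reach = np.where(init, np.minimum(idx + extra, limit), -1)
    covered = np.maximum.accumulate(reach, axis=1) >= idx
    return covered.astype(np.uint8)


def simulate_distributive(landscape: CgLandscape, theta: float, seed: int = 0,
                          molecule_id: int = 0) -> MethTemplate:
    """Methylate each CG site independently with probability theta."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return MethTemplate(landscape, _distributive_calls(landscape.n_sites, theta, rng), molecule_id)


def simulate_processive(landscape: CgLandscape, alpha: float, rho: float,
                        max_gap_bp: int | None = None, seed: int = 0,
                        molecule_id: int = 0) -> MethTemplate:
    """Methylate CG sites in tracts (see processive_calls_matrix)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    calls = processive_calls_matrix(landscape.cg_positions, alpha, rho, max_gap_bp, rng)[0]
    return MethTemplate(landscape, calls, molecule_id)


def processive_coverage_level(alpha: float, rho: float, tol: float = 1e-12) -> float:
    """Stationary per-site methylation level of the unbounded-gap tract model.

    A site is covered by the tract starting g sites upstream with
    probability alpha * rho**g, independently over g, giving
    level = 1 - prod_{g>=0} (1 - alpha * rho**g).  The product is truncated
    once its factors exceed 1 - tol.
    """
    if alpha == 0.0:
        return 0.0
    log_unmeth = 0.0
    g = 0
    while True:
        factor = 1.0 - alpha * rho**g
        if factor <= 0.0:
            return 1.0
        log_unmeth += math.log(factor)
        if factor > 1.0 - tol or rho == 0.0:
            break
        g += 1
    return 1.0 - math.exp(log_unmeth)


def solve_alpha_for_level(target_level: float, rho: float) -> float:
    """Invert processive_coverage_level in alpha by bisection."""
    if not 0.0 <= target_level < 1.0:
        raise ValueError("target_level must be in [0, 1)")
    if target_level == 0.0:
        return 0.0
    lo, hi = 0.0, 1.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if processive_coverage_level(mid, rho) < target_level:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _simulate_one(landscape: CgLandscape, config: SimConfig, molecule_id: int) -> MethTemplate:
    child = derive_seed(config.seed, molecule_id)
    if config.model == "distributive":
        return simulate_distributive(landscape, config.theta, child, molecule_id)
    return simulate_processive(landscape, config.alpha, config.rho, config.max_gap_bp,
                               child, molecule_id)


def simulate_oocyte_pool(landscape: CgLandscape, config: SimConfig) -> list[MethTemplate]:
    """Independent molecules modelling the cell-to-cell methylation mosaic of a pooled-oocyte sample."""
    return [_simulate_one(landscape, config, i) for i in range(config.n_molecules)]


def sample_reads(pool: Sequence[MethTemplate], config: SimConfig,
                 allele: str = "U") -> list[MethRead]:
    """Sample fixed-length single-end bisulfite reads from a molecule pool.

    The read count is Poisson with mean mean_depth * length_bp /
    read_length_bp (expected per-base depth = mean_depth); each read picks a
    molecule uniformly and a uniform start, copies the covered CG calls and
    flips them with the configured error rates.  Reads covering zero CG
    sites are emitted (k = 0 flags them) so depth bookkeeping stays honest.
    """
    if not pool:
        raise ValueError("empty molecule pool")
    landscape = pool[0].landscape
    for t in pool:
        if t.landscape is not landscape and not np.array_equal(
                t.landscape.cg_positions, landscape.cg_positions):
            raise ValueError("all templates must share one landscape")
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed) & 0xFFFFFFFF, 0x5EAD)))
    length = landscape.length_bp
    rl = min(config.read_length_bp, length)
    n_reads = int(rng.poisson(config.mean_depth * length / rl))
    starts = rng.integers(0, max(length - rl, 0) + 1, size=n_reads)
    mols = rng.integers(0, len(pool), size=n_reads)
    pos = landscape.cg_positions
    reads: list[MethRead] = []
    for i in range(n_reads):
        start = int(starts[i])
        end = start + rl
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end - 1, side="right"))  # CG needs both bases inside
        site_pos = pos[lo:hi]
        calls = pool[int(mols[i])].calls[lo:hi].copy()
        if calls.size:
            flips = rng.random(calls.size)
            over = (calls == 0) & (flips < config.eps_over)
            under = (calls == 1) & (flips < config.eps_under)
            calls[over] = 1
            calls[under] = 0
        reads.append(MethRead(
            read_id=f"sim{i:07d}",
            chrom=landscape.chrom_name,
            start=start,
            end=end,
            cg_positions=site_pos,
            calls=calls,
            allele=allele,
        ))
    return reads


def simulate_imprint_trajectory(config: ImprintSimConfig) -> pd.DataFrame:
    """Stage-resolved per-embryo, per-ICR methylation under anchor protection.

    Oocyte stage: every CG site (anchors included) is methylated
    independently with probability oocyte_level.  Blastocyst stage: in
    embryos where no anchor of an ICR is methylated, each methylated
    non-anchor site is erased with probability
    1 - (1 - erasure_rate)**n_cleavage_divisions; protected ICRs (>= 1
    methylated anchor) lose nothing.  Post-implantation: protected ICRs are
    restored to full methylation, unprotected ones collapse to zero.

    Returns a tidy frame with one row per (embryo, ICR) and columns
    icr, embryo, n_sites, protected, level_oocyte, level_blastocyst,
    level_postimplantation.
    """
    rows = []
    p_erase = 1.0 - (1.0 - config.erasure_rate) ** config.n_cleavage_divisions
    for icr_idx in range(config.n_icrs):
        icr_rng = np.random.default_rng(derive_seed(config.seed, icr_idx))
        lo, hi = config.icr_length_range
        length = int(icr_rng.uniform(lo, hi))
        landscape = generate_cg_landscape(
            max(length, 64), config.mean_cg_spacing_bp, 2,
            seed=derive_seed(config.seed, 100_000 + icr_idx),
            chrom_name=f"ICR{icr_idx:02d}")
        n_sites = max(landscape.n_sites, config.n_anchors)
        anchors = icr_rng.choice(n_sites, size=config.n_anchors, replace=False)
        anchor_mask = np.zeros(n_sites, dtype=bool)
        anchor_mask[anchors] = True

        oocyte = icr_rng.random((config.n_embryos, n_sites)) < config.oocyte_level
        protected = oocyte[:, anchor_mask].any(axis=1)
        erase = icr_rng.random((config.n_embryos, n_sites)) < p_erase
        blast = oocyte & ~(erase & ~anchor_mask[None, :] & ~protected[:, None])
        lvl_oo = oocyte.mean(axis=1)
        lvl_bl = blast.mean(axis=1)
        lvl_post = protected.astype(float)
        for e in range(config.n_embryos):
            rows.append({
                "icr": f"ICR{icr_idx:02d}",
                "embryo": f"embryo{e:04d}",
                "n_sites": n_sites,
                "protected": bool(protected[e]),
                "level_oocyte": float(lvl_oo[e]),
                "level_blastocyst": float(lvl_bl[e]),
                "level_postimplantation": float(lvl_post[e]),
            })
    return pd.DataFrame(rows)
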