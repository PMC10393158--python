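#!/usr/bin/env python
"""Simulate the two study-like conditions and write their read sets.

Generates one CG landscape, then two mosaic oocyte pools sampled to
bisulfite reads: a "wildtype-like" pool in which methylation is laid down
processively (tracts, rho = 0.8) and a "mutant-like" pool methylated
distributively at the same stationary level.  Writes per-read TSVs,
Bismark-style site coverage and a BED of ICR-like regions under
results/sim/.
"""

import argparse
from pathlib import Path

from methstretch.io import write_bed, write_bismark_cov
from methstretch.pipeline import default_regions
from methstretch.regions import aggregate_site_counts
from methstretch.simulate import (
    SimConfig,
    generate_cg_landscape,
    sample_reads,
    simulate_oocyte_pool,
    solve_alpha_for_level,
)
from methstretch.readstats import write_read_calls

TARGET_LEVEL = 0.48
RHO_WT = 0.8


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--length-bp", type=int, default=100_000)
    parser.add_argument("--outdir", type=Path, default=Path("results/sim"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    landscape = generate_cg_landscape(args.length_bp, 10.0, seed=args.seed)
    print(f"landscape: {landscape.n_sites} CG sites over {args.length_bp} bp")

    alpha = solve_alpha_for_level(TARGET_LEVEL, RHO_WT)
    conditions = {
        "wildtype_like": SimConfig(model="processive", alpha=alpha, rho=RHO_WT,
                                   n_molecules=200, mean_depth=30.0, seed=args.seed),
        "mutant_like": SimConfig(model="distributive", theta=TARGET_LEVEL,
                                 n_molecules=200, mean_depth=30.0, seed=args.seed + 1),
    }
    for name, cfg in conditions.items():
        pool = simulate_oocyte_pool(landscape, cfg)
        reads = sample_reads(pool, cfg)
        write_read_calls(reads, args.outdir / f"{name}.reads.tsv")
        sites = aggregate_site_counts(reads)
        write_bismark_cov(sites, args.outdir / f"{name}.cov")
        level = sites["n_meth"].sum() / (sites["n_meth"] + sites["n_unmeth"]).sum()
        print(f"{name}: {len(reads)} reads, site-level methylation {level:.3f} "
              f"(target {TARGET_LEVEL})")

    write_bed(default_regions(landscape), args.outdir / "icr_like_regions.bed")
    print(f"wrote read sets, coverage and regions to {args.outdir}")


if __name__ == "__main__":
    main()
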