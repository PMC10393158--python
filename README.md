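# methstretch

Read-level analysis of DNA methylation processivity from whole-genome
bisulfite sequencing (WGBS), with an exact combinatorial null model, and
a simulator of stochastic imprint loss and regain in early embryos.

## The problem

De novo DNA methyltransferases can act *distributively* (each CpG site is
an independent event) or *processively* (one chromatin engagement
methylates a tract of consecutive CpGs). Bulk methylation levels cannot
distinguish the two, but single WGBS reads can: a read reports the
methylation state of every CpG it covers on **one** DNA molecule. If
methylation arrives in tracts, methylated CpGs cluster within reads; the
natural statistic is the **longest stretch of consecutively methylated
CpGs per read**.

The catch is that longer stretches also arise trivially from higher
methylation. `methstretch` removes this confound by conditioning on read
*composition*: reads with exactly `k` CpG sites of which `m` are
methylated. Under independent methylation, all `C(k, m)` arrangements of
the `m` methylated sites are equally likely, so the null distribution of
the longest run `L` is exact combinatorics:

```
P(L <= l) = N(k, m, l) / C(k, m)
```

where `N(k, m, l)` counts binary strings of length `k` with `m` ones and
no run of ones longer than `l`, computed by inclusion–exclusion over the
`k − m + 1` slots between zeros (exact integer arithmetic; cross-checked
against exhaustive enumeration). Departure of the observed per-stratum
run distribution from this null is measured by the Kullback–Leibler
divergence `D(obs ‖ null) = Σ_l p_l log2(p_l / q_l)` (bits) and by the
mean longest run.

The package also covers the downstream, region-level side of the same
biology: coverage-filtered site pileups, 10-kb bin and ICR (imprinting
control region) methylation levels, allele splitting, all-or-none state
calls flagging stochastic imprint loss, and a stage-resolved simulator in
which partially methylated ICRs leave the oocyte, lose unprotected
methylation during cleavage, and collapse to full-or-no methylation after
implantation depending on anchor sites (a ZFP57-like protection proxy).

A synthetic-data module generates everything needed to exercise the
analysis without sequencing data: CpG landscapes, single-molecule
methylation under either mechanism, mosaic oocyte pools, ~100-nt
bisulfite reads with conversion error, and imprint trajectories.

## Worked example

```python
from methstretch import (SimConfig, generate_cg_landscape, simulate_oocyte_pool,
                         sample_reads, filter_reads_min_cg, stratify_by_composition,
                         strata_from_ratio_window, compare_to_null, per_read_level)

land = generate_cg_landscape(100_000, mean_spacing_bp=10.0, seed=1)
cfg = SimConfig(model="processive", alpha=0.117, rho=0.8,
                n_molecules=200, mean_depth=30.0, seed=1)
reads = sample_reads(simulate_oocyte_pool(land, cfg), cfg)
kept = filter_reads_min_cg(reads, 4)            # keep reads with > 4 CpGs
groups, _ = stratify_by_composition(kept, strata_from_ratio_window())
print(compare_to_null(groups).pooled_kl_bits)
```

Running the numbered drivers in `analysis/` on this configuration prints

```
wildtype_like: 30157 reads, site-level methylation 0.479 (target 0.48)
mutant_like:   30190 reads, site-level methylation 0.483 (target 0.48)
wildtype_like: pooled KL 2.6847 bits over 15 populated strata; rho_hat = 0.75
mutant_like:   pooled KL 0.0051 bits over 15 populated strata; rho_hat = 0.00
```

Both conditions have the same bulk methylation (~48%), but the tract-laid
("wildtype-like") reads diverge strongly from the independence null —
their methylated CpGs sit in long stretches — while the distributive
("mutant-like") reads are statistically indistinguishable from it. The
grid-search estimator recovers the tract-extension probability used in
the simulation (0.8) to within one grid step from reads alone. A read's
level itself is reported as `100·m/k` rounded half-even to one decimal,
e.g. `per_read_level` gives 41.7% for (k=12, m=5) and 54.5% for
(k=11, m=6) — the bounds of the default stratification window.

The imprint driver (`analysis/05_imprint_dynamics.py`) prints the
stage-wise state fractions, e.g. at oocyte level 0.5 with one anchor:
partial states 1.00 → 0.80 → 0.00 across oocyte → blastocyst →
post-implantation, with 0.51 of ICRs ending fully methylated (closed
form: 1 − 0.5¹ = 0.5).

## Command line

`methstretch` exposes subcommands `simulate`, `readstats`, `nulldist`,
`compare`, `regions`, `imprint-sim` and `run` (end-to-end experiment with
a YAML config); every simulation subcommand requires `--seed`.

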