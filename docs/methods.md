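# Methods

## The longest-run statistic and its exact null

A WGBS read covering `k` CpG sites with binary calls `x_1..x_k` has
composition `(k, m)` with `m = Σ x_i`, methylation level `100·m/k`
(rounded half-even to one decimal, so 5/12 → 41.7 and 6/11 → 54.5), and
longest methylated run `L = max` block of consecutive ones. Conditioning
on `(k, m)` is what makes `L` informative about mechanism rather than
about level: under mutually independent methylation all `C(k, m)`
arrangements are equally likely regardless of the per-site rate, so the
null law of `L` depends on `(k, m)` only.

`N(k, m, l)`, the number of arrangements with no run longer than `l`, is
computed by distributing the `m` ones into the `r = k − m + 1` slots
between and around the `k − m` zeros with at most `l` per slot:

    N(k, m, l) = Σ_j (−1)^j C(r, j) C(m − j(l+1) + r − 1, r − 1)

in exact integer arithmetic; the pmf is the difference sequence divided
by `C(k, m)`, kept as `fractions.Fraction` until the caller wants floats.
Useful closed forms, used as test oracles: `N(k, m, m) = C(k, m)`,
`N(k, m, 1) = C(k − m + 1, m)`, and `P(L = m) = (k − m + 1)/C(k, m)`.
The feasible support is `[⌈m/(k − m + 1)⌉, m]` (pigeonhole). A seeded
permutation null (shuffling calls within the read) is provided as a
Monte-Carlo cross-check; the analytic form is the default because it is
deterministic and exactly testable.

Divergence is reported as `D(obs ‖ null)` in **bits** (the direction is
observed-from-expected; the log base is a convention and is labelled in
every output). Empirical pmfs are not smoothed: the exact null is
strictly positive on the whole feasible support, so the divergence is
finite whenever the data are consistent with the composition. Observed
mass outside the feasible support raises an explicit error rather than
returning infinity. Per-stratum divergences are pooled by read-count
weighting. Strata with fewer than 50 reads (configurable) are reported
but flagged low-confidence.

The default strata are all `(k, m)` with `5 ≤ k ≤ 15` whose ratio lies in
the closed window `[5/12, 6/11]` — the window is configurable because the
exact list used in any given study is an analysis choice, while the
bounds are the two worked-example compositions above.

## The two methylation mechanisms in the simulator

*Distributive*: each CpG methylated independently with probability
`theta`.

*Processive*: at each CpG a tract initiates independently with
probability `alpha`; a tract starting at site `i` covers `i` and then
each next site with continuation probability `rho` (geometric length),
stopping early if the next CpG is more than `max_gap_bp` away (unbounded
by default). Overlapping tracts merge (site-level OR). The biology
motivating this is an enzyme tethered to chromatin acting on
consecutive CpGs per engagement; the geometric-tract parameterisation is
our choice because it has a single interpretable extension parameter and
a closed-form stationary level,

    level(alpha, rho) = 1 − Π_{g≥0} (1 − alpha·rho^g),

(truncated when factors exceed 1 − 1e−12) which the tests validate
against a brute-force tract simulator. `rho = 0` reduces exactly to the
distributive model with `theta = alpha`; `rho = 1` is rejected
(non-terminating tracts). When the two scenario presets are compared,
`alpha` is solved by bisection so both mechanisms have the same
stationary level (default 0.48, chosen so the default stratification
window is well populated) — the contrast then isolates mechanism from
level.

## Landscapes, pools, reads

CpG positions come from a renewal process: gap = `min_spacing_bp` (≥ 2,
because CG dinucleotides cannot overlap) plus a geometric excess with the
mean set by `mean_spacing_bp`. The default 10-bp mean spacing emulates a
CpG-island-like density, appropriate for ICR-focused read analysis; it is
not a genome-wide average.

A pool is `n_molecules` independent molecules (default 200, the scale of
a pooled-oocyte WGBS library), each simulated from a child seed hashed
from `(master_seed, molecule_id)` via `numpy.random.SeedSequence`, so
pools are reproducible and any molecule can be regenerated alone. Reads
are single-end and fixed-length (default 100 bp, matching ~100-nt WGBS
reads), with Poisson total count at the target mean per-base depth
(default 30×), uniform starts, uniformly chosen source molecule, and
per-site call flips `0→1` with `eps_over` (default 0.003, the scale of
bisulfite conversion failure) and `1→0` with `eps_under` (default 0).
Reads covering no CpG are emitted with `k = 0` and flagged so depth
accounting stays consistent. What this generator does *not* emulate:
sequence context, mappability, strand asymmetries, PCR duplicates and
coverage biases of real libraries — passing tests show the statistics are
computed correctly, not that real data are this clean.

## Conditional (fixed-composition) sampling and rho recovery

`simulate_stratum_runs` draws longest-run samples under the tract model
*conditioned on* `(k, m)`: `k` evenly spaced sites, `alpha` solved so the
stationary level equals `m/k`, and rejection on molecules with exactly
`m` methylated sites. This is exact conditioning and, at `rho = 0`,
provably reproduces the analytic null (uniform arrangements).

`estimate_rho` grid-searches `rho`, scoring each candidate by the
read-count-weighted KL of the observed per-stratum pmfs from reference
pmfs simulated at that candidate. Because the references are Monte-Carlo
estimates, a 0.5 pseudocount over the feasible support is added to the
*reference only* (observed pmfs are never smoothed) to keep scores finite
where the reference undersamples rare lengths; reported divergences from
the analytic null are unaffected. Ties break toward smaller `rho`. A
likelihood approach was rejected because the run-length law of the tract
model conditional on `(k, m)` has no convenient closed form.

## Site, bin and region summaries

Aggregation pools calls per `(chrom, position, context, allele)`;
untagged reads enter the combined pileup only. Coordinates are 0-based
half-open internally; Bismark-style coverage files are written 1-based
inclusive; regions travel as BED with the class label in the name field
(`name|class`). Coverage windows default to 4–100 reads (combined) and
1–100 (allele-split, where selected reads are scarcer). Bins tile each
chromosome from 0 in fixed 10-kb windows, excluded when they hold fewer
than five informative sites (CpG and non-CpG pooled — the filter is a
data-quantity rule, not a context rule); the final partial bin is kept if
it passes. Levels are read-weighted (summed methylated calls over summed
calls), the common WGBS convention; a site-averaged mode exists for
sensitivity checks. Regions require more than 10 cumulative CG calls
(summed coverage with multiplicity — our reading of a redundant-count
threshold) or they are reported `no_data`.

ICR states: `full` at level ≥ 0.75, `lost` at ≤ 0.25, `partial` between.
The thresholds operationalise "almost fully methylated / almost fully
unmethylated"; they are configurable and echoed in outputs. The
`stochastic_loss` flag marks maternal-ICR calls that are lost or partial
on the maternal allele (or on combined data, which is correct for
uniparental samples such as parthenogenetic embryos).

## Imprint trajectory model

Per ICR: length uniform on 0.7–6.7 kb (the maternal-ICR size range; 25-bp
mean CpG spacing, CpG-island-like), with `n_anchors` protector sites
(default 1). Per embryo: oocyte stage methylates every site independently
at `oocyte_level`; the ICR is *protected* iff ≥ 1 anchor is methylated.
Blastocyst stage: in unprotected ICRs each methylated non-anchor site is
erased with probability `1 − (1 − erasure_rate)^n_divisions` (defaults
0.15 and 4 — a passive-dilution proxy over cleavage divisions producing
clearly intermediate blastocyst levels); protected ICRs lose nothing.
Post-implantation: protected → 1.0, unprotected → 0.0. The closed form
`P(full) = 1 − (1 − oocyte_level)^n_anchors` is the main test oracle.
This is a minimal two-step model — loss initiating before implantation,
regain after — not a mechanistic account of demethylation kinetics.

## Determinism and numerics

Every simulator is a pure function of its config including the seed.
Pipeline outputs use fixed column orders and number formats (percent one
decimal, KL and levels four decimals) so reruns are byte-identical.
Percent rounding is half-even to avoid platform-dependent half-up.
Degenerate inputs: empty call vectors have longest run 0; `m = 0`
strata are a point mass at 0; `k = 0` reads carry an undefined (NaN)
level but are retained.

## Problem sizes

The test suite and the drivers run on a 100-kb landscape at 10-bp CpG
spacing (~10⁴ sites), 200 molecules, 30× depth (~3×10⁴ reads), 5000
conditioned reads per stratum for null-consistency checks, 20 paired
seed replicates for the mechanism contrast, 20 000 reads for rho
recovery, and 2000 embryos × 2 ICRs for the imprint closed-form check.
These sizes give Monte-Carlo error comfortably inside every asserted
tolerance while keeping a full run in tens of seconds.

## Known limitations

- The tract model is one of several mechanisms compatible with
  "clustered methylation"; `rho` is a simulator parameter, not an
  enzymological rate.
- Strand collapse is assumed done upstream (the simulator emits collapsed
  plus-strand positions); importers of real data must collapse first.
- No SNP calling, no alignment, no FASTQ/BAM input: per-read methylation
  calls arrive via the TSV dialect, site counts via coverage files.
- KL divergences carry no p-values; they are descriptive, and their
  sampling variability at small stratum sizes is only flagged
  (`flag_low_n`), not corrected.
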