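"""Site pileups, coverage/bin filters, region levels, allele splitting, ICR states."""

import numpy as np
import pandas as pd
import pytest

from methstretch.io import (
    BedFormatError,
    read_bed,
    read_bismark_cov,
    write_bed,
    write_bismark_cov,
)
from methstretch.regions import (
    Region,
    aggregate_site_counts,
    bin_methylation,
    classify_icr_state,
    filter_sites_by_coverage,
    global_methylation,
    region_methylation,
    split_by_allele,
)
from methstretch.simulate import (
    ImprintSimConfig,
    SimConfig,
    sample_reads,
    simulate_imprint_trajectory,
    simulate_oocyte_pool,
)

from conftest import make_read


def site_table(rows):
    """rows: (chrom, pos, context, allele, n_meth, n_unmeth)"""
    return pd.DataFrame(rows, columns=["chrom", "pos", "context", "allele",
                                       "n_meth", "n_unmeth"])


class TestAggregate:
    def test_three_reads_one_site(self):
        reads = [make_read([1]), make_read([1]), make_read([0])]
        sites = aggregate_site_counts(reads)
        assert len(sites) == 1
        assert sites.loc[0, "n_meth"] == 2 and sites.loc[0, "n_unmeth"] == 1

    def test_by_allele_with_untagged_reads(self):
        reads = [make_read([1], allele="U"), make_read([0], allele="U")]
        sites = aggregate_site_counts(reads, by_allele=True)
        assert set(sites["allele"]) == {"combined"}

    def test_allele_split_counts(self):
        reads = [make_read([1], allele="M"), make_read([0], allele="P"),
                 make_read([1], allele="U")]
        sites = aggregate_site_counts(reads, by_allele=True)
        comb = sites[sites["allele"] == "combined"]
        assert int(comb["n_meth"].sum()) == 2 and int(comb["n_unmeth"].sum()) == 1
        mat = sites[sites["allele"] == "maternal"]
        assert int(mat["n_meth"].sum()) == 1 and int(mat["n_unmeth"].sum()) == 0

    def test_call_conservation(self, small_landscape):
        cfg = SimConfig(model="distributive", theta=0.5, n_molecules=5,
                        mean_depth=4, seed=31)
        reads = sample_reads(simulate_oocyte_pool(small_landscape, cfg), cfg)
        sites = aggregate_site_counts(reads)
        total_calls = sum(r.calls.size for r in reads)
        assert int((sites["n_meth"] + sites["n_unmeth"]).sum()) == total_calls

    def test_non_cg_context_kept_separate(self):
        read = make_read([1, 0], contexts=np.array(["C", "N"]))
        sites = aggregate_site_counts([read])
        assert set(sites["context"]) == {"CG", "non-CG"}


class TestCoverageFilter:
    def test_hand_enumerated_survivors(self):
        sites = site_table([("c", p, "CG", "combined", cov, 0)
                            for p, cov in zip(range(0, 60, 10), [0, 3, 4, 50, 100, 101])])
        out = filter_sites_by_coverage(sites, 4, 100)
        assert (out["n_meth"].tolist()) == [4, 50, 100]

    def test_allelic_defaults_keep_singletons(self):
        sites = site_table([("c", 0, "CG", "maternal", 1, 0)])
        assert len(filter_sites_by_coverage(sites, 1, 100)) == 1

    def test_idempotent(self):
        sites = site_table([("c", p, "CG", "combined", c, c)
                            for p, c in zip(range(0, 50, 10), [1, 2, 3, 40, 60])])
        once = filter_sites_by_coverage(sites, 4, 100)
        twice = filter_sites_by_coverage(once, 4, 100)
        assert once.equals(twice)

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            filter_sites_by_coverage(site_table([]), 0, 10)


class TestBins:
    def test_sparse_bin_excluded(self):
        sites = site_table([("c", p, "CG", "combined", 3, 3) for p in (0, 10, 20, 30)])
        assert bin_methylation(sites, 10_000, 5).empty

    def test_weighted_level(self):
        sites = site_table([("c", 0, "CG", "combined", 10, 0),
                            ("c", 10, "CG", "combined", 0, 10),
                            ("c", 20, "CG", "combined", 5, 5),
                            ("c", 30, "CG", "combined", 5, 5),
                            ("c", 40, "CG", "combined", 5, 5)])
        bins = bin_methylation(sites, 10_000, 5)
        assert len(bins) == 1
        assert bins.loc[0, "level"] == pytest.approx(0.5)

    def test_informative_count_pools_contexts(self):
        rows = [("c", p, "CG", "combined", 2, 2) for p in (0, 10, 20)]
        rows += [("c", p, "non-CG", "combined", 0, 4) for p in (30, 40)]
        bins = bin_methylation(site_table(rows), 10_000, 5)
        assert set(bins["context"]) == {"CG", "non-CG"}  # 5 informative sites total

    def test_global_level(self):
        sites = site_table([("c", 0, "CG", "combined", 30, 70)])
        assert global_methylation(sites)["CG"] == pytest.approx(0.3)


class TestRegionMethylation:
    def test_cumulative_call_threshold(self):
        reg = [Region("c", 0, 100, "icr", "maternal_ICR")]
        at10 = site_table([("c", 10, "CG", "combined", 5, 5)])
        out = region_methylation(at10, reg, 10)
        assert out.loc[0, "status"] == "no_data"
        at11 = site_table([("c", 10, "CG", "combined", 6, 5)])
        out = region_methylation(at11, reg, 10)
        assert out.loc[0, "status"] == "ok"
        assert out.loc[0, "level"] == pytest.approx(6 / 11)

    def test_region_without_sites_is_no_data(self):
        reg = [Region("c", 1000, 2000, "empty", "CpG_island")]
        sites = site_table([("c", 10, "CG", "combined", 20, 0)])
        out = region_methylation(sites, reg)
        assert out.loc[0, "status"] == "no_data"

    def test_fully_methylated_region(self):
        reg = [Region("c", 0, 100, "full", "maternal_ICR")]
        sites = site_table([("c", p, "CG", "combined", 6, 0) for p in (10, 20)])
        out = region_methylation(sites, reg)
        assert out.loc[0, "level"] == 1.0

    def test_level_is_coverage_weighted_mean_of_site_levels(self):
        sites = site_table([("c", 10, "CG", "combined", 9, 1),
                            ("c", 20, "CG", "combined", 1, 9)])
        reg = [Region("c", 0, 100, "r", "other")]
        out = region_methylation(sites, reg)
        # read-weighted: (9+1)/(10+10); site-averaged: mean(0.9, 0.1) = 0.5 too,
        # so distinguish with unequal coverage
        sites2 = site_table([("c", 10, "CG", "combined", 9, 1),
                             ("c", 20, "CG", "combined", 1, 19)])
        w = region_methylation(sites2, reg).loc[0, "level"]
        assert w == pytest.approx(10 / 30)
        s = region_methylation(sites2, reg, site_averaged=True).loc[0, "level"]
        assert s == pytest.approx((0.9 + 0.05) / 2)


class TestAlleleSplit:
    def test_counts(self):
        reads = ([make_read([1], allele="M")] * 5 + [make_read([1], allele="P")] * 3
                 + [make_read([1], allele="U")] * 2)
        mat, pat, untagged = split_by_allele(reads)
        assert (len(mat), len(pat), untagged) == (5, 3, 2)

    def test_all_untagged(self):
        mat, pat, untagged = split_by_allele([make_read([1])])
        assert mat == [] and pat == [] and untagged == 1

    def test_maternal_only_methylation(self):
        reads = [make_read([1, 1, 1], allele="M", read_id=f"m{i}") for i in range(20)]
        reads += [make_read([0, 0, 0], allele="P", read_id=f"p{i}") for i in range(20)]
        sites = aggregate_site_counts(reads, by_allele=True)
        reg = [Region("chrSim", 0, 100, "icr", "maternal_ICR")]
        out = region_methylation(sites, reg)
        by_allele = out.set_index("allele")["level"]
        assert by_allele["maternal"] == 1.0 and by_allele["paternal"] == 0.0


class TestClassifyIcrState:
    def _frame(self, levels):
        return pd.DataFrame({
            "region": [f"r{i}" for i in range(len(levels))],
            "region_class": "maternal_ICR",
            "allele": "maternal",
            "level": levels,
            "n_informative_cg": 10,
            "cumulative_calls": 100,
            "status": "ok",
        })

    def test_threshold_states(self):
        out = classify_icr_state(self._frame([1.0, 0.0, 0.5, 0.75, 0.25]))
        assert out["state"].tolist() == ["full", "lost", "partial", "full", "lost"]

    def test_stochastic_loss_flag(self):
        out = classify_icr_state(self._frame([0.1, 0.9]))
        assert out["stochastic_loss"].tolist() == [True, False]

    def test_misordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_icr_state(self._frame([0.5]), full_min=0.2, lost_max=0.3)

    def test_imprint_simulator_post_implantation_all_or_none(self):
        cfg = ImprintSimConfig(n_icrs=4, n_embryos=50, oocyte_level=0.5, seed=6)
        traj = simulate_imprint_trajectory(cfg)
        frame = pd.DataFrame({
            "region": traj["icr"], "region_class": "maternal_ICR",
            "allele": "combined", "level": traj["level_postimplantation"],
            "n_informative_cg": traj["n_sites"], "cumulative_calls": 100,
            "status": "ok"})
        out = classify_icr_state(frame)
        assert set(out["state"]) <= {"full", "lost"}

    def test_imprint_simulator_blastocyst_has_partial_states(self):
        cfg = ImprintSimConfig(n_icrs=6, n_embryos=50, oocyte_level=0.5, seed=7)
        traj = simulate_imprint_trajectory(cfg)
        frame = pd.DataFrame({
            "region": traj["icr"], "region_class": "maternal_ICR",
            "allele": "combined", "level": traj["level_blastocyst"],
            "n_informative_cg": traj["n_sites"], "cumulative_calls": 100,
            "status": "ok"})
        out = classify_icr_state(frame)
        assert (out["state"] == "partial").any()


class TestFileFormats:
    def test_bismark_round_trip(self, tmp_path):
        sites = site_table([("chr1", 99, "CG", "combined", 7, 3),
                            ("chr1", 199, "CG", "combined", 0, 5)])
        path = tmp_path / "sites.cov"
        write_bismark_cov(sites, path)
        back = read_bismark_cov(path)
        assert back["pos"].tolist() == [99, 199]
        assert back["n_meth"].tolist() == [7, 0]
        # 1-based inclusive on disk
        first = path.read_text().splitlines()[0].split("\t")
        assert first[1] == "100" and first[2] == "100"

    def test_bed_round_trip(self, tmp_path):
        regions = [Region("chr1", 0, 500, "icrA", "maternal_ICR"),
                   Region("chr2", 100, 900, "plain", "other")]
        path = tmp_path / "regions.bed"
        write_bed(regions, path)
        assert read_bed(path) == regions

    def test_malformed_bed_names_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t500\tok\t0\t+\nchr1\tx\t500\tbad\t0\t+\n")
        with pytest.raises(BedFormatError, match="line 2"):
            read_bed(path)
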