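"""Generator contracts: implant geometry, count model, FISH and single cells."""

import numpy as np
import pandas as pd
import pytest

from asrt import GenomeSpec, SimParams
from asrt.genome import default_genome
from asrt.simulate import (
    rt_to_s_copy,
    simulate_counts,
    simulate_fish,
    simulate_fish_orientation,
    simulate_fish_pairwise,
    simulate_rt_landscape,
    simulate_single_cells,
    simulate_snp_catalog,
    simulate_tagged_reads,
)


class TestLandscape:
    def test_zero_effect_gives_identical_allele_tracks(self, small_genome):
        params = SimParams(seed=0, as_effect=0.0, n_genetic_regions=0,
                          n_deletions=0)
        truth = simulate_rt_landscape(small_genome, params)
        assert np.array_equal(truth.clone_rt[:, :, 0], truth.clone_rt[:, :, 1])

    def test_requested_number_of_disjoint_grid_regions(self, small_genome):
        params = SimParams(seed=1, n_as_regions=5, as_region_length=10,
                          n_genetic_regions=0, n_deletions=0)
        truth = simulate_rt_landscape(small_genome, params)
        reg = truth.as_regions
        assert len(reg) == 5
        w = small_genome.window_size
        assert ((reg["end"] - reg["start"]) == 10 * w).all()
        assert (reg["start"] % w == 0).all()
        for chrom, sub in reg.groupby("chrom"):
            iv = sorted(zip(sub["start"], sub["end"]))
            assert all(a[1] <= b[0] for a, b in zip(iv, iv[1:]))

    def test_implanted_delta_equals_effect(self, truth, default_params):
        """Inside every AS region the early-late RT gap is exactly as_effect."""
        for c in range(default_params.n_clones):
            mask = truth.region_window_mask(truth.as_regions)
            delta = np.abs(truth.clone_rt[c, mask, 0] - truth.clone_rt[c, mask, 1])
            assert np.allclose(delta, default_params.as_effect)

    def test_alleles_identical_outside_implants(self, truth):
        outside = ~(truth.region_window_mask(truth.as_regions)
                    | truth.region_window_mask(truth.genetic_regions))
        d = truth.clone_rt[:, outside, 0] - truth.clone_rt[:, outside, 1]
        assert np.allclose(d, 0.0)

    def test_rt_bounded(self, truth):
        assert truth.clone_rt.min() >= -2.0 and truth.clone_rt.max() <= 2.0

    def test_genetic_direction_shared_by_clones_and_pure_strains(self, truth):
        mask = truth.region_window_mask(truth.genetic_regions)
        d_pure = truth.pure_rt[mask, 0] - truth.pure_rt[mask, 1]
        for c in range(truth.clone_rt.shape[0]):
            d_clone = truth.clone_rt[c, mask, 0] - truth.clone_rt[c, mask, 1]
            assert np.array_equal(np.sign(d_clone), np.sign(d_pure))

    def test_shared_orientation_option(self, small_genome):
        params = SimParams(seed=2, shared_orientation=True, n_clones=4)
        truth = simulate_rt_landscape(small_genome, params)
        assert (truth.as_orientations == truth.as_orientations[:, :1]).all()

    def test_infeasible_region_count_raises(self):
        tiny = GenomeSpec({"chr1": 2_000_000})
        with pytest.raises(ValueError, match="cannot place|could not place"):
            simulate_rt_landscape(tiny, SimParams(seed=0, n_as_regions=10))

    def test_determinism_bit_identical(self, small_genome, default_params):
        t1 = simulate_rt_landscape(small_genome, default_params)
        t2 = simulate_rt_landscape(small_genome, default_params)
        assert np.array_equal(t1.clone_rt, t2.clone_rt)
        pd.testing.assert_frame_equal(t1.as_regions, t2.as_regions)
        c1 = simulate_counts(t1)
        c2 = simulate_counts(t2)
        for k in c1:
            pd.testing.assert_frame_equal(c1[k], c2[k])


class TestCounts:
    def test_poisson_mean_matches_depth(self):
        """Null-genome G1 counts average the configured depth (moment check)."""
        spec = default_genome(1, 10_000)
        params = SimParams(seed=3, n_as_regions=0, n_genetic_regions=0,
                          n_deletions=0, n_clones=1, n_replicates=1,
                          mean_g1_depth=100.0)
        truth = simulate_rt_landscape(spec, params)
        track = simulate_counts(truth)[0]
        g1 = track[(track["fraction"] == "G1")
                   & (track["allele"] == "B6")]["count"].to_numpy()
        n = len(g1)
        assert n == 10_000
        assert abs(g1.mean() - 100.0) < 3 * np.sqrt(100.0) / np.sqrt(n)

    def test_full_deletion_zeroes_affected_allele(self, small_genome):
        params = SimParams(seed=4, n_as_regions=0, n_genetic_regions=0,
                          n_deletions=1, deletion_depth_ratio=0.0, n_clones=1)
        truth = simulate_rt_landscape(small_genome, params)
        track = simulate_counts(truth)[0]
        d = truth.deletions.iloc[0]
        sub = track[(track["chrom"] == d["chrom"])
                    & (track["start"] >= d["start"]) & (track["start"] < d["end"])
                    & (track["allele"] == d["strain"])]
        assert (sub["count"] == 0).all()

    def test_equal_rt_zero_noise_gives_symmetric_expectations(self, small_genome):
        """With identical allele RT and no noise the allele S/G1 ratios match
        in expectation; check via large-sample means."""
        params = SimParams(seed=5, n_as_regions=0, n_genetic_regions=0,
                          n_deletions=0, rt_noise_sd=0.0, n_clones=1)
        truth = simulate_rt_landscape(small_genome, params)
        track = simulate_counts(truth)[0]
        means = track.groupby(["allele", "fraction"])["count"].mean()
        for frac in ("S", "G1"):
            a, b = means["B6", frac], means["Cast", frac]
            assert abs(a - b) / a < 0.02

    def test_rt_to_s_copy_monotone_and_bounded(self):
        rt = np.linspace(-3, 3, 101)
        g = rt_to_s_copy(rt)
        assert g.min() >= 1.0 and g.max() <= 2.0
        assert (np.diff(g) >= 0).all()
        assert rt_to_s_copy(np.array(-2.0)) == 1.0
        assert rt_to_s_copy(np.array(2.0)) == 2.0

    def test_read_conservation(self, truth, clone_counts):
        """Total simulated reads equal the sum over windows x samples."""
        track = clone_counts[0]
        total = track["count"].sum()
        by_sample = track.groupby(["allele", "replicate", "fraction"])["count"].sum()
        assert by_sample.sum() == total


class TestFish:
    def test_synchronous_probe_matches_background_rate(self, small_genome):
        params = SimParams(seed=6, n_as_regions=0, n_genetic_regions=0,
                          n_deletions=0)
        truth = simulate_rt_landscape(small_genome, params)
        probe = [("chr1", 0, 1_000_000)]
        f = simulate_fish(truth, params, probe, n_nuclei=20_000)
        rate = f["n_sd"].iloc[0] / 20_000
        # binomial 99.9% band around the background rate
        se = np.sqrt(0.15 * 0.85 / 20_000)
        assert abs(rate - 0.15) < 3.3 * se

    def test_as_probe_rate_within_binomial_ci(self, small_genome):
        """|dRT| = 1 probe: SD rate 0.15 + 0.35 = 0.50 at large n."""
        params = SimParams(seed=7, n_as_regions=2, n_genetic_regions=0,
                          n_deletions=0, as_effect=1.0, n_clones=1)
        truth = simulate_rt_landscape(small_genome, params)
        r = truth.as_regions.iloc[0]
        f = simulate_fish(truth, params,
                          [(r["chrom"], int(r["start"]), int(r["end"]))],
                          n_nuclei=10_000)
        rate = f["n_sd"].iloc[0] / 10_000
        se = np.sqrt(0.5 * 0.5 / 10_000)
        assert abs(rate - 0.50) < 2.58 * se

    def test_parallel_truth_zero_flip_gives_no_antiparallel(self, small_genome):
        params = SimParams(seed=8, n_as_regions=6, n_genetic_regions=0,
                          n_deletions=0, fish_pair_flip_rate=0.0,
                          shared_orientation=True, n_clones=1)
        truth = simulate_rt_landscape(small_genome, params)
        reg = truth.as_regions
        same = [i for i in range(len(reg))
                if truth.as_orientations[i, 0] == truth.as_orientations[0, 0]]
        a, b = same[0], same[1]
        pair = [((reg.iloc[a]["chrom"], int(reg.iloc[a]["start"]), int(reg.iloc[a]["end"])),
                 (reg.iloc[b]["chrom"], int(reg.iloc[b]["start"]), int(reg.iloc[b]["end"])))]
        f = simulate_fish_pairwise(truth, pair, params, n_nuclei=500)
        assert f["n_antiparallel"].iloc[0] == 0
        assert f["true_relation"].iloc[0] == "parallel"

    def test_probe_outside_genome_raises(self, truth, default_params):
        with pytest.raises(ValueError, match="outside|not in genome"):
            simulate_fish(truth, default_params, [("chr1", -5, 100)])
        with pytest.raises(ValueError, match="not in genome"):
            simulate_fish(truth, default_params, [("chr99", 0, 100_000)])

    def test_orientation_pool_near_half(self, truth, default_params):
        reg = truth.as_regions.iloc[0]
        probes = [(reg["chrom"], int(reg["start"]), int(reg["end"]))]
        f = simulate_fish_orientation(truth, probes, default_params,
                                      n_nuclei=10_000, population="pool")
        assert abs(f["k_paternal_early"].iloc[0] / 10_000 - 0.5) < 0.02


class TestSingleCells:
    def test_threshold_below_all_rt_replicates_everything(self, small_genome):
        params = SimParams(seed=9, n_as_regions=0, n_genetic_regions=0,
                          n_deletions=0, sc_noise_sd=0.0, sc_missing_rate=0.0,
                          sc_mid_s_range=(0.999, 1.0), landscape_sd=0.4)
        truth = simulate_rt_landscape(small_genome, params)
        assert truth.clone_rt.min() > -1.99
        m = simulate_single_cells(truth, 5, params)
        # end-of-S cells: threshold ~ -2, below every RT value
        assert np.nanmin(m.states) == 1.0

    def test_synchronous_bins_noise_free_never_one_allele(self, small_genome):
        params = SimParams(seed=10, n_as_regions=0, n_genetic_regions=0,
                          n_deletions=0, sc_noise_sd=0.0, sc_missing_rate=0.0)
        truth = simulate_rt_landscape(small_genome, params)
        m = simulate_single_cells(truth, 20, params)
        one = np.nansum(m.states, axis=2) == 1
        assert not one.any()

    def test_bad_inputs_raise(self, truth, default_params):
        with pytest.raises(ValueError, match="n_cells"):
            simulate_single_cells(truth, 0, default_params)
        with pytest.raises(ValueError, match="multiple"):
            simulate_single_cells(truth, 5, default_params, bin_size=250_000)


class TestReads:
    def test_tagged_reads_cover_catalog_positions(self, small_genome):
        params = SimParams(seed=12, snp_nocall_rate=0.0)
        catalog = simulate_snp_catalog(small_genome, params, bad_snp_rate=0.0)
        reads, obs, labels = simulate_tagged_reads(small_genome, catalog, 300,
                                                   params)
        assert len(reads) == 300 and len(labels) == 300
        merged = obs.merge(reads, on="read_id", suffixes=("", "_r"))
        assert ((merged["pos"] >= merged["start"])
                & (merged["pos"] < merged["end"])).all()
        assert set(labels.unique()) <= {"B6", "Cast", "unassigned", "discarded"}
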