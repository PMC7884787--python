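"""LRT, BH-FDR, seed-and-extend region calling, master-list subtraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from asrt.detection import (
    bh_fdr,
    call_regions,
    detect_asrt,
    genetic_regions_from_pure_strains,
    lrt_track,
    lrt_window,
    merge_intervals,
    subtract_genetic,
)
from asrt.profiling import profile_counts
from asrt.simulate import SimParams, simulate_pure_strain_counts, simulate_rt_landscape


def numeric_ml_lrt(a, b):
    """Independent oracle: numerically maximize both Gaussian likelihoods."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    x = np.concatenate([a, b])

    def nll_null(theta):
        mu, logsd = theta
        return -stats.norm.logpdf(x, mu, np.exp(logsd)).sum()

    def nll_alt(theta):
        mu1, mu2, logsd = theta
        sd = np.exp(logsd)
        return -(stats.norm.logpdf(a, mu1, sd).sum()
                 + stats.norm.logpdf(b, mu2, sd).sum())

    sd0 = max(x.std(), 1e-3)
    r0 = optimize.minimize(nll_null, [x.mean(), np.log(sd0)],
                           method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12,
                                    "maxiter": 5000})
    r1 = optimize.minimize(nll_alt, [a.mean(), b.mean(), np.log(sd0)],
                           method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12,
                                    "maxiter": 5000})
    return 2.0 * (r0.fun - r1.fun)


class TestLRTWindow:
    def test_identical_groups_give_zero(self):
        res = lrt_window([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_all_six_identical(self):
        res = lrt_window([1.0] * 3, [1.0] * 3)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_label_symmetry(self, rng):
        a, b = rng.normal(size=3), rng.normal(size=3)
        assert lrt_window(a, b) == lrt_window(b, a)

    def test_degenerate_within_fit(self):
        res = lrt_window([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert res.degenerate and res.pvalue == 0.0

    def test_example_against_numeric_ml_oracle(self):
        a, b = (1.0, 1.1, 0.9), (0.1, 0.0, -0.1)
        got = lrt_window(a, b)
        assert abs(got.statistic - numeric_ml_lrt(a, b)) < 1e-6
        # closed form: 6 ln(SS0/SS1) with SS0=1.54, SS1=0.04
        assert abs(got.statistic - 6 * np.log(1.54 / 0.04)) < 1e-12

    def test_track_within_variant_matches_scalar(self, truth, clone_counts):
        prof = profile_counts(clone_counts[0])
        tests = lrt_track(prof, variance="within")
        ok = np.flatnonzero(prof.informative)[:50]
        for i in ok:
            res = lrt_window(prof.values[i, 0, :], prof.values[i, 1, :])
            assert np.isclose(tests["statistic"].iloc[i], res.statistic)
            assert np.isclose(tests["pvalue"].iloc[i], res.pvalue)

    def test_pooled_variant_calibrated_null(self, rng):
        """Pooled-variance statistic is chi2(1) under the Gaussian null."""
        v = rng.normal(size=(4000, 2, 3))
        ss0 = ((v.reshape(4000, -1) - v.reshape(4000, -1).mean(1, keepdims=True)) ** 2).sum(1)
        gm = v.mean(axis=2)
        ss1 = ((v - gm[:, :, None]) ** 2).sum(axis=(1, 2))
        sigma2 = ss1.sum() / (4 * 4000)
        lam = (ss0 - ss1) / sigma2
        # compare tail fractions with chi2(1)
        for q in (0.5, 0.9, 0.99):
            thr = stats.chi2.ppf(q, 1)
            assert abs((lam > thr).mean() - (1 - q)) < 0.015


class TestBH:
    def test_single_pvalue(self):
        assert bh_fdr(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_example(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_empty(self):
        assert bh_fdr(np.array([])).size == 0

    def test_matches_independent_step_up(self, rng):
        p = rng.uniform(size=1000)
        got = bh_fdr(p)
        # independent implementation of the step-up rule
        m = len(p)
        order = np.argsort(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        expect = np.empty(m)
        expect[order] = np.minimum(ranked, 1.0)
        assert np.allclose(got, expect)

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=200)
        assert (bh_fdr(p) >= p - 1e-12).all()


def make_tests(qvals, deltas, informative=None, chrom="chr1"):
    n = len(qvals)
    if informative is None:
        informative = np.ones(n, dtype=bool)
    df = pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(n) * 100_000,
        "end": (np.arange(n) + 1) * 100_000,
        "delta_rt": deltas,
        "statistic": 1.0,
        "pvalue": qvals,
        "informative": informative,
        "segment": 0,
        "qvalue": qvals,
    })
    df.attrs["alleles"] = ("B6", "Cast")
    return df


def brute_force_regions(q, delta, q_seed=0.01, q_extend=0.05, min_delta=0.5):
    """Reference enumeration of the seed-and-extend rule on one segment."""
    n = len(q)
    windows = set()
    for i in range(n):
        if q[i] < q_seed:
            lo = i
            while lo > 0 and q[lo - 1] <= q_extend:
                lo -= 1
            hi = i
            while hi < n - 1 and q[hi + 1] <= q_extend:
                hi += 1
            windows.add((lo, hi))
    merged = []
    for lo, hi in sorted(windows):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return [(lo, hi) for lo, hi in merged
            if np.abs(delta[lo:hi + 1]).max() > min_delta]


class TestCallRegions:
    def test_all_q_one_no_regions(self):
        tests = make_tests(np.ones(20), np.zeros(20))
        assert len(call_regions(tests)) == 0

    def test_seed_and_extend_three_windows(self):
        """q = (..., 0.9, 0.04, 0.005, 0.04, 0.9, ...) spans exactly the
        middle three windows."""
        q = np.array([0.9, 0.9, 0.04, 0.005, 0.04, 0.9, 0.9])
        d = np.array([0.0, 0.0, 0.6, 0.8, 0.6, 0.0, 0.0])
        regions = call_regions(make_tests(q, d))
        assert len(regions) == 1
        r = regions.iloc[0]
        assert (r["start"], r["end"]) == (200_000, 500_000)
        assert r["n_windows"] == 3
        assert r["orientation"] == "B6_early"
        assert r["min_q"] == pytest.approx(0.005)

    def test_orientation_from_peak_sign(self):
        q = np.array([0.9, 0.001, 0.9])
        d = np.array([0.0, -0.9, 0.0])
        regions = call_regions(make_tests(q, d))
        assert regions.iloc[0]["orientation"] == "Cast_early"

    def test_delta_filter_drops_weak_regions(self):
        q = np.array([0.9, 0.001, 0.9])
        d = np.array([0.0, 0.49, 0.0])
        assert len(call_regions(make_tests(q, d))) == 0
        d2 = np.array([0.0, 0.51, 0.0])
        assert len(call_regions(make_tests(q, d2))) == 1

    def test_masked_window_breaks_extension(self):
        q = np.array([0.04, 0.04, 0.005, 0.04, 0.04])
        d = np.full(5, 0.8)
        inf = np.array([True, False, True, True, True])
        regions = call_regions(make_tests(q, d, informative=inf))
        assert len(regions) == 1
        assert regions.iloc[0]["start"] == 200_000  # cannot cross window 1

    def test_matches_brute_force_on_random_track(self, rng):
        q = rng.uniform(size=500) ** 3        # heavy low tail
        d = rng.normal(0, 0.5, 500)
        regions = call_regions(make_tests(q, d))
        expect = brute_force_regions(q, d)
        got = [(r["start"] // 100_000, r["end"] // 100_000 - 1)
               for _, r in regions.iterrows()]
        assert got == expect

    def test_non_uniform_grid_raises(self):
        tests = make_tests(np.ones(5), np.zeros(5))
        tests.loc[3, "start"] += 1
        with pytest.raises(ValueError, match="uniform grid"):
            call_regions(tests)


class TestMasterList:
    def _regions(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "orientation", "min_q",
                           "max_abs_delta", "n_windows"])

    def test_empty_genetic_keeps_merged_union(self):
        clones = {
            0: self._regions([("chr1", 0, 300_000, "B6_early", 1e-3, 0.8, 3)]),
            1: self._regions([("chr1", 200_000, 500_000, "B6_early", 1e-3, 0.9, 3)]),
        }
        master = subtract_genetic(clones, pd.DataFrame(columns=["chrom", "start", "end"]))
        assert len(master) == 1
        assert (master.iloc[0]["start"], master.iloc[0]["end"]) == (0, 500_000)

    def test_identical_genetic_region_removed(self):
        clones = {0: self._regions([("chr1", 0, 300_000, "B6_early", 1e-3, 0.8, 3)])}
        genetic = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 300_000}])
        assert len(subtract_genetic(clones, genetic)) == 0

    def test_single_bp_overlap_removes(self):
        clones = {0: self._regions([("chr1", 0, 300_000, "B6_early", 1e-3, 0.8, 3)])}
        genetic = pd.DataFrame([{"chrom": "chr1", "start": 299_999, "end": 400_000}])
        assert len(subtract_genetic(clones, genetic)) == 0
        disjoint = pd.DataFrame([{"chrom": "chr1", "start": 300_000, "end": 400_000}])
        assert len(subtract_genetic(clones, disjoint)) == 1

    def test_matches_quadratic_overlap_scan(self, rng):
        def rand_regions(n, seed):
            r = np.random.default_rng(seed)
            starts = r.integers(0, 90, n) * 100_000
            lens = r.integers(1, 8, n) * 100_000
            return self._regions([
                ("chr1", int(s), int(s + l), "B6_early", 1e-3, 0.8, int(l // 1e5))
                for s, l in zip(starts, lens)])
        clones = {0: rand_regions(12, 1), 1: rand_regions(12, 2)}
        genetic = rand_regions(6, 3)[["chrom", "start", "end"]]
        master = subtract_genetic(clones, genetic)
        merged = merge_intervals(list(clones.values()))
        expect = []
        for _, m in merged.iterrows():
            hit = any(g["start"] < m["end"] and g["end"] > m["start"]
                      for _, g in genetic.iterrows())
            if not hit:
                expect.append((m["start"], m["end"]))
        assert [(r["start"], r["end"]) for _, r in master.iterrows()] == expect

    def test_merge_records_contributing_orientations(self):
        clones = {
            0: self._regions([("chr1", 0, 300_000, "B6_early", 1e-3, 0.8, 3)]),
            1: self._regions([("chr1", 100_000, 400_000, "Cast_early", 1e-3, 0.9, 3)]),
        }
        master = subtract_genetic(clones, pd.DataFrame(columns=["chrom", "start", "end"]))
        assert master.iloc[0]["orientation"] == "mixed"
        assert master.iloc[0]["orientations"] == "B6_early,Cast_early"


class TestPureStrains:
    def test_identical_strain_profiles_give_empty_list(self, small_genome):
        params = SimParams(seed=31, n_as_regions=6, n_genetic_regions=0,
                          n_deletions=0)
        truth = simulate_rt_landscape(small_genome, params)
        pure = profile_counts(simulate_pure_strain_counts(truth))
        regions = genetic_regions_from_pure_strains(pure)
        assert len(regions) == 0

    def test_implanted_genetic_differential_detected(self, small_genome):
        """The strict BH caller finds genetic differentials (partial power on
        a sparse-signal genome); the sensitivity-first mask finds them all."""
        from asrt.detection import genetic_mask_from_pure_strains

        params = SimParams(seed=32, n_as_regions=0, n_genetic_regions=3,
                          n_deletions=0, genetic_effect=1.0)
        truth = simulate_rt_landscape(small_genome, params)
        pure = profile_counts(simulate_pure_strain_counts(truth))

        def hits(regions):
            return sum(
                any(r["chrom"] == g["chrom"] and r["start"] < g["end"]
                    and r["end"] > g["start"] for _, r in regions.iterrows())
                for _, g in truth.genetic_regions.iterrows())

        assert hits(genetic_regions_from_pure_strains(pure)) >= 1
        assert hits(genetic_mask_from_pure_strains(pure)) == 3

    def test_strain_swap_flips_orientation_same_intervals(self, small_genome):
        params = SimParams(seed=33, n_as_regions=0, n_genetic_regions=3,
                          n_deletions=0)
        truth = simulate_rt_landscape(small_genome, params)
        track = simulate_pure_strain_counts(truth)
        swapped = track.copy()
        swapped["allele"] = track["allele"].map({"B6": "Cast", "Cast": "B6"})
        # keep the original allele order in the pivot by category ordering
        r1 = genetic_regions_from_pure_strains(profile_counts(track))
        r2 = genetic_regions_from_pure_strains(profile_counts(swapped))
        assert list(r1["start"]) == list(r2["start"])
        flip = {"B6_early": "Cast_early", "Cast_early": "B6_early"}
        assert [flip[o] for o in r1["orientation"]] == list(r2["orientation"])


class TestEndToEnd:
    def test_region_calling_invariant_to_chromosome_order(self, clone_counts):
        track = clone_counts[0]
        reordered = pd.concat(
            [track[track["chrom"] == "chr2"], track[track["chrom"] == "chr1"]],
            ignore_index=True)
        _, r1 = detect_asrt(profile_counts(track))
        _, r2 = detect_asrt(profile_counts(reordered))
        key = lambda df: sorted(zip(df["chrom"], df["start"], df["end"]))
        assert key(r1) == key(r2)

    def test_recovered_orientation_matches_truth(self, truth, clone_counts,
                                                 default_params):
        """Whenever an implanted region is recovered, its called orientation
        matches the clone's implanted orientation."""
        for clone, track in clone_counts.items():
            _, regions = detect_asrt(profile_counts(track))
            truth_c = truth.as_regions_for_clone(clone)
            for _, t in truth_c.iterrows():
                for _, c in regions.iterrows():
                    if (c["chrom"] == t["chrom"] and c["start"] < t["end"]
                            and c["end"] > t["start"]):
                        assert c["orientation"] == t["orientation"]


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=80))
@settings(deadline=None, derandomize=True)
def test_bh_properties(pvals):
    """q >= p, q <= 1, and monotone in sorted-p order."""
    p = np.array(pvals)
    q = bh_fdr(p)
    assert (q <= 1.0 + 1e-12).all()
    assert (q >= p - 1e-12).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()
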