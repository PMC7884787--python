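"""End-to-end verification experiments against generator ground truth.

Each function runs a self-contained experiment on synthetic data — null
calibration of the region caller, recovery of implanted AS regions through
the full multi-clone pipeline, deletion detection, FISH separation, and
single-cell enrichment — and returns plain dictionaries of summary numbers.
They are deterministic given ``seed``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detection import detect_asrt, merge_intervals
from .genome import GenomeSpec, default_genome
from .genomics import detect_deletions
from .pipeline import PipelineConfig, run_pipeline
from .profiling import profile_counts
from .simulate import (
    SimParams,
    simulate_counts,
    simulate_fish,
    simulate_rt_landscape,
    simulate_single_cells,
)
from .singlecell import asynchrony_counts, enrichment_chisq

__all__ = [
    "interval_overlap",
    "score_recovery",
    "count_false_calls",
    "run_null_calibration",
    "run_recovery_experiment",
    "run_deletion_check",
    "run_fish_separation",
    "run_single_cell_enrichment",
]


def interval_overlap(a: tuple, b: tuple) -> int:
    """Overlap in bp between (chrom, start, end) tuples."""
    if a[0] != b[0]:
        return 0
    return max(0, min(a[2], b[2]) - max(a[1], b[1]))


def _tuples(df: pd.DataFrame) -> list[tuple]:
    return [(r["chrom"], int(r["start"]), int(r["end"]))
            for _, r in df.iterrows()]


def score_recovery(truth_regions: pd.DataFrame, called: pd.DataFrame,
                   min_reciprocal: float = 0.5) -> dict:
    """Fraction of truth intervals matched by a call at reciprocal overlap."""
    truths = _tuples(truth_regions)
    calls = _tuples(called)
    recovered = 0
    for t in truths:
        length = t[2] - t[1]
        for c in calls:
            ov = interval_overlap(t, c)
            if ov >= min_reciprocal * length and ov >= min_reciprocal * (c[2] - c[1]):
                recovered += 1
                break
    return {"n_truth": len(truths), "n_recovered": recovered,
            "recovery_fraction": recovered / len(truths) if truths else float("nan")}


def count_false_calls(called: pd.DataFrame, truth_all: pd.DataFrame) -> int:
    """Calls with zero overlap against every truth interval."""
    truths = _tuples(truth_all)
    return sum(
        1 for c in _tuples(called)
        if not any(interval_overlap(t, c) > 0 for t in truths))


def run_null_calibration(n_genomes: int = 200, seed: int = 0,
                         n_chromosomes: int = 2, n_windows: int = 500,
                         q_seed: float = 0.01) -> dict:
    """Region-calling false-positive behaviour on signal-free genomes.

    Simulates genomes with no implanted regions (both alleles identical) and
    runs profiling plus detection on each; reports the fraction of genomes
    with at least one called region and the mean fraction of informative
    windows reaching q < ``q_seed``.
    """
    spec = default_genome(n_chromosomes, n_windows)
    any_call = 0
    q_fracs = []
    for i in range(n_genomes):
        params = SimParams(seed=seed + i, n_as_regions=0,
                          n_genetic_regions=0, n_deletions=0, n_clones=1)
        truth = simulate_rt_landscape(spec, params)
        track = simulate_counts(truth)[0]
        tests, regions = detect_asrt(profile_counts(track))
        any_call += len(regions) > 0
        q = tests["qvalue"].to_numpy()
        ok = np.isfinite(q)
        q_fracs.append(float((q[ok] < q_seed).mean()) if ok.any() else 0.0)
    return {
        "n_genomes": n_genomes,
        "fraction_genomes_with_calls": any_call / n_genomes,
        "mean_fraction_windows_q_below_seed": float(np.mean(q_fracs)),
    }


def run_recovery_experiment(seed: int = 1, n_as_regions: int = 50,
                            n_genetic_regions: int = 4, n_deletions: int = 2,
                            n_chromosomes: int = 5, n_windows: int = 600,
                            ) -> dict:
    """Full-pipeline recovery of implanted AS regions.

    Runs the default multi-clone pipeline (3 clones, 3 replicates, depth 100,
    replicate RT noise 0.25, effect 1.0) and scores the master list against
    the implanted truth: recovery at 50% reciprocal overlap, false calls,
    per-clone orientation accuracy among matched calls, and contamination by
    implanted genetic regions.
    """
    spec = default_genome(n_chromosomes, n_windows)
    params = SimParams(seed=seed, n_as_regions=n_as_regions,
                      n_genetic_regions=n_genetic_regions,
                      n_deletions=n_deletions)
    cfg = PipelineConfig(genome=spec, sim=params, write_outputs=False)
    res = run_pipeline(cfg)
    truth = res.truth

    rec = score_recovery(truth.as_regions, res.master)
    all_truth = pd.concat(
        [truth.as_regions[["chrom", "start", "end"]],
         truth.genetic_regions[["chrom", "start", "end"]],
         truth.deletions[["chrom", "start", "end"]]], ignore_index=True)
    n_false = count_false_calls(res.master, all_truth)

    # orientation accuracy: per-clone calls vs that clone's implanted map
    matched = correct = 0
    for clone, regions in res.clone_regions.items():
        truth_c = truth.as_regions_for_clone(clone)
        for _, t in truth_c.iterrows():
            tt = (t["chrom"], int(t["start"]), int(t["end"]))
            length = tt[2] - tt[1]
            for _, c in regions.iterrows():
                cc = (c["chrom"], int(c["start"]), int(c["end"]))
                ov = interval_overlap(tt, cc)
                if ov >= 0.5 * length and ov >= 0.5 * (cc[2] - cc[1]):
                    matched += 1
                    correct += c["orientation"] == t["orientation"]
                    break

    contamination = sum(
        1 for _, g in truth.genetic_regions.iterrows()
        if any(interval_overlap((g["chrom"], int(g["start"]), int(g["end"])),
                                c) > 0 for c in _tuples(res.master)))
    # mechanics: every master region is disjoint from every detected
    # genetic interval (mask and BH list)
    detected_genetic = pd.concat(
        [res.genetic_mask[["chrom", "start", "end"]],
         res.genetic_regions[["chrom", "start", "end"]]], ignore_index=True)
    mechanics_violations = sum(
        1 for c in _tuples(res.master)
        if any(interval_overlap(g, c) > 0 for g in _tuples(res.genetic_mask)))

    return rec | {
        "n_master_calls": int(len(res.master)),
        "n_false_calls": int(n_false),
        "false_call_fraction": n_false / max(len(res.master), 1),
        "n_orientation_matched": matched,
        "orientation_accuracy": correct / matched if matched else float("nan"),
        "genetic_regions_implanted": int(len(truth.genetic_regions)),
        "genetic_contamination": int(contamination),
        "subtraction_violations": int(mechanics_violations),
    }


def run_deletion_check(seed: int = 0, n_windows: int = 400,
                       window: int = 50_000) -> dict:
    """Implanted >=2-window CNVs at ratio 3 / 0.3 must be called exactly;
    flat genomes and single-window spikes must stay silent."""
    rng = np.random.default_rng(seed)
    grid = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n_windows) * window,
        "end": (np.arange(n_windows) + 1) * window,
    })
    refs = {f"ref{i}": rng.poisson(100, n_windows) for i in range(3)}
    lam = np.full(n_windows, 100.0)
    implants = [(40, 44, 0.3, "loss"), (120, 122, 3.0, "gain"),
                (250, 253, 3.0, "gain"), (320, 322, 0.3, "loss")]
    for lo, hi, ratio, _ in implants:
        lam[lo:hi] *= ratio
    spike = 200
    lam[spike] *= 3.0
    depth = grid.assign(**refs, clone=rng.poisson(lam))
    calls = detect_deletions(depth, list(refs))
    expected = {(lo * window, hi * window, d) for lo, hi, _, d in implants}
    got = {(int(r["start"]), int(r["end"]), r["direction"])
           for _, r in calls.iterrows()}
    flat = grid.assign(**refs, clone=rng.poisson(np.full(n_windows, 100.0)))
    n_flat_calls = len(detect_deletions(flat, list(refs)))
    return {
        "n_implanted": len(implants),
        "n_detected_exactly": len(expected & got),
        "n_extra_calls": len(got - expected),
        "n_flat_genome_calls": int(n_flat_calls),
        "spike_called": any(lo <= spike * window < hi for lo, hi, _ in got),
    }


def run_fish_separation(n_replicates: int = 100, seed: int = 0,
                        n_nuclei: int = 100) -> dict:
    """Seeded FISH replicates: AS probe SD% > 35 and synchronous SD% < 23.

    Uses the generator defaults (background 0.15, gain 0.35 per |dRT|), one
    AS probe at |dRT| = 1 and one synchronous probe per replicate.
    """
    spec = default_genome(4, 500)
    hits = 0
    for i in range(n_replicates):
        params = SimParams(seed=seed + i, n_as_regions=4,
                          n_genetic_regions=0, n_deletions=0)
        truth = simulate_rt_landscape(spec, params)
        r = truth.as_regions.iloc[0]
        as_probe = [(r["chrom"], int(r["start"]), int(r["end"]))]
        mask = truth.region_window_mask(truth.as_regions)
        wins = truth.windows
        sync_idx = next(i for i in range(len(wins))
                        if wins["chrom"].iloc[i] == "chr4" and not mask[i])
        sync_probe = [("chr4", int(wins["start"].iloc[sync_idx]),
                       int(wins["start"].iloc[sync_idx]) + spec.window_size)]
        f_as = simulate_fish(truth, params, as_probe, n_nuclei=n_nuclei)
        f_sync = simulate_fish(truth, params, sync_probe, n_nuclei=n_nuclei)
        sd_as = 100.0 * f_as["n_sd"].iloc[0] / n_nuclei
        sd_sync = 100.0 * f_sync["n_sd"].iloc[0] / n_nuclei
        hits += (sd_as > 35.0) and (sd_sync < 23.0)
    return {"n_replicates": n_replicates, "n_separated": hits,
            "separation_fraction": hits / n_replicates}


def run_single_cell_enrichment(seed: int = 0, n_cells: int = 40,
                               effects: tuple = (0.0, 0.5, 1.0),
                               n_as_regions: int = 25) -> dict:
    """Chi-square enrichment of one-allele events in AS vs synchronous bins
    across effect sizes, at matched genome and cell count."""
    spec = default_genome(4, 500)
    chi2s, pvals = [], []
    for eff in effects:
        params = SimParams(seed=seed, n_as_regions=n_as_regions,
                          n_genetic_regions=0, n_deletions=0, as_effect=eff)
        truth = simulate_rt_landscape(spec, params)
        m = simulate_single_cells(truth, n_cells, params)
        table = asynchrony_counts(m, truth.as_regions)
        chi2, p = enrichment_chisq(table)
        chi2s.append(float(chi2))
        pvals.append(float(p))
    return {
        "effects": list(effects),
        "chi2": chi2s,
        "pvalues": pvals,
        "monotone": bool(np.all(np.diff(chi2s) > 0)),
    }
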