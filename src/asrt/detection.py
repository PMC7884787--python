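"""Calling asynchronously replicating regions from replicated RT profiles.

Per window, the six smoothed RT values (two alleles x three replicates, or in
general two groups of replicates) are compared with a Gaussian likelihood-ratio
test: the null model gives all values one common mean, the alternative one
mean per allele, with a shared unknown variance. The statistic is

    Lambda = n * ln(SS0 / SS1)

with n the total number of values, SS0 the total sum of squares about the
grand mean and SS1 the pooled within-group sum of squares; p-values come from
the chi-square distribution with 1 df. Benjamini-Hochberg correction yields
per-window q-values. Regions are seeded at maximal runs of windows with
q < q_seed (0.01), extended over consecutive informative windows while
q <= q_extend (0.05), merged when they overlap, and kept only if they contain
at least one window with |mean RT difference| > min_delta (0.5). The master
list across clones is the merged union of clone regions minus anything
overlapping a pure-strain (genetic) differential region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiling import RTProfile

__all__ = [
    "LRTResult",
    "lrt_window",
    "lrt_track",
    "bh_fdr",
    "call_regions",
    "detect_asrt",
    "subtract_genetic",
    "genetic_regions_from_pure_strains",
    "merge_intervals",
    "overlaps_any",
]

REGION_COLUMNS = ["chrom", "start", "end", "orientation", "min_q",
                  "max_abs_delta", "n_windows"]


class LRTResult(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool = False


def lrt_window(a: Iterable[float], b: Iterable[float]) -> LRTResult:
    """Likelihood-ratio test that two replicate groups share a mean.

    Both models assume Gaussian values with a shared (profiled-out) variance;
    the alternative gives each group its own mean. Returns
    ``(Lambda, p, degenerate)``; ``degenerate`` flags a perfect within-group
    fit (SS1 = 0) with distinct group means, where the statistic diverges and
    p = 0 is returned.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 1 or b.size < 1 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("both groups need finite values")
    n = a.size + b.size
    grand = (a.sum() + b.sum()) / n
    ss0 = float(((a - grand) ** 2).sum() + ((b - grand) ** 2).sum())
    ss1 = float(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
    if ss1 == 0.0:
        if ss0 == 0.0:
            return LRTResult(0.0, 1.0, False)
        return LRTResult(np.inf, 0.0, True)
    lam = n * np.log(ss0 / ss1)
    lam = max(lam, 0.0)
    return LRTResult(float(lam), float(stats.chi2.sf(lam, df=1)), False)


def lrt_track(profile: RTProfile, variance: str = "pooled") -> pd.DataFrame:
    """Vectorized per-window LRT over a profile's informative windows.

    Returns the WindowTest table: one row per window on the grid with
    delta_rt (mean allele[0] - mean allele[1] of smoothed values), the LRT
    statistic, p-value and BH q-value (computed over informative windows
    only); NaN elsewhere.

    ``variance`` selects the variance treatment. ``"pooled"`` (default)
    estimates one replicate variance from the within-group sums of squares of
    all informative windows, so the per-window statistic is the between-group
    sum of squares over that common variance and the chi-square(1) reference
    is well calibrated even with few replicates. ``"within"`` is the
    window-local shared-unknown-variance LRT of :func:`lrt_window`, whose
    chi-square reference is only asymptotic in the replicate count.
    """
    v = profile.values                      # (W, 2, R)
    n = v.shape[1] * v.shape[2]
    grand = v.reshape(v.shape[0], -1).mean(axis=1)
    ss0 = ((v.reshape(v.shape[0], -1) - grand[:, None]) ** 2).sum(axis=1)
    group_mean = v.mean(axis=2)             # (W, 2)
    ss1 = ((v - group_mean[:, :, None]) ** 2).sum(axis=(1, 2))
    if variance == "pooled":
        ok = profile.informative & np.isfinite(ss1)
        df_within = n - 2
        if not ok.any() or ss1[ok].sum() == 0:
            sigma2 = np.nan
        else:
            sigma2 = ss1[ok].sum() / (df_within * ok.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = (ss0 - ss1) / sigma2
        lam = np.where(np.isnan(lam), np.nan, np.maximum(lam, 0.0))
        pvals = stats.chi2.sf(lam, df=1)
    elif variance == "within":
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = n * np.log(ss0 / ss1)
        lam = np.where(np.isnan(lam), np.nan, np.maximum(lam, 0.0))
        degenerate = (ss1 == 0) & (ss0 > 0)
        lam[degenerate] = np.inf
        pvals = stats.chi2.sf(lam, df=1)
        pvals[degenerate] = 0.0
        both_zero = (ss1 == 0) & (ss0 == 0)
        lam[both_zero] = 0.0
        pvals[both_zero] = 1.0
    else:
        raise ValueError("variance must be 'pooled' or 'within'")

    out = profile.windows.copy()
    out["delta_rt"] = group_mean[:, 0] - group_mean[:, 1]
    out["statistic"] = lam
    out["pvalue"] = pvals
    out["informative"] = profile.informative
    out["segment"] = profile.segment
    qvals = np.full(len(out), np.nan)
    mask = profile.informative & np.isfinite(pvals)
    qvals[mask] = bh_fdr(pvals[mask])
    out["qvalue"] = qvals
    return out


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as half-open (start, stop) index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    return [(p[0], p[-1] + 1) for p in np.split(idx, breaks + 1)]


def call_regions(tests: pd.DataFrame, q_seed: float = 0.01,
                 q_extend: float = 0.05, min_delta: float = 0.5,
                 gap_tolerance: int = 0) -> pd.DataFrame:
    """Seed-and-extend region calling on a WindowTest table.

    Within each run of consecutive informative windows, maximal runs with
    q < q_seed seed regions, which extend outward window by window while
    q <= q_extend (extension stops at the first failing window; masked
    windows always stop extension unless within ``gap_tolerance``). Extended
    regions that overlap are merged. Regions without a window of
    |delta_rt| > min_delta are dropped; orientation comes from the sign of
    delta_rt at the maximal-|delta_rt| window.
    """
    alleles = tests.attrs.get("alleles", ("A", "B"))
    regions: list[dict] = []
    for chrom, sub in tests.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        starts = sub["start"].to_numpy()
        if len(starts) > 1:
            widths = np.diff(starts)
            if (widths <= 0).any() or len(np.unique(widths)) > 1:
                raise ValueError(
                    f"windows on {chrom} are not a contiguous uniform grid")
        q = sub["qvalue"].to_numpy()
        delta = sub["delta_rt"].to_numpy()
        informative = (sub["informative"].to_numpy()
                       if "informative" in sub else np.isfinite(q))
        usable = informative & np.isfinite(q)

        for run_lo, run_hi in _runs_with_gaps(usable, gap_tolerance):
            qr = q[run_lo:run_hi]
            ok = usable[run_lo:run_hi]
            seed_mask = ok & (qr < q_seed)
            intervals = []
            for s0, s1 in _runs(seed_mask):
                lo = s0
                while lo > 0 and ok[lo - 1] and qr[lo - 1] <= q_extend:
                    lo -= 1
                hi = s1
                while hi < len(qr) and ok[hi] and qr[hi] <= q_extend:
                    hi += 1
                intervals.append((lo, hi))
            for lo, hi in _merge_index_intervals(intervals):
                dr = delta[run_lo + lo:run_lo + hi]
                dr_ok = ok[lo:hi]
                vals = np.where(dr_ok, np.abs(dr), -np.inf)
                peak = int(np.argmax(vals))
                if not np.isfinite(vals[peak]) or vals[peak] <= min_delta:
                    continue
                orient = alleles[0] if dr[peak] > 0 else alleles[1]
                qs = q[run_lo + lo:run_lo + hi][dr_ok]
                regions.append({
                    "chrom": chrom,
                    "start": int(sub["start"].iloc[run_lo + lo]),
                    "end": int(sub["end"].iloc[run_lo + hi - 1]),
                    "orientation": f"{orient}_early",
                    "min_q": float(np.min(qs)),
                    "max_abs_delta": float(vals[peak]),
                    "n_windows": int(hi - lo),
                })
    return pd.DataFrame(regions, columns=REGION_COLUMNS)


def _runs_with_gaps(mask: np.ndarray, gap: int) -> list[tuple[int, int]]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > gap + 1)
    return [(p[0], p[-1] + 1) for p in np.split(idx, breaks + 1)]


def _merge_index_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def detect_asrt(profile: RTProfile, q_seed: float = 0.01,
                q_extend: float = 0.05, min_delta: float = 0.5,
                gap_tolerance: int = 0, variance: str = "pooled",
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LRT -> BH -> region calling on one clone's profile."""
    tests = lrt_track(profile, variance=variance)
    tests.attrs["alleles"] = profile.alleles
    regions = call_regions(tests, q_seed=q_seed, q_extend=q_extend,
                           min_delta=min_delta, gap_tolerance=gap_tolerance)
    return tests, regions


def merge_intervals(frames: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Merge overlapping intervals across region tables.

    Overlapping (but not merely book-ended) intervals are unioned; the merged
    region records contributing orientations and the extreme q / delta over
    its members.
    """
    rows = pd.concat([f for f in frames if len(f)], ignore_index=True) \
        if any(len(f) for f in frames) else pd.DataFrame(columns=REGION_COLUMNS)
    if rows.empty:
        return pd.DataFrame(columns=REGION_COLUMNS + ["orientations"])
    out = []
    for chrom, sub in rows.groupby("chrom", sort=False):
        sub = sub.sort_values(["start", "end"]).reset_index(drop=True)
        cur = None
        for _, r in sub.iterrows():
            if cur is None or r["start"] >= cur["end"]:
                if cur is not None:
                    out.append(cur)
                cur = {"chrom": chrom, "start": int(r["start"]),
                       "end": int(r["end"]),
                       "orientations": {str(r.get("orientation", "."))},
                       "min_q": float(r.get("min_q", np.nan)),
                       "max_abs_delta": float(r.get("max_abs_delta", np.nan))}
            else:
                cur["end"] = max(cur["end"], int(r["end"]))
                cur["orientations"].add(str(r.get("orientation", ".")))
                pair_q = [cur["min_q"], float(r.get("min_q", np.nan))]
                pair_d = [cur["max_abs_delta"],
                          float(r.get("max_abs_delta", np.nan))]
                cur["min_q"] = (np.nanmin(pair_q)
                                if not np.isnan(pair_q).all() else np.nan)
                cur["max_abs_delta"] = (np.nanmax(pair_d)
                                        if not np.isnan(pair_d).all() else np.nan)
        if cur is not None:
            out.append(cur)
    res = pd.DataFrame(out)
    res["orientation"] = res["orientations"].map(
        lambda s: sorted(s)[0] if len(s) == 1 else "mixed")
    res["orientations"] = res["orientations"].map(lambda s: ",".join(sorted(s)))
    res["n_windows"] = np.nan
    return res[["chrom", "start", "end", "orientation", "min_q",
                "max_abs_delta", "n_windows", "orientations"]]


def overlaps_any(region: pd.Series, others: pd.DataFrame) -> bool:
    """True if the region shares >= 1 bp with any interval in ``others``."""
    if others.empty:
        return False
    same = others["chrom"] == region["chrom"]
    return bool(((others.loc[same, "start"] < region["end"])
                 & (others.loc[same, "end"] > region["start"])).any())


def subtract_genetic(clone_regions: dict | list, genetic_regions: pd.DataFrame,
                     pure_profile: RTProfile | None = None,
                     alpha_region: float = 0.02) -> pd.DataFrame:
    """Master AS-region list: merged clone union minus genetic differentials.

    Any merged region overlapping a pure-strain differential region by at
    least one bp is removed; these reflect strain genetics, not epigenetic
    allelic choice. When ``pure_profile`` is given, each surviving candidate
    is additionally screened with a region-level pure-strain test
    (:func:`pure_strain_region_test`): aggregating the strain difference over
    the whole candidate region has far more power than any per-window scan,
    so genetic regions that slipped past the window-level mask are still
    caught, at a false-removal cost of about ``alpha_region`` per candidate.
    """
    if isinstance(clone_regions, dict):
        frames = list(clone_regions.values())
    else:
        frames = list(clone_regions)
    merged = merge_intervals(frames)
    if merged.empty:
        return merged
    keep = np.array([not overlaps_any(r, genetic_regions)
                     for _, r in merged.iterrows()])
    if pure_profile is not None and keep.any():
        candidates = merged.loc[keep]
        genetic_like = pure_strain_region_test(pure_profile, candidates,
                                               alpha=alpha_region)
        keep[np.flatnonzero(keep)[genetic_like]] = False
    return merged.loc[keep].reset_index(drop=True)


def pure_strain_region_test(pure_profile: RTProfile, regions: pd.DataFrame,
                            alpha: float = 0.01) -> np.ndarray:
    """Region-level test for a pure-strain RT difference over each interval.

    For each region and replicate, the strain difference is averaged over the
    region's informative windows, giving one independent difference per
    replicate library (spatial correlation from smoothing does not couple
    replicates). Because the variance of such a region mean scales inversely
    with the number of windows averaged, per-replicate variances are pooled
    across regions on the per-window scale (v_i ~ c / n_i) before forming
    each region's z statistic. When a region carries an unambiguous
    orientation from the clone calls the test is one-sided toward that
    direction — a genetic difference always agrees with the direction the
    clones saw — otherwise two-sided. Regions with no informative
    pure-strain windows cannot be cleared of a genetic origin and are
    flagged. Returns a boolean array, True = genetic-like.
    """
    wins = pure_profile.windows
    alleles = pure_profile.alleles
    diffs = pure_profile.values[:, 0, :] - pure_profile.values[:, 1, :]
    per_region: list[tuple | None] = []
    for _, r in regions.iterrows():
        m = ((wins["chrom"] == r["chrom"]) & (wins["start"] < r["end"])
             & (wins["end"] > r["start"])).to_numpy()
        m &= pure_profile.informative
        per_region.append((diffs[m].mean(axis=0), int(m.sum()))
                          if m.any() else None)
    usable = [(d, n) for item in per_region if item is not None
              for d, n in [item] if len(d) >= 2]
    if not usable:
        return np.array([item is None for item in per_region])
    # per-window variance scale: Var(region mean) ~ c / n_windows
    c_hat = float(np.mean([np.var(d, ddof=1) * n for d, n in usable]))
    n_rep = len(usable[0][0])
    flags = np.zeros(len(per_region), dtype=bool)
    for i, item in enumerate(per_region):
        if item is None:
            flags[i] = True
            continue
        d, n = item
        if c_hat == 0:
            flags[i] = bool(np.mean(d) != 0)
            continue
        z = np.mean(d) / np.sqrt(c_hat / (n * n_rep))
        orient = str(regions.iloc[i].get("orientation", "mixed"))
        if orient == f"{alleles[0]}_early":
            flags[i] = bool(z > stats.norm.isf(alpha))
        elif orient == f"{alleles[1]}_early":
            flags[i] = bool(-z > stats.norm.isf(alpha))
        else:
            flags[i] = bool(abs(z) > stats.norm.isf(alpha / 2))
    return flags


def genetic_regions_from_pure_strains(pure_profile: RTProfile,
                                      q_seed: float = 0.01,
                                      q_extend: float = 0.05,
                                      min_delta: float = 0.5) -> pd.DataFrame:
    """Differential regions between pure parental strains.

    The pure-strain count track uses the strain name in the allele slot, so
    the identical LRT -> BH -> seed-and-extend machinery applies with groups =
    strain replicates.
    """
    if len(pure_profile.replicates) < 2:
        raise ValueError("need >= 2 replicates per strain")
    _, regions = detect_asrt(pure_profile, q_seed=q_seed,
                             q_extend=q_extend, min_delta=min_delta)
    return regions


def genetic_mask_from_pure_strains(pure_profile: RTProfile,
                                   p_threshold: float = 0.01,
                                   min_run: int = 3,
                                   margin: int = 0) -> pd.DataFrame:
    """Sensitivity-first pure-strain differential mask for master-list
    subtraction.

    Masking genetic differences trades specificity for sensitivity: a missed
    genetic region contaminates the epigenetic master list, whereas an
    over-eager mask merely drops a candidate. Runs of at least ``min_run``
    consecutive informative windows with uncorrected per-window LRT
    p < ``p_threshold`` are masked, optionally padded by ``margin`` windows.
    Because subtraction removes on any overlap, no padding is needed by
    default. Use :func:`genetic_regions_from_pure_strains` when the
    pure-strain differential regions are themselves the object of interest.
    """
    if len(pure_profile.replicates) < 2:
        raise ValueError("need >= 2 replicates per strain")
    tests = lrt_track(pure_profile)
    out = []
    for chrom, sub in tests.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        hit = (sub["informative"].to_numpy()
               & (sub["pvalue"].to_numpy() < p_threshold))
        for lo, hi in _runs(hit):
            if hi - lo < min_run:
                continue
            lo = max(lo - margin, 0)
            hi = min(hi + margin, len(sub))
            out.append({"chrom": chrom,
                        "start": int(sub["start"].iloc[lo]),
                        "end": int(sub["end"].iloc[hi - 1])})
    frame = pd.DataFrame(out, columns=["chrom", "start", "end"])
    if frame.empty:
        return frame
    merged = merge_intervals([frame.assign(orientation=".",
                                           min_q=np.nan, max_abs_delta=np.nan,
                                           n_windows=np.nan)])
    return merged[["chrom", "start", "end"]]
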