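"""S/G1 replication-timing profiles: ratio, filters, normalization, smoothing.

The replication-timing (RT) proxy is the per-window ratio of depth-normalized
S-phase to G1-phase read counts: a locus replicating early in S is present at
up to twice the G1 copy number in an S-sorted population, so higher S/G1 means
earlier replication. Per allele and replicate the pipeline is

    RPM-normalize -> S/G1 ratio -> mask uninformative windows and G1
    allelic-ratio outliers -> log2 + per-sample z-score -> cubic smoothing
    spline per segment.

Smoothing uses the classic penalized objective
``p * sum_i (y_i - f(x_i))^2 + (1 - p) * integral f''(x)^2 dx`` (the csaps
convention). Because p trades off against the cube of the x spacing, the
config's ``p_units`` states whether ``smoothing_p`` refers to base-pair x
coordinates (the convention RT studies quote, default p = 1e-16) or to
window-index units; internally the spline is always solved in window units
with ``lam = (1 - p) / p / w^3`` for bp units (w = window size in bp).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "RTConfig",
    "RatioTrack",
    "RTProfile",
    "counts_to_arrays",
    "s_over_g1",
    "filter_g1_outliers",
    "normalize_rt",
    "smooth_interpolate",
    "smoothing_spline",
    "profile_counts",
]

TRACK_COLUMNS = ["chrom", "start", "end", "allele", "replicate", "fraction", "count"]


def is_autosome(chrom: str) -> bool:
    return chrom.removeprefix("chr").upper() not in {"X", "Y"}


@dataclass(frozen=True)
class RTConfig:
    """Profiling parameters.

    ``smoothing_p`` is the csaps roughness/fidelity trade-off in (0, 1);
    ``p_units`` gives the x-coordinate convention it refers to ("bp" or
    "window"). ``min_segment_windows`` drops segments with fewer informative
    windows; ``g1_outlier_sd`` masks windows whose log allelic G1 ratio is
    further than that many SDs from the genome mean; ``max_gap_windows`` is
    the longest run of uninformative windows a segment may interpolate
    across before it is split.
    """

    window_size: int = 100_000
    smoothing_p: float = 1e-16
    p_units: str = "bp"
    min_segment_windows: int = 15
    g1_outlier_sd: float = 2.0
    min_g1_count: int = 1
    max_gap_windows: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.smoothing_p < 1.0:
            raise ValueError("smoothing_p must be in (0, 1)")
        if self.p_units not in ("bp", "window"):
            raise ValueError("p_units must be 'bp' or 'window'")
        if self.min_segment_windows < 1:
            raise ValueError("min_segment_windows must be >= 1")
        if self.g1_outlier_sd <= 0:
            raise ValueError("g1_outlier_sd must be positive")
        if self.max_gap_windows < 0:
            raise ValueError("max_gap_windows must be >= 0")

    @property
    def lam_window_units(self) -> float:
        """Roughness penalty for the spline solved in window-index units."""
        lam = (1.0 - self.smoothing_p) / self.smoothing_p
        if self.p_units == "bp":
            lam /= float(self.window_size) ** 3
        return lam


@dataclass
class RatioTrack:
    """Per-window values for each allele x replicate plus a shared mask.

    ``values`` has shape (n_windows, n_alleles, n_replicates); ``g1`` keeps
    the raw G1 counts for the allelic-balance outlier filter. ``informative``
    is a single mask shared by all samples.
    """

    windows: pd.DataFrame
    alleles: tuple[str, ...]
    replicates: tuple
    values: np.ndarray
    g1: np.ndarray
    informative: np.ndarray

    def copy(self) -> "RatioTrack":
        return RatioTrack(self.windows, self.alleles, self.replicates,
                          self.values.copy(), self.g1,
                          self.informative.copy())


@dataclass
class RTProfile:
    """Smoothed RT values on the window grid.

    ``segment`` labels each window with the id of the segment it belongs to,
    -1 for windows outside any retained segment. RT values are NaN outside
    retained segments. ``informative`` marks the windows whose data
    contributed to the fits (interpolated windows inside a segment carry RT
    values but are not informative).
    """

    windows: pd.DataFrame
    alleles: tuple[str, ...]
    replicates: tuple
    values: np.ndarray
    informative: np.ndarray
    segment: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def delta_rt(self) -> np.ndarray:
        """Mean RT difference allele[0] - allele[1] per window."""
        # plain mean: NaN propagates for windows outside retained segments
        return self.values[:, 0, :].mean(axis=1) - self.values[:, 1, :].mean(axis=1)


def counts_to_arrays(track: pd.DataFrame):
    """Pivot a long AlleleCountTrack into (windows, alleles, reps, S, G1)."""
    missing = [c for c in TRACK_COLUMNS if c not in track.columns]
    if missing:
        raise ValueError(f"count track missing columns: {missing}")
    bad = set(track["fraction"].unique()) - {"S", "G1"}
    if bad:
        raise ValueError(f"unknown fraction labels: {sorted(bad)}")

    alleles = tuple(pd.unique(track["allele"]))
    reps = tuple(sorted(pd.unique(track["replicate"])))
    if len(alleles) != 2:
        raise ValueError(f"expected exactly 2 alleles, got {alleles}")

    ref = None
    n_windows = 0
    shape = None
    s = g1 = None
    for ai, allele in enumerate(alleles):
        for ri, rep in enumerate(reps):
            for fraction, target in (("S", "s"), ("G1", "g1")):
                sub = track[(track["allele"] == allele)
                            & (track["replicate"] == rep)
                            & (track["fraction"] == fraction)]
                sub = sub.sort_index()
                grid = sub[["chrom", "start", "end"]].reset_index(drop=True)
                if ref is None:
                    ref = grid
                    n_windows = len(ref)
                    s = np.zeros((n_windows, len(alleles), len(reps)))
                    g1 = np.zeros_like(s)
                elif len(grid) != n_windows or not grid.equals(ref):
                    raise ValueError(
                        f"window grid mismatch for sample "
                        f"({allele}, rep {rep}, {fraction})")
                vals = sub["count"].to_numpy(dtype=float)
                if target == "s":
                    s[:, ai, ri] = vals
                else:
                    g1[:, ai, ri] = vals
    return ref, alleles, reps, s, g1


def s_over_g1(track: pd.DataFrame, min_g1_count: int = 1) -> RatioTrack:
    """Depth-normalized S/G1 ratio per window per allele per replicate.

    Each sample (allele x replicate x fraction) is scaled to reads per
    million before dividing. Windows where any sample has fewer than
    ``min_g1_count`` G1 reads or zero S reads are marked uninformative; their
    ratio is NaN.
    """
    windows, alleles, reps, s, g1 = counts_to_arrays(track)
    s_tot = s.sum(axis=0, keepdims=True)
    g_tot = g1.sum(axis=0, keepdims=True)
    if (s_tot == 0).any() or (g_tot == 0).any():
        raise ValueError("a sample has zero total reads")
    s_rpm = s / s_tot * 1e6
    g_rpm = g1 / g_tot * 1e6
    informative = ((g1 >= min_g1_count).all(axis=(1, 2))
                   & (s > 0).all(axis=(1, 2)))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = s_rpm / g_rpm
    ratio[~informative] = np.nan
    return RatioTrack(windows=windows, alleles=alleles, replicates=reps,
                      values=ratio, g1=g1, informative=informative)


def filter_g1_outliers(track: RatioTrack, threshold: float = 2.0) -> RatioTrack:
    """Mask windows with an outlying allelic G1 ratio.

    Copy-number differences between the alleles (e.g. strain deletions)
    distort the S/G1 ratio without reflecting replication timing, so windows
    whose log(G1 allele-a / G1 allele-b) lies more than ``threshold`` SDs from
    the genome mean are removed. The log ratio uses G1 counts summed over
    replicates.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = track.copy()
    g1a = track.g1[:, 0, :].sum(axis=1)
    g1b = track.g1[:, 1, :].sum(axis=1)
    usable = out.informative & (g1a > 0) & (g1b > 0)
    if usable.sum() < 3:
        raise ValueError("fewer than 3 informative windows; SD undefined")
    log_ratio = np.full(len(g1a), np.nan)
    log_ratio[usable] = np.log(g1a[usable] / g1b[usable])
    mean = np.nanmean(log_ratio[usable])
    sd = np.nanstd(log_ratio[usable], ddof=1)
    if sd == 0:
        return out
    outlier = usable & (np.abs(log_ratio - mean) > threshold * sd)
    out.informative &= ~outlier
    out.values[~out.informative] = np.nan
    return out


def normalize_rt(track: RatioTrack) -> RatioTrack:
    """log2 ratio, then per-sample z-score over informative autosomal windows."""
    out = track.copy()
    autosomal = track.windows["chrom"].map(is_autosome).to_numpy()
    fit = track.informative & autosomal
    if fit.sum() < 2:
        raise ValueError("not enough informative autosomal windows to normalize")
    with np.errstate(divide="ignore", invalid="ignore"):
        logv = np.log2(track.values)
    for a in range(logv.shape[1]):
        for r in range(logv.shape[2]):
            col = logv[:, a, r]
            mu = np.nanmean(col[fit])
            sd = np.nanstd(col[fit], ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(
                    f"zero variance in sample (allele {a}, replicate {r})")
            logv[:, a, r] = (col - mu) / sd
    out.values = logv
    out.values[~out.informative] = np.nan
    return out


def smoothing_spline(x: np.ndarray, y: np.ndarray, p: float):
    """Natural cubic smoothing spline for the csaps objective.

    Minimizes ``p * sum (y - f(x))^2 + (1 - p) * integral f''^2`` over natural
    cubic splines with knots at ``x`` and returns a callable spline.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("smoothing parameter p must be in (0, 1)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return make_smoothing_spline(x, y, lam=(1.0 - p) / p)


def _segments(informative: np.ndarray, max_gap: int, min_windows: int):
    """Split one chromosome's mask into retained segments.

    A segment is a run of windows from one informative window to another in
    which no internal gap of consecutive uninformative windows exceeds
    ``max_gap``; segments with fewer than ``min_windows`` informative windows
    are dropped.
    """
    idx = np.flatnonzero(informative)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
    pieces = np.split(idx, breaks + 1)
    return [p for p in pieces if p.size >= min_windows]


def smooth_interpolate(track: RatioTrack, config: RTConfig) -> RTProfile:
    """Fit the smoothing spline per segment and evaluate on the full grid.

    Only informative windows enter each fit (x = window index in window
    units); the fitted spline is evaluated across the segment span, filling
    interpolated values at masked interior windows. Windows outside retained
    segments get NaN.
    """
    n = len(track.windows)
    n_all, n_rep = track.values.shape[1], track.values.shape[2]
    values = np.full((n, n_all, n_rep), np.nan)
    segment = np.full(n, -1, dtype=int)
    retained_informative = np.zeros(n, dtype=bool)
    lam = config.lam_window_units

    seg_id = 0
    chrom_codes, chrom_first = pd.factorize(track.windows["chrom"])
    for ci in range(len(chrom_first)):
        sl = np.flatnonzero(chrom_codes == ci)
        lo = sl[0]
        mask = track.informative[sl]
        for piece in _segments(mask, config.max_gap_windows,
                               config.min_segment_windows):
            x_fit = piece.astype(float)
            span = np.arange(piece[0], piece[-1] + 1)
            for a in range(n_all):
                for r in range(n_rep):
                    y = track.values[lo + piece, a, r]
                    spl = make_smoothing_spline(x_fit, y, lam=lam)
                    values[lo + span, a, r] = spl(span.astype(float))
            segment[lo + span] = seg_id
            retained_informative[lo + piece] = True
            seg_id += 1

    return RTProfile(windows=track.windows, alleles=track.alleles,
                     replicates=track.replicates, values=values,
                     informative=retained_informative, segment=segment)


def profile_counts(track: pd.DataFrame, config: RTConfig | None = None) -> RTProfile:
    """Full profiling chain from a long count track to a smoothed RTProfile."""
    if config is None:
        config = RTConfig()
    ratio = s_over_g1(track, min_g1_count=config.min_g1_count)
    ratio = filter_g1_outliers(ratio, threshold=config.g1_outlier_sd)
    ratio = normalize_rt(ratio)
    return smooth_interpolate(ratio, config)
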