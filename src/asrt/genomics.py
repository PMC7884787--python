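"""Auxiliary genomics: read-depth CNV detection, allelic skew, saturation.

* :func:`detect_deletions` finds strain copy-number changes from window read
  depth relative to a reference strain (runs of at least two consecutive
  windows with depth ratio above 2 or below 1/2).
* :func:`allelic_skew` scores allele-specific RNA/ATAC read counts over AS
  regions and tests whether regions whose first allele replicates early are
  skewed toward that allele (one-sided Welch t).
* :func:`saturation_estimate` extrapolates the total number of AS domains
  from the cumulative unique-region count as clones are added.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "detect_deletions",
    "allelic_skew",
    "saturation_estimate",
    "SaturationFit",
]

logger = logging.getLogger(__name__)


def _rpm(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    if total == 0:
        raise ValueError("sample has zero total reads")
    return counts / total * 1e6


def detect_deletions(depth: pd.DataFrame, reference_samples: list[str],
                     samples: list[str] | None = None,
                     gain_ratio: float = 2.0, loss_ratio: float = 0.5,
                     min_windows: int = 2) -> pd.DataFrame:
    """Candidate copy-number intervals from window depth ratios.

    ``depth`` is a wide table: chrom, start, end plus one raw-count column per
    sample. Every sample is normalized to reads per million; each window's
    ratio is sample RPM over the mean reference RPM. Maximal runs of at least
    ``min_windows`` consecutive windows all above ``gain_ratio`` (gain) or all
    below ``loss_ratio`` (loss) are emitted. Windows where the reference has
    zero depth are masked and logged.
    """
    for col in ("chrom", "start", "end"):
        if col not in depth.columns:
            raise ValueError(f"depth table missing column {col!r}")
    for s in reference_samples:
        if s not in depth.columns:
            raise ValueError(f"reference sample {s!r} not in table")
    if samples is None:
        samples = [c for c in depth.columns
                   if c not in ("chrom", "start", "end")
                   and c not in reference_samples]

    ref = np.column_stack([_rpm(depth[s].to_numpy(dtype=float))
                           for s in reference_samples]).mean(axis=1)
    ref_ok = ref > 0
    if (~ref_ok).any():
        logger.warning("masking %d windows with zero reference depth",
                       int((~ref_ok).sum()))

    calls = []
    chrom_codes, chrom_names = pd.factorize(depth["chrom"])
    for sample in samples:
        rpm = _rpm(depth[sample].to_numpy(dtype=float))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(ref_ok, rpm / ref, np.nan)
        for direction, mask in (
            ("gain", ref_ok & (ratio > gain_ratio)),
            ("loss", ref_ok & (ratio < loss_ratio)),
        ):
            for ci in range(len(chrom_names)):
                sl = np.flatnonzero(chrom_codes == ci)
                sub = mask[sl]
                idx = np.flatnonzero(sub)
                if idx.size == 0:
                    continue
                breaks = np.flatnonzero(np.diff(idx) > 1)
                for run in np.split(idx, breaks + 1):
                    if run.size < min_windows:
                        continue
                    lo, hi = sl[run[0]], sl[run[-1]]
                    calls.append({
                        "chrom": chrom_names[ci],
                        "start": int(depth["start"].iloc[lo]),
                        "end": int(depth["end"].iloc[hi]),
                        "sample": sample,
                        "direction": direction,
                        "mean_ratio": float(np.nanmean(ratio[sl[run[0]]:sl[run[-1]] + 1])),
                        "n_windows": int(run.size),
                    })
    return pd.DataFrame(
        calls, columns=["chrom", "start", "end", "sample", "direction",
                        "mean_ratio", "n_windows"])


def filter_known_deletions(calls: pd.DataFrame, known: pd.DataFrame) -> pd.DataFrame:
    """Keep CNV calls overlapping a user-supplied BED of known deletions."""
    if calls.empty or known.empty:
        return calls.iloc[0:0]
    keep = []
    for _, r in calls.iterrows():
        same = known["chrom"] == r["chrom"]
        hit = ((known.loc[same, "start"] < r["end"])
               & (known.loc[same, "end"] > r["start"])).any()
        keep.append(bool(hit))
    return calls.loc[keep].reset_index(drop=True)


def allelic_skew(table: pd.DataFrame, pseudocount: float = 1.0,
                 early_label: str | None = None) -> tuple[pd.DataFrame, float]:
    """Per-window allelic skew and a one-sided Welch t-test by orientation.

    Skew is log2((count_a + c) / (count_b + c)). The test asks whether windows
    in regions where allele a replicates early (orientation ``early_label``,
    default the first orientation label encountered ending in ``_early``)
    have higher skew than those where allele b is early.
    """
    for col in ("count_a", "count_b", "orientation"):
        if col not in table.columns:
            raise ValueError(f"skew table missing column {col!r}")
    out = table.copy()
    out["skew"] = np.log2((out["count_a"] + pseudocount)
                          / (out["count_b"] + pseudocount))
    labels = out["orientation"].unique()
    if len(labels) != 2:
        raise ValueError(f"expected 2 orientation groups, got {list(labels)}")
    if early_label is None:
        early_label = sorted(labels)[0]
    x = out.loc[out["orientation"] == early_label, "skew"]
    y = out.loc[out["orientation"] != early_label, "skew"]
    if x.empty or y.empty:
        raise ValueError("an orientation group is empty")
    res = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
    return out, float(res.pvalue)


@dataclass
class SaturationFit:
    """Saturating-model fit of cumulative AS-region discovery."""

    model: str
    total: float
    params: dict
    fitted: np.ndarray
    residual_ss: float


def _saturating(n, a, k):
    return a * (1.0 - np.exp(-k * n))


def saturation_estimate(points, model: str = "saturating",
                        horizon: float = 20.0):
    """Extrapolate the total number of AS domains from discovery curves.

    ``points`` is a sequence of (n_clones, cumulative_unique_regions) with
    n_clones increasing. The default saturating model y = A (1 - exp(-k n))
    reports the asymptote A as the total; the ``log`` model y = a ln(n) + b
    reports its value at ``horizon`` clones. ``model="both"`` returns a dict
    with both fits.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (n_clones, n_regions) points")
    n, y = pts[:, 0], pts[:, 1]
    if (np.diff(n) <= 0).any():
        raise ValueError("n_clones must be strictly increasing")

    if model == "both":
        return {m: saturation_estimate(pts, model=m, horizon=horizon)
                for m in ("saturating", "log")}

    if model == "saturating":
        if np.allclose(y, y[0]):
            fitted = np.full_like(y, y[0])
            return SaturationFit("saturating", float(y[0]),
                                 {"A": float(y[0]), "k": np.inf}, fitted, 0.0)
        p0 = (max(y.max(), 1.0) * 1.5, 0.5)
        try:
            popt, _ = optimize.curve_fit(_saturating, n, y, p0=p0,
                                         maxfev=10_000)
        except RuntimeError as err:
            raise RuntimeError(
                f"saturating fit did not converge (p0={p0}): {err}") from err
        fitted = _saturating(n, *popt)
        return SaturationFit("saturating", float(popt[0]),
                             {"A": float(popt[0]), "k": float(popt[1])},
                             fitted, float(((y - fitted) ** 2).sum()))

    if model == "log":
        a, b = np.polyfit(np.log(n), y, 1)
        fitted = a * np.log(n) + b
        return SaturationFit("log", float(a * np.log(horizon) + b),
                             {"a": float(a), "b": float(b),
                              "horizon": float(horizon)},
                             fitted, float(((y - fitted) ** 2).sum()))

    raise ValueError("model must be 'saturating', 'log' or 'both'")
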