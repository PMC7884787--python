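"""Allelic replication asynchrony in single-cell binary replication data.

Each S-phase cell reports, per genomic bin (typically 400 kb) and per allele,
whether that allele has already replicated. A (cell, bin) event with exactly
one replicated allele is the sequencing analogue of a FISH single/double
nucleus. AS regions should show such one-allele events more often than
synchronous background; the analysis is restricted to autosomal bins whose
population mean RT lies strictly between -0.5 and 0.5 (mid-S), where both
replicated and unreplicated states are observable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiling import is_autosome

__all__ = [
    "SingleCellMatrix",
    "asynchrony_counts",
    "enrichment_chisq",
    "per_allele_direction",
]


@dataclass
class SingleCellMatrix:
    """cells x bins x 2 alleles binary replication states.

    ``states`` entries are 1.0 (replicated), 0.0 (unreplicated) or NaN
    (missing). ``bins`` carries chrom/start/end and the population
    ``mean_rt`` per bin on the -2..2 scale.
    """

    bins: pd.DataFrame
    states: np.ndarray
    s_position: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.states.ndim != 3 or self.states.shape[2] != 2:
            raise ValueError("states must have shape (cells, bins, 2)")
        if self.states.shape[1] != len(self.bins):
            raise ValueError("states and bins disagree on bin count")

    @property
    def n_cells(self) -> int:
        return self.states.shape[0]


def _mids_mask(m: SingleCellMatrix, lo: float = -0.5, hi: float = 0.5) -> np.ndarray:
    """Autosomal bins with mean RT strictly inside (lo, hi)."""
    auto = m.bins["chrom"].map(is_autosome).to_numpy()
    rt = m.bins["mean_rt"].to_numpy()
    return auto & (rt > lo) & (rt < hi)


def _bin_region_mask(bins: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(len(bins), dtype=bool)
    for _, r in regions.iterrows():
        mask |= ((bins["chrom"] == r["chrom"])
                 & (bins["start"] < r["end"])
                 & (bins["end"] > r["start"])).to_numpy()
    return mask


def asynchrony_counts(m: SingleCellMatrix, as_regions: pd.DataFrame,
                      sync_regions: pd.DataFrame | None = None,
                      ) -> pd.DataFrame:
    """2x2 table of (region class) x (one-allele vs both-same) events.

    Events are (cell, bin) pairs with both alleles observed, in mid-S
    autosomal bins. ``one_allele`` counts events where exactly one allele has
    replicated. AS bins are those overlapping ``as_regions``; the synchronous
    class is every other mid-S bin unless ``sync_regions`` is given.
    """
    mid = _mids_mask(m)
    as_bins = _bin_region_mask(m.bins, as_regions) & mid
    if sync_regions is None:
        sync_bins = mid & ~_bin_region_mask(m.bins, as_regions)
    else:
        sync_bins = _bin_region_mask(m.bins, sync_regions) & mid
    rows = {}
    for name, bins in (("as", as_bins), ("sync", sync_bins)):
        if not bins.any():
            raise ValueError(f"no mid-S bins in the {name!r} class")
        sub = m.states[:, bins, :]
        observed = ~np.isnan(sub).any(axis=2)
        one = (np.nansum(sub, axis=2) == 1) & observed
        n_obs = int(observed.sum())
        if n_obs == 0:
            raise ValueError(f"no fully observed events in the {name!r} class")
        n_one = int(one.sum())
        rows[name] = {"one_allele": n_one, "both_same": n_obs - n_one}
    return pd.DataFrame(rows).T[["one_allele", "both_same"]]


def enrichment_chisq(table: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def per_allele_direction(m: SingleCellMatrix, regions: pd.DataFrame,
                         alleles: tuple[str, str] = ("B6", "Cast"),
                         ) -> pd.DataFrame:
    """Per region: cells in which each allele alone has replicated.

    Counts (cell, bin) events inside the region (mid-S filtered) where only
    allele[0] or only allele[1] is replicated, summed over the region's bins.
    """
    mid = _mids_mask(m)
    rows = []
    for _, r in regions.iterrows():
        bins = _bin_region_mask(m.bins, pd.DataFrame([r])) & mid
        sub = m.states[:, bins, :]
        observed = ~np.isnan(sub).any(axis=2)
        a_only = (sub[:, :, 0] == 1) & (sub[:, :, 1] == 0) & observed
        b_only = (sub[:, :, 1] == 1) & (sub[:, :, 0] == 0) & observed
        rows.append({
            "chrom": r["chrom"], "start": r["start"], "end": r["end"],
            f"{alleles[0]}_early_cells": int(a_only.sum()),
            f"{alleles[1]}_early_cells": int(b_only.sum()),
        })
    return pd.DataFrame(rows)
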