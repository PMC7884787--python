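"""Replication-FISH dot-pattern statistics.

In S-phase nuclei an unreplicated locus hybridizes as a single dot and a
replicated one as a doublet, so a nucleus showing one single and one double
dot (SD pattern) marks a locus whose two alleles replicate asynchronously.
This module computes SD percentages, compares asynchronous probes against
synchronous controls (one-sided Mann-Whitney), tests orientation counts
against the fair-coin null (exact two-tailed binomial), and scores pairwise
parallel/antiparallel coordination between two probes on the same chromosome.
"""

from __future__ import annotations

from importlib import resources
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "percent_single_double",
    "compare_as_vs_sync",
    "orientation_binomial",
    "pairwise_coordination",
    "load_fish_survey",
]

# Largest number of group-membership arrangements enumerated exactly.
_MAX_ENUM = 200_000


def percent_single_double(n_ss: int, n_sd: int, n_dd: int) -> float:
    """Percentage of nuclei with the single/double pattern."""
    for v in (n_ss, n_sd, n_dd):
        if v < 0:
            raise ValueError("counts must be non-negative")
    total = n_ss + n_sd + n_dd
    if total == 0:
        raise ValueError("no nuclei counted")
    return 100.0 * n_sd / total


def _mannwhitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for x vs y with midrank tie handling."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def compare_as_vs_sync(as_percentages, sync_percentages) -> float:
    """One-sided Mann-Whitney p that asynchronous SD% exceed synchronous.

    For small groups (all arrangements enumerable) the p-value is the exact
    permutation tail P(U >= U_obs) over every assignment of the pooled values
    to groups, with ties contributing half-counts to U. Larger inputs use the
    normal approximation with tie correction.
    """
    x = np.asarray(list(as_percentages), dtype=float)
    y = np.asarray(list(sync_percentages), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    u_obs = _mannwhitney_u(x, y)
    if comb(n1 + n2, n1) <= _MAX_ENUM:
        pooled = np.concatenate([x, y])
        idx = range(n1 + n2)
        hits = 0
        total = 0
        for picks in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(picks)] = True
            u = _mannwhitney_u(pooled[mask], pooled[~mask])
            hits += u >= u_obs
            total += 1
        return hits / total
    res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return float(res.pvalue)


def orientation_binomial(k: int, n: int, method: str = "double_tail") -> float:
    """Exact two-tailed binomial p-value against success probability 1/2.

    ``double_tail`` doubles the smaller tail and caps at 1 (simple and
    reproducible); ``min_likelihood`` sums all outcomes no more likely than
    the observed one.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n with n >= 1")
    if method == "double_tail":
        lower = stats.binom.cdf(k, n, 0.5)
        upper = stats.binom.sf(k - 1, n, 0.5)
        return float(min(1.0, 2.0 * min(lower, upper)))
    if method == "min_likelihood":
        return float(stats.binomtest(k, n, 0.5).pvalue)
    raise ValueError("method must be 'double_tail' or 'min_likelihood'")


def pairwise_coordination(n_antiparallel: int, n_parallel: int,
                          ) -> tuple[float, float]:
    """Percent antiparallel among dual-SD nuclei and two-tailed binomial p.

    A nucleus is antiparallel when the single signal of one probe shares a
    homolog with the double signal of the other; parallel when both doubles
    sit on the same homolog. Under independent orientation the split is 1:1.
    """
    if n_antiparallel < 0 or n_parallel < 0:
        raise ValueError("counts must be non-negative")
    total = n_antiparallel + n_parallel
    if total == 0:
        raise ValueError("no dual single/double nuclei")
    percent = 100.0 * n_antiparallel / total
    return percent, orientation_binomial(n_antiparallel, total)


def load_fish_survey() -> pd.DataFrame:
    """Packaged FISH single/double survey of mouse pre-B clones and controls.

    A published per-probe survey of SD percentages across two hybrid pre-B
    clones (E-5, C2), a pure-strain clone (B4), ES cells, MEFs and human
    lymphoblasts, with probes classified as asynchronous or synchronous by
    whole-genome replication analysis. Columns: probe, chrom, population,
    sd_percent, n_nuclei, classification.
    """
    ref = resources.files("asrt.data").joinpath("fish_survey_table.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    expected = {"probe", "chrom", "population", "sd_percent", "n_nuclei",
                "classification"}
    if set(df.columns) != expected:
        raise ValueError("fish survey table has unexpected columns")
    return df
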