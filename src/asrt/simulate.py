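"""Synthetic allele-specific replication-timing data with known ground truth.

The generator emulates the statistical structure of an S/G1 replication-timing
experiment on clonal hybrid (B6 x Cast) cell populations:

* a smooth, autocorrelated baseline replication-timing (RT) landscape on the
  window grid, expressed on the conventional -2 (very late) .. +2 (very early)
  scale;
* implanted asynchronously replicating (AS) regions where the two alleles'
  RT differs by a fixed effect, with the identity of the early allele chosen
  independently per clone (or shared across clones on request);
* genetic differential regions, present with the same direction in every clone
  and in the pure parental strains;
* strain deletions that scale the affected allele's copy number;
* per-window Poisson S- and G1-fraction read counts per allele x replicate,
  where the S-phase expectation increases monotonically with RT;
* FISH single/double dot counts whose single/double rate grows with the local
  allelic RT difference, pairwise parallel/antiparallel assays, and
  orientation assays;
* binary single-cell replication matrices at 400 kb resolution;
* SNP catalogs and SNP-tagged reads, including occasional contradictory reads.

Everything is deterministic given the seed in :class:`SimParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .genome import GenomeSpec

__all__ = [
    "SimParams",
    "SyntheticTruth",
    "simulate_rt_landscape",
    "simulate_counts",
    "simulate_pure_strain_counts",
    "simulate_fish",
    "simulate_fish_pairwise",
    "simulate_fish_orientation",
    "simulate_single_cells",
    "simulate_snp_catalog",
    "simulate_tagged_reads",
    "rt_to_s_copy",
]

RT_MIN, RT_MAX = -2.0, 2.0


@dataclass(frozen=True)
class SimParams:
    """Generator parameters.

    Depths are mean reads per window per allele per replicate. ``rt_noise_sd``
    is the per-replicate Gaussian noise added to the RT track (in RT units)
    before conversion to S-phase copy number. FISH rates are probabilities;
    the single/double probability at a probe is
    ``fish_background_sd_rate + fish_as_sd_rate * |dRT|`` (clipped to [0, 1]).
    """

    n_clones: int = 3
    n_replicates: int = 3
    mean_g1_depth: float = 100.0
    mean_s_depth: float = 100.0
    rt_noise_sd: float = 0.25
    n_as_regions: int = 8
    as_region_length: int = 10
    as_effect: float = 1.0
    n_genetic_regions: int = 2
    genetic_region_length: int = 10
    genetic_effect: float = 1.0
    n_deletions: int = 2
    deletion_length: int = 4
    deletion_depth_ratio: float = 0.3
    contradictory_read_rate: float = 0.05
    snp_nocall_rate: float = 0.01
    fish_background_sd_rate: float = 0.15
    fish_as_sd_rate: float = 0.35
    fish_pair_flip_rate: float = 0.05
    sc_noise_sd: float = 0.25
    sc_missing_rate: float = 0.05
    sc_mid_s_range: tuple[float, float] = (0.25, 0.75)
    landscape_sd: float = 1.0
    landscape_corr_windows: float = 20.0
    shared_orientation: bool = False
    read_length: int = 250
    alleles: tuple[str, str] = ("B6", "Cast")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("deletion_depth_ratio", "contradictory_read_rate",
                     "snp_nocall_rate", "fish_background_sd_rate",
                     "fish_pair_flip_rate", "sc_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_g1_depth <= 0 or self.mean_s_depth <= 0:
            raise ValueError("depths must be positive")
        for name in ("rt_noise_sd", "fish_as_sd_rate", "sc_noise_sd",
                     "as_effect", "genetic_effect", "landscape_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n_clones < 1 or self.n_replicates < 1:
            raise ValueError("n_clones and n_replicates must be >= 1")
        if min(self.n_as_regions, self.n_genetic_regions, self.n_deletions) < 0:
            raise ValueError("region counts must be >= 0")
        if min(self.as_region_length, self.genetic_region_length,
               self.deletion_length) < 1:
            raise ValueError("region lengths must be >= 1 window")
        if abs(self.as_effect) > RT_MAX - RT_MIN \
                or abs(self.genetic_effect) > RT_MAX - RT_MIN:
            raise ValueError("effects cannot exceed the RT scale span (4)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SyntheticTruth:
    """Implanted ground truth for recovery scoring.

    ``clone_rt`` has shape (n_clones, n_windows, 2 alleles); ``pure_rt`` is the
    per-strain RT track of the pure parental lines (genetic effects only).
    ``as_orientations[r, c]`` is the allele index replicating early at AS
    region ``r`` in clone ``c``.
    """

    spec: GenomeSpec
    params: SimParams
    windows: pd.DataFrame
    baseline_rt: np.ndarray
    clone_rt: np.ndarray
    pure_rt: np.ndarray
    copy_number: np.ndarray
    pure_copy: np.ndarray
    as_regions: pd.DataFrame
    as_orientations: np.ndarray
    genetic_regions: pd.DataFrame
    deletions: pd.DataFrame

    def as_regions_for_clone(self, clone: int) -> pd.DataFrame:
        """Implanted AS intervals with this clone's early allele as name."""
        out = self.as_regions[["chrom", "start", "end"]].copy()
        alleles = self.params.alleles
        out["orientation"] = [
            f"{alleles[a]}_early" for a in self.as_orientations[:, clone]
        ]
        return out

    def region_window_mask(self, regions: pd.DataFrame) -> np.ndarray:
        """Boolean mask over the window grid covered by ``regions``."""
        mask = np.zeros(len(self.windows), dtype=bool)
        for _, row in regions.iterrows():
            mask |= (
                (self.windows["chrom"] == row["chrom"])
                & (self.windows["start"] < row["end"])
                & (self.windows["end"] > row["start"])
            ).to_numpy()
        return mask


def rt_to_s_copy(rt: np.ndarray) -> np.ndarray:
    """Monotone map from RT on [-2, 2] to relative S-phase copy number [1, 2].

    A locus replicating at the very start of S phase is present in two copies
    in almost every S cell (copy 2); a very late locus in one (copy 1). The
    map is log-linear, ``2 ** ((rt + 2) / 4)``, so a fixed RT difference
    produces the same fold-change in expected S depth anywhere on the RT
    scale; RT values outside [-2, 2] are clipped.
    """
    return 2.0 ** ((np.clip(rt, RT_MIN, RT_MAX) - RT_MIN) / (RT_MAX - RT_MIN))


def _place_regions(spec: GenomeSpec, lengths: list[int],
                   rng: np.random.Generator, min_gap: int = 5,
                   max_tries: int = 2000) -> list[tuple[str, int, int]]:
    """Place disjoint window-grid intervals (chrom, start_win, end_win).

    Implants are separated by at least ``min_gap`` windows so that distinct
    truth features stay distinguishable at the analysis smoothing bandwidth
    (a few windows); features closer than that are unresolvable in principle.
    """
    chroms = list(spec.chromosomes)
    n_win = {c: spec.n_windows(c) for c in chroms}
    need = sum(lengths) + min_gap * len(lengths)
    if need > sum(n_win.values()):
        raise ValueError(
            f"cannot place {len(lengths)} regions totalling {sum(lengths)} "
            f"windows in a {sum(n_win.values())}-window genome"
        )
    occupied = {c: np.zeros(n_win[c], dtype=bool) for c in chroms}
    weights = np.array([n_win[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: list[tuple[str, int, int]] = []
    for length in lengths:
        for attempt in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            if n_win[chrom] < length:
                continue
            start = int(rng.integers(0, n_win[chrom] - length + 1))
            lo = max(0, start - min_gap)
            hi = min(n_win[chrom], start + length + min_gap)
            if not occupied[chrom][lo:hi].any():
                occupied[chrom][start:start + length] = True
                placed.append((chrom, start, start + length))
                break
        else:
            raise ValueError(
                f"could not place a {length}-window region after "
                f"{max_tries} tries; genome too crowded"
            )
    return placed


def _regions_frame(spec: GenomeSpec, placed: list[tuple[str, int, int]]) -> pd.DataFrame:
    w = spec.window_size
    return pd.DataFrame(
        {
            "chrom": [c for c, _, _ in placed],
            "start": [s * w for _, s, _ in placed],
            "end": [e * w for _, _, e in placed],
        }
    )


def _grid_mask(spec: GenomeSpec, chrom: str, start_win: int, end_win: int) -> np.ndarray:
    mask = np.zeros(spec.total_windows, dtype=bool)
    sl = spec.chrom_slices()[chrom]
    mask[sl.start + start_win:sl.start + end_win] = True
    return mask


def simulate_rt_landscape(spec: GenomeSpec, params: SimParams,
                          rng: np.random.Generator | None = None) -> SyntheticTruth:
    """Draw the true RT landscape and implant AS/genetic regions and deletions.

    The baseline is a smoothed Gaussian track (correlation length
    ``landscape_corr_windows`` windows, sd ``landscape_sd``) shared by both
    alleles, clones and pure strains. Inside an AS region the early allele is
    shifted up and the late allele down by ``as_effect / 2`` each; genetic
    regions shift strains analogously in every clone and in the pure strains.
    All tracks are clipped to [-2, 2].
    """
    if rng is None:
        rng = params.rng()
    windows = spec.windows()
    total = len(windows)

    base = np.empty(total)
    for chrom, sl in spec.chrom_slices().items():
        n = sl.stop - sl.start
        white = rng.standard_normal(n)
        smooth = gaussian_filter1d(white, sigma=params.landscape_corr_windows,
                                   mode="reflect")
        sd = smooth.std()
        if sd > 0:
            smooth = smooth / sd * params.landscape_sd
        base[sl] = smooth
    base = np.clip(base, RT_MIN, RT_MAX)

    lengths = (
        [params.as_region_length] * params.n_as_regions
        + [params.genetic_region_length] * params.n_genetic_regions
        + [params.deletion_length] * params.n_deletions
    )
    placed = _place_regions(spec, lengths, rng) if lengths else []
    as_placed = placed[: params.n_as_regions]
    gen_placed = placed[params.n_as_regions:
                        params.n_as_regions + params.n_genetic_regions]
    del_placed = placed[params.n_as_regions + params.n_genetic_regions:]

    n_cl = params.n_clones
    clone_rt = np.broadcast_to(base[None, :, None], (n_cl, total, 2)).copy()
    pure_rt = np.broadcast_to(base[:, None], (total, 2)).copy()

    # AS regions: per-clone random early allele unless a shared map is asked for
    if params.shared_orientation:
        shared = rng.integers(0, 2, size=params.n_as_regions)
        orientations = np.tile(shared[:, None], (1, n_cl))
    else:
        orientations = rng.integers(0, 2, size=(params.n_as_regions, n_cl))
    # Implants recentre toward mid-S where needed so the allelic difference
    # is exactly the requested effect even near the scale bounds.
    half = params.as_effect / 2.0
    for r, (chrom, s, e) in enumerate(as_placed):
        m = _grid_mask(spec, chrom, s, e)
        center = np.clip(base[m], RT_MIN + half, RT_MAX - half)
        for c in range(n_cl):
            early = orientations[r, c]
            clone_rt[c, m, early] = center + half
            clone_rt[c, m, 1 - early] = center - half

    gen_dirs = rng.integers(0, 2, size=params.n_genetic_regions)
    ghalf = params.genetic_effect / 2.0
    for r, (chrom, s, e) in enumerate(gen_placed):
        m = _grid_mask(spec, chrom, s, e)
        center = np.clip(base[m], RT_MIN + ghalf, RT_MAX - ghalf)
        early = int(gen_dirs[r])
        clone_rt[:, m, early] = center + ghalf
        clone_rt[:, m, 1 - early] = center - ghalf
        pure_rt[m, early] = center + ghalf
        pure_rt[m, 1 - early] = center - ghalf

    copy_number = np.ones((n_cl, total, 2))
    pure_copy = np.ones((total, 2))
    del_strains = rng.integers(0, 2, size=params.n_deletions)
    for r, (chrom, s, e) in enumerate(del_placed):
        m = _grid_mask(spec, chrom, s, e)
        strain = int(del_strains[r])
        copy_number[:, m, strain] *= params.deletion_depth_ratio
        pure_copy[m, strain] *= params.deletion_depth_ratio

    alleles = params.alleles
    as_df = _regions_frame(spec, as_placed)
    gen_df = _regions_frame(spec, gen_placed)
    gen_df["orientation"] = [f"{alleles[d]}_early" for d in gen_dirs]
    del_df = _regions_frame(spec, del_placed)
    del_df["strain"] = [alleles[s] for s in del_strains]

    return SyntheticTruth(
        spec=spec, params=params, windows=windows, baseline_rt=base,
        clone_rt=clone_rt, pure_rt=pure_rt, copy_number=copy_number,
        pure_copy=pure_copy, as_regions=as_df, as_orientations=orientations,
        genetic_regions=gen_df, deletions=del_df,
    )


def _count_frame(windows: pd.DataFrame, allele: str, rep: int, fraction: str,
                 counts: np.ndarray) -> pd.DataFrame:
    out = windows.copy()
    out["allele"] = allele
    out["replicate"] = rep
    out["fraction"] = fraction
    out["count"] = counts
    return out


def simulate_counts(truth: SyntheticTruth, params: SimParams | None = None,
                    clones: list[int] | None = None,
                    rng: np.random.Generator | None = None,
                    ) -> dict[int, pd.DataFrame]:
    """Per-clone window count tracks (long TSV schema).

    G1 counts are Poisson(mean_g1_depth x copy number). S counts are
    Poisson(mean_s_depth x g(RT + replicate noise) / g(0) x copy number) with
    ``g`` the monotone RT -> [1, 2] relative-copy map; dividing by g(0) makes
    ``mean_s_depth`` the expected S depth of an RT = 0 window.
    """
    if params is None:
        params = truth.params
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    if clones is None:
        clones = list(range(params.n_clones))
    mid = rt_to_s_copy(np.array(0.0))
    out: dict[int, pd.DataFrame] = {}
    for c in clones:
        frames = []
        for a, allele in enumerate(params.alleles):
            for rep in range(1, params.n_replicates + 1):
                copy = truth.copy_number[c, :, a]
                g1 = rng.poisson(params.mean_g1_depth * copy)
                rt = truth.clone_rt[c, :, a] + rng.normal(
                    0.0, params.rt_noise_sd, size=len(copy))
                s_lam = params.mean_s_depth * rt_to_s_copy(rt) / mid * copy
                s = rng.poisson(s_lam)
                frames.append(_count_frame(truth.windows, allele, rep, "G1", g1))
                frames.append(_count_frame(truth.windows, allele, rep, "S", s))
        out[c] = pd.concat(frames, ignore_index=True)
    return out


def simulate_pure_strain_counts(truth: SyntheticTruth,
                                params: SimParams | None = None,
                                rng: np.random.Generator | None = None,
                                ) -> pd.DataFrame:
    """Count track for the two pure parental strains.

    Emitted in the AlleleCountTrack schema with the strain name in the
    ``allele`` column, so the same profiling machinery applies with groups =
    strain replicates. Only genetic effects (and deletions) are present.
    """
    if params is None:
        params = truth.params
    if rng is None:
        rng = np.random.default_rng(params.seed + 2)
    mid = rt_to_s_copy(np.array(0.0))
    frames = []
    for a, strain in enumerate(params.alleles):
        for rep in range(1, params.n_replicates + 1):
            copy = truth.pure_copy[:, a]
            g1 = rng.poisson(params.mean_g1_depth * copy)
            rt = truth.pure_rt[:, a] + rng.normal(
                0.0, params.rt_noise_sd, size=len(copy))
            s = rng.poisson(params.mean_s_depth * rt_to_s_copy(rt) / mid * copy)
            frames.append(_count_frame(truth.windows, strain, rep, "G1", g1))
            frames.append(_count_frame(truth.windows, strain, rep, "S", s))
    return pd.concat(frames, ignore_index=True)


def _probe_stats(truth: SyntheticTruth, probe: tuple[str, int, int],
                 clone: int) -> tuple[float, float]:
    chrom, start, end = probe
    if chrom not in truth.spec.chromosomes:
        raise ValueError(f"probe chromosome {chrom!r} not in genome")
    if start < 0 or end > truth.spec.chromosomes[chrom] or start >= end:
        raise ValueError(f"probe {probe} outside genome bounds")
    w = truth.windows
    m = ((w["chrom"] == chrom) & (w["start"] < end) & (w["end"] > start)).to_numpy()
    if not m.any():
        raise ValueError(f"probe {probe} covers no analysis window")
    rt = truth.clone_rt[clone][m]
    return float(rt[:, 0].mean() - rt[:, 1].mean()), float(rt.mean())


def simulate_fish(truth: SyntheticTruth, params: SimParams | None = None,
                  probes: list[tuple[str, int, int]] | None = None,
                  n_nuclei: int = 100, clone: int = 0,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Trinomial FISH dot-pattern counts per probe.

    The single/double probability is background + gain x |dRT| at the probe;
    the remaining mass splits between single/single and double/double
    according to how early the probe replicates on average.
    """
    if params is None:
        params = truth.params
    if rng is None:
        rng = np.random.default_rng(params.seed + 3)
    if probes is None:
        probes = [
            (r["chrom"], int(r["start"]), int(r["end"]))
            for _, r in truth.as_regions.iterrows()
        ]
    rows = []
    for i, probe in enumerate(probes):
        drt, mean_rt = _probe_stats(truth, probe, clone)
        p_sd = float(np.clip(
            params.fish_background_sd_rate + params.fish_as_sd_rate * abs(drt),
            0.0, 1.0))
        frac_early = (np.clip(mean_rt, RT_MIN, RT_MAX) - RT_MIN) / (RT_MAX - RT_MIN)
        p_dd = (1.0 - p_sd) * frac_early
        p_ss = max(1.0 - p_sd - p_dd, 0.0)
        n_ss, n_sd, n_dd = rng.multinomial(n_nuclei, [p_ss, p_sd, p_dd])
        rows.append(
            {"probe": f"probe_{i}", "chrom": probe[0], "start": probe[1],
             "end": probe[2], "n_ss": int(n_ss), "n_sd": int(n_sd),
             "n_dd": int(n_dd), "true_abs_delta_rt": abs(drt)}
        )
    return pd.DataFrame(rows)


def _probe_early_allele(truth: SyntheticTruth, probe: tuple[str, int, int],
                        clone: int) -> int:
    """Early-allele index of the AS region containing the probe midpoint."""
    chrom, start, end = probe
    mid = (start + end) // 2
    reg = truth.as_regions
    hit = reg[(reg["chrom"] == chrom) & (reg["start"] <= mid) & (reg["end"] > mid)]
    if hit.empty:
        raise ValueError(f"probe {probe} is not inside an implanted AS region")
    return int(truth.as_orientations[hit.index[0], clone])


def simulate_fish_pairwise(truth: SyntheticTruth,
                           probe_pairs: list[tuple[tuple[str, int, int],
                                                   tuple[str, int, int]]],
                           params: SimParams | None = None,
                           n_nuclei: int = 100, clone: int = 0,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Parallel/antiparallel labels for dual single/double nuclei.

    ``n_nuclei`` is the number of nuclei showing the single/double pattern at
    both probes. Each is labelled consistently with the truth orientation
    relation, flipped with probability ``fish_pair_flip_rate``.
    """
    if params is None:
        params = truth.params
    if rng is None:
        rng = np.random.default_rng(params.seed + 4)
    rows = []
    for pa, pb in probe_pairs:
        ea, eb = (_probe_early_allele(truth, p, clone) for p in (pa, pb))
        anti_truth = ea != eb
        p_anti = (1.0 - params.fish_pair_flip_rate) if anti_truth \
            else params.fish_pair_flip_rate
        n_anti = int(rng.binomial(n_nuclei, p_anti))
        rows.append(
            {"probe_a": str(pa), "probe_b": str(pb),
             "n_antiparallel": n_anti, "n_parallel": n_nuclei - n_anti,
             "true_relation": "antiparallel" if anti_truth else "parallel"}
        )
    return pd.DataFrame(rows)


def simulate_fish_orientation(truth: SyntheticTruth,
                              probes: list[tuple[str, int, int]],
                              params: SimParams | None = None,
                              n_nuclei: int = 100, population: str = "clone",
                              clone: int = 0, paternal: str | None = None,
                              rng: np.random.Generator | None = None,
                              ) -> pd.DataFrame:
    """Counts of nuclei with the paternal allele replicating early.

    In a clonal population the orientation is fixed, so the paternal-early
    fraction sits near 0 or 1; in a mixed pool both orientations are present
    and the fraction sits near 1/2.
    """
    if params is None:
        params = truth.params
    if rng is None:
        rng = np.random.default_rng(params.seed + 5)
    if paternal is None:
        paternal = params.alleles[1]
    pat_idx = params.alleles.index(paternal)
    rows = []
    for probe in probes:
        if population == "pool":
            p = 0.5
        elif population == "clone":
            early = _probe_early_allele(truth, probe, clone)
            p = (1.0 - params.fish_pair_flip_rate) if early == pat_idx \
                else params.fish_pair_flip_rate
        else:
            raise ValueError("population must be 'clone' or 'pool'")
        k = int(rng.binomial(n_nuclei, p))
        rows.append({"probe": str(probe), "k_paternal_early": k, "n": n_nuclei})
    return pd.DataFrame(rows)


def simulate_single_cells(truth: SyntheticTruth, n_cells: int,
                          params: SimParams | None = None,
                          bin_size: int = 400_000, clone: int = 0,
                          mid_s_only: bool = True,
                          rng: np.random.Generator | None = None):
    """Binary replication states (cells x bins x alleles) at ``bin_size``.

    Each cell sits at an S-phase position s; loci with RT above the moving
    threshold t = 2 - 4 s have replicated. Per-(cell, bin, allele) Gaussian
    noise on RT produces occasional discordant calls; ``sc_missing_rate``
    entries are dropped (NaN). With ``mid_s_only`` the S-phase positions are
    restricted to ``sc_mid_s_range``, emulating mid-S sorted cells.
    """
    from .singlecell import SingleCellMatrix

    if params is None:
        params = truth.params
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if bin_size % truth.spec.window_size != 0:
        raise ValueError("bin_size must be a multiple of the window size")
    if rng is None:
        rng = np.random.default_rng(params.seed + 6)
    k = bin_size // truth.spec.window_size

    bin_rows = []
    bin_rt = []
    for chrom, sl in truth.spec.chrom_slices().items():
        n_bins = (sl.stop - sl.start) // k
        for b in range(n_bins):
            lo = sl.start + b * k
            hi = lo + k
            bin_rows.append(
                {"chrom": chrom, "start": b * bin_size, "end": (b + 1) * bin_size}
            )
            bin_rt.append(truth.clone_rt[clone, lo:hi].mean(axis=0))
    bins = pd.DataFrame(bin_rows)
    allele_rt = np.array(bin_rt)          # (n_bins, 2)
    bins["mean_rt"] = allele_rt.mean(axis=1)

    lo_s, hi_s = params.sc_mid_s_range if mid_s_only else (0.0, 1.0)
    s_pos = rng.uniform(lo_s, hi_s, size=n_cells)
    thresh = RT_MAX - (RT_MAX - RT_MIN) * s_pos      # 2 - 4 s
    noise = rng.normal(0.0, params.sc_noise_sd,
                       size=(n_cells, len(bins), 2))
    states = (allele_rt[None, :, :] + noise
              > thresh[:, None, None]).astype(float)
    if params.sc_missing_rate > 0:
        miss = rng.random(states.shape) < params.sc_missing_rate
        states[miss] = np.nan
    return SingleCellMatrix(bins=bins, states=states, s_position=s_pos)


_BASES = np.array(list("ACGT"))


def simulate_snp_catalog(spec: GenomeSpec, params: SimParams,
                         rng: np.random.Generator | None = None,
                         bad_snp_rate: float = 0.1,
                         pileup_depth: float = 30.0) -> pd.DataFrame:
    """Discovery-pileup SNP catalog with a fraction of unreliable SNPs.

    Reliable SNPs draw their pileup counts from a balanced binomial; a
    ``bad_snp_rate`` fraction are heavily skewed (minor-allele fraction ~5%)
    and should be removed by the 20% minor-fraction filter.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 7)
    rows = []
    for chrom, length in spec.chromosomes.items():
        n_snps = int(spec.snp_density * length / 1000)
        pos = np.sort(rng.choice(length, size=min(n_snps, length), replace=False))
        for p in pos:
            a, b = rng.choice(4, size=2, replace=False)
            total = max(int(rng.poisson(pileup_depth)), 1)
            frac = 0.05 if rng.random() < bad_snp_rate else 0.5
            ca = int(rng.binomial(total, frac))
            rows.append(
                {"chrom": chrom, "pos": int(p),
                 "base_a": _BASES[a], "base_b": _BASES[b],
                 "count_a": ca, "count_b": total - ca}
            )
    return pd.DataFrame(rows)


def simulate_tagged_reads(spec: GenomeSpec, catalog: pd.DataFrame,
                          n_reads: int, params: SimParams,
                          rng: np.random.Generator | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """SNP-tagged reads with known allele labels.

    Returns (reads, observations, truth labels). Reads covering at least one
    catalog SNP carry that SNP's base for their true allele; with probability
    ``contradictory_read_rate`` a read covering >= 2 SNPs gets one base flipped
    to the opposite strain (truth label ``discarded``). Reads covering no SNP
    are labelled ``unassigned``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 8)
    chroms = list(spec.chromosomes)
    lens = np.array([spec.chromosomes[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    cat_by_chrom = {c: g.sort_values("pos").reset_index(drop=True)
                    for c, g in catalog.groupby("chrom")}
    alleles = params.alleles

    read_rows, obs_rows, labels = [], [], []
    for i in range(n_reads):
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        start = int(rng.integers(0, max(int(lens[ci]) - params.read_length, 1)))
        end = start + params.read_length
        read_id = f"read_{i}"
        read_rows.append({"read_id": read_id, "chrom": chrom,
                          "start": start, "end": end})
        cat = cat_by_chrom.get(chrom)
        covered = (cat[(cat["pos"] >= start) & (cat["pos"] < end)]
                   if cat is not None else None)
        if covered is None or covered.empty:
            labels.append("unassigned")
            continue
        true = int(rng.integers(0, 2))
        bases = [
            (r["base_a"] if true == 0 else r["base_b"])
            for _, r in covered.iterrows()
        ]
        label = alleles[true]
        if len(bases) >= 2 and rng.random() < params.contradictory_read_rate:
            j = int(rng.integers(0, len(bases)))
            row = covered.iloc[j]
            bases[j] = row["base_b"] if true == 0 else row["base_a"]
            label = "discarded"
        for (pos, base) in zip(covered["pos"], bases):
            if rng.random() < params.snp_nocall_rate:
                base = "N"
            obs_rows.append({"read_id": read_id, "chrom": chrom,
                             "pos": int(pos), "base": base})
        labels.append(label)

    reads = pd.DataFrame(read_rows)
    obs = pd.DataFrame(obs_rows, columns=["read_id", "chrom", "pos", "base"])
    return reads, obs, pd.Series(labels, index=reads["read_id"], name="truth")
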