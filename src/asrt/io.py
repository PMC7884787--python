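"""Validated readers/writers for the pipeline's tabular formats.

All interval formats are 0-based half-open. TSVs carry a header line; BED and
bedGraph do not. Malformed rows raise :class:`FormatError` with a 1-based
line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .profiling import RTProfile, TRACK_COLUMNS

__all__ = [
    "FormatError",
    "read_count_track",
    "write_count_track",
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "write_rt_profile",
    "read_fish_counts",
    "write_fish_counts",
    "read_single_cell_long",
    "write_single_cell_long",
]


class FormatError(ValueError):
    """A file did not conform to its declared schema."""


def _check_intervals(df: pd.DataFrame, path, header_lines: int) -> None:
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    bad = np.flatnonzero((starts < 0) | (starts >= ends))
    if bad.size:
        line = int(bad[0]) + header_lines + 1
        raise FormatError(
            f"{path}: line {line}: invalid interval "
            f"(start={starts[bad[0]]}, end={ends[bad[0]]}); "
            "coordinates must be 0-based half-open with start < end")


def read_count_track(path, one_based: bool = False) -> pd.DataFrame:
    """Read an AlleleCountTrack TSV (chrom, start, end, allele, replicate,
    fraction, count). ``one_based`` converts inclusive 1-based starts."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if one_based:
        df["start"] = df["start"] - 1
    _check_intervals(df, path, header_lines=1)
    if (df["count"] < 0).any():
        line = int(np.flatnonzero(df["count"] < 0)[0]) + 2
        raise FormatError(f"{path}: line {line}: negative count")
    return df


def write_count_track(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_bed(path, one_based: bool = False) -> pd.DataFrame:
    """Read BED3/BED6 into (chrom, start, end[, name, score, strand])."""
    path = Path(path)
    names = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :6]
    df.columns = names[: df.shape[1]]
    if one_based:
        df["start"] = df["start"] - 1
    _check_intervals(df, path, header_lines=0)
    return df


def write_bed(regions: pd.DataFrame, path, score_from: str = "max_abs_delta",
              name_from: str = "orientation") -> None:
    """Write regions as BED6: name = orientation, score = round(1000 x
    max |dRT|) clipped to [0, 1000], strand '.'."""
    out = regions[["chrom", "start", "end"]].copy()
    out["name"] = regions.get(name_from, ".")
    if score_from in regions:
        vals = pd.to_numeric(regions[score_from], errors="coerce").fillna(0)
        out["score"] = (1000 * vals).round().clip(0, 1000).astype(int)
    else:
        out["score"] = 0
    out["strand"] = "."
    out.to_csv(path, sep="\t", index=False, header=False)


def write_bedgraph(windows: pd.DataFrame, values: np.ndarray, path) -> None:
    """Write one sample's per-window values as bedGraph, skipping NaN."""
    mask = np.isfinite(values)
    out = windows.loc[mask, ["chrom", "start", "end"]].copy()
    out["value"] = np.asarray(values)[mask]
    out.to_csv(path, sep="\t", index=False, header=False,
               float_format="%.6g")


def write_rt_profile(profile: RTProfile, out_dir, prefix: str = "rt") -> list[Path]:
    """One bedGraph per allele x replicate plus a combined TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    combined = profile.windows.copy()
    for a, allele in enumerate(profile.alleles):
        for r, rep in enumerate(profile.replicates):
            col = profile.values[:, a, r]
            name = out_dir / f"{prefix}_{allele}_rep{rep}.bedgraph"
            write_bedgraph(profile.windows, col, name)
            written.append(name)
            combined[f"rt_{allele}_rep{rep}"] = col
    combined["informative"] = profile.informative
    combined["segment"] = profile.segment
    tsv = out_dir / f"{prefix}_profile.tsv"
    combined.to_csv(tsv, sep="\t", index=False, float_format="%.6g")
    written.append(tsv)
    return written


FISH_COLUMNS = ["probe", "n_ss", "n_sd", "n_dd"]


def read_fish_counts(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FISH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    counts = df[["n_ss", "n_sd", "n_dd"]].to_numpy()
    bad = np.flatnonzero((counts < 0).any(axis=1))
    if bad.size:
        raise FormatError(f"{path}: line {int(bad[0]) + 2}: negative count")
    return df


def write_fish_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


SC_COLUMNS = ["cell", "chrom", "start", "end", "allele", "state"]


def write_single_cell_long(matrix, alleles: tuple[str, str], path) -> None:
    """Long-format TSV (cell, chrom, start, end, allele, state); missing
    entries are omitted."""
    bins = matrix.bins
    rows = []
    for c in range(matrix.n_cells):
        for a, allele in enumerate(alleles):
            states = matrix.states[c, :, a]
            ok = np.isfinite(states)
            part = bins.loc[ok, ["chrom", "start", "end"]].copy()
            part.insert(0, "cell", f"cell_{c}")
            part["allele"] = allele
            part["state"] = states[ok].astype(int)
            rows.append(part)
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_single_cell_long(path, mean_rt: pd.DataFrame | None = None):
    """Read the long format back into a SingleCellMatrix.

    ``mean_rt``, if given, is a (chrom, start, end, mean_rt) table; otherwise
    the per-bin mean RT is set to 0 (callers must then supply their own mid-S
    filtering information).
    """
    from .singlecell import SingleCellMatrix

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    cells = list(pd.unique(df["cell"]))
    alleles = list(pd.unique(df["allele"]))
    if len(alleles) != 2:
        raise FormatError(f"{path}: expected 2 alleles, got {alleles}")
    bins = (df[["chrom", "start", "end"]].drop_duplicates()
            .sort_values(["chrom", "start"], kind="stable")
            .reset_index(drop=True))
    bin_key = {(r.chrom, r.start): i for i, r in
               enumerate(bins.itertuples(index=False))}
    states = np.full((len(cells), len(bins), 2), np.nan)
    cell_idx = {c: i for i, c in enumerate(cells)}
    allele_idx = {a: i for i, a in enumerate(alleles)}
    for row in df.itertuples(index=False):
        states[cell_idx[row.cell], bin_key[(row.chrom, row.start)],
               allele_idx[row.allele]] = float(row.state)
    if mean_rt is not None:
        bins = bins.merge(mean_rt, on=["chrom", "start", "end"], how="left")
    else:
        bins["mean_rt"] = 0.0
    return SingleCellMatrix(bins=bins, states=states)
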