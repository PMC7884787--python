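"""SNP filtering and read-to-allele assignment for hybrid genomes.

Two-step protocol: first retain only SNPs whose minor allele is well
represented in the discovery pileup (so both parental bases are genuinely
observed, avoiding reference-mapping bias), then label each read by the strain
of the SNP bases it carries. Reads carrying confident bases from both strains
are discarded as likely PCR template-switching artefacts; reads covering no
retained SNP stay unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSpec

__all__ = ["filter_snps", "assign_reads", "AssignmentResult"]

logger = logging.getLogger(__name__)

SNP_COLUMNS = ["chrom", "pos", "base_a", "base_b", "count_a", "count_b"]
LABELS = ("A", "B", "unassigned", "discarded")


def filter_snps(catalog: pd.DataFrame, min_fraction: float = 0.20) -> pd.DataFrame:
    """Keep SNPs whose minor-allele pileup fraction is >= ``min_fraction``.

    The boundary is inclusive: a SNP at exactly the threshold is retained.
    SNPs with zero total coverage are dropped with a logged warning. Row order
    is preserved.
    """
    if not 0 <= min_fraction <= 0.5:
        raise ValueError("min_fraction must be in [0, 0.5]")
    missing = [c for c in SNP_COLUMNS if c not in catalog.columns]
    if missing:
        raise ValueError(f"catalog missing columns: {missing}")
    ca = catalog["count_a"].to_numpy(dtype=float)
    cb = catalog["count_b"].to_numpy(dtype=float)
    if (ca < 0).any() or (cb < 0).any():
        raise ValueError("negative pileup counts")
    total = ca + cb
    zero = total == 0
    if zero.any():
        logger.warning("dropping %d SNPs with zero pileup coverage",
                       int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        minor = np.minimum(ca, cb) / np.where(total > 0, total, np.nan)
    keep = ~zero & (minor >= min_fraction)
    return catalog.loc[keep].reset_index(drop=True)


@dataclass
class AssignmentResult:
    """Per-read labels plus per-window allele counts.

    ``labels`` maps read_id -> one of A / B / unassigned / discarded, where
    A and B are the catalog's strain-a and strain-b. ``window_counts`` bins
    assigned reads by read start on the genome window grid.
    """

    labels: pd.Series
    window_counts: pd.DataFrame
    discarded_fraction: float
    nocall_bases: int

    def counts(self) -> dict[str, int]:
        vc = self.labels.value_counts()
        return {lab: int(vc.get(lab, 0)) for lab in LABELS}


def assign_reads(reads: pd.DataFrame, observations: pd.DataFrame,
                 catalog: pd.DataFrame, spec: GenomeSpec | None = None,
                 allele_names: tuple[str, str] = ("A", "B"),
                 ) -> AssignmentResult:
    """Label reads by the parental strain of their SNP bases.

    Parameters
    ----------
    reads
        One row per read: read_id, chrom, start, end.
    observations
        One row per (read, SNP) base call: read_id, chrom, pos, base.
        Positions not in the (already filtered) catalog are ignored; bases
        matching neither catalog allele are no-calls and never make a read
        contradictory.
    catalog
        Filtered SNP catalog (see :func:`filter_snps`).
    spec
        If given, assigned reads are binned by start coordinate on the window
        grid and returned as an AlleleCountTrack-style frame.
    """
    for col in ("read_id", "chrom", "start", "end"):
        if col not in reads.columns:
            raise ValueError(f"reads missing column {col!r}")

    key = catalog.set_index(["chrom", "pos"])
    votes_a = pd.Series(0, index=reads["read_id"], dtype=int)
    votes_b = pd.Series(0, index=reads["read_id"], dtype=int)
    nocall = 0
    if len(observations):
        obs = observations.merge(
            catalog[["chrom", "pos", "base_a", "base_b"]],
            on=["chrom", "pos"], how="inner",
        )
        is_a = obs["base"] == obs["base_a"]
        is_b = obs["base"] == obs["base_b"]
        nocall = int((~is_a & ~is_b).sum())
        if nocall:
            logger.warning(
                "%d SNP observations matched neither catalog base (no-calls)",
                nocall)
        va = obs.loc[is_a, "read_id"].value_counts()
        vb = obs.loc[is_b, "read_id"].value_counts()
        votes_a = votes_a.add(va.reindex(votes_a.index, fill_value=0),
                              fill_value=0).astype(int)
        votes_b = votes_b.add(vb.reindex(votes_b.index, fill_value=0),
                              fill_value=0).astype(int)

    labels = pd.Series("unassigned", index=reads["read_id"], name="label")
    labels[(votes_a > 0) & (votes_b == 0)] = "A"
    labels[(votes_b > 0) & (votes_a == 0)] = "B"
    labels[(votes_a > 0) & (votes_b > 0)] = "discarded"

    n = len(reads)
    discarded = float((labels == "discarded").sum() / n) if n else 0.0
    logger.info("assigned %d reads: %.2f%% discarded as contradictory",
                n, 100 * discarded)

    window_counts = pd.DataFrame(
        columns=["chrom", "start", "end", "allele", "count"])
    if spec is not None and n:
        assigned = reads.assign(label=labels.to_numpy())
        assigned = assigned[assigned["label"].isin(["A", "B"])]
        grid = spec.windows()
        w = spec.window_size
        rows = []
        for (lab, name) in zip(("A", "B"), allele_names):
            sub = assigned[assigned["label"] == lab]
            counts = np.zeros(len(grid), dtype=int)
            for chrom, g in sub.groupby("chrom"):
                if chrom not in spec.chromosomes:
                    raise ValueError(f"read chromosome {chrom!r} not in genome")
                sl = spec.chrom_slices()[chrom]
                idx = (g["start"] // w).to_numpy()
                idx = idx[idx < (sl.stop - sl.start)]
                np.add.at(counts, sl.start + idx, 1)
            part = grid.copy()
            part["allele"] = name
            part["count"] = counts
            rows.append(part)
        window_counts = pd.concat(rows, ignore_index=True)

    return AssignmentResult(labels=labels, window_counts=window_counts,
                            discarded_fraction=discarded, nocall_bases=nocall)
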