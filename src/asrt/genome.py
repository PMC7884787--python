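"""Genome window grids.

All coordinates are 0-based half-open (BED convention). The analysis grid is a
fixed tiling of each chromosome into windows of ``window_size`` bp; the last,
partial window of a chromosome is dropped so every window has equal length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeSpec"]


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names/lengths plus the analysis window size.

    Parameters
    ----------
    chromosomes
        Mapping of chromosome name to length in bp. Names containing ``X`` or
        ``Y`` (e.g. ``chrX``) are treated as sex chromosomes; everything else
        is autosomal.
    window_size
        Analysis window size in bp (default 100 kb).
    snp_density
        Informative SNPs per kb, used only by the read-level simulator.
    """

    chromosomes: dict[str, int]
    window_size: int = 100_000
    snp_density: float = 0.5

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome is required")
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.snp_density < 0:
            raise ValueError("snp_density must be >= 0")

    def n_windows(self, chrom: str) -> int:
        return self.chromosomes[chrom] // self.window_size

    @property
    def total_windows(self) -> int:
        return sum(self.n_windows(c) for c in self.chromosomes)

    def is_autosome(self, chrom: str) -> bool:
        tail = chrom.removeprefix("chr").upper()
        return tail not in {"X", "Y"}

    def windows(self) -> pd.DataFrame:
        """Window grid as a (chrom, start, end) frame in genome order."""
        frames = []
        for chrom in self.chromosomes:
            n = self.n_windows(chrom)
            starts = np.arange(n, dtype=np.int64) * self.window_size
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": starts + self.window_size}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def window_index(self, chrom: str, pos: int) -> int:
        """Global (genome-order) index of the window containing ``pos``."""
        if chrom not in self.chromosomes:
            raise KeyError(chrom)
        if not 0 <= pos < self.chromosomes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        local = pos // self.window_size
        if local >= self.n_windows(chrom):
            raise ValueError(f"position {pos} falls in the dropped partial window")
        offset = 0
        for c in self.chromosomes:
            if c == chrom:
                break
            offset += self.n_windows(c)
        return offset + local

    def chrom_slices(self) -> dict[str, slice]:
        """Global-index slice of each chromosome on the window grid."""
        out: dict[str, slice] = {}
        at = 0
        for chrom in self.chromosomes:
            n = self.n_windows(chrom)
            out[chrom] = slice(at, at + n)
            at += n
        return out


def default_genome(n_chromosomes: int = 4, n_windows: int = 500,
                   window_size: int = 100_000) -> GenomeSpec:
    """Convenience synthetic genome: equal-sized autosomes on the grid."""
    return GenomeSpec(
        {f"chr{i + 1}": n_windows * window_size for i in range(n_chromosomes)},
        window_size=window_size,
    )
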