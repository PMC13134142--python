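"""Genome bin grids.

A :class:`GenomeSpec` describes a set of chromosomes with lengths and a single
bin resolution.  All genomic coordinates in this package are 0-based,
half-open.  Bins are dense and ordered by (chromosome order as given, start),
and every binned data structure (contact matrices, per-bin tracks, bead
profiles) indexes into the same global bin table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names/lengths (bp) plus a bin resolution (bp).

    Parameters
    ----------
    chromosomes:
        Mapping of chromosome name to length in bp, in genome order.
    resolution:
        Bin size in bp.  The last bin of each chromosome may be shorter.
    """

    chromosomes: dict[str, int]
    resolution: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chromosomes)

    def nbins_of(self, chrom: str) -> int:
        return -(-self.chromosomes[chrom] // self.resolution)  # ceil div

    @property
    def nbins(self) -> int:
        return sum(self.nbins_of(c) for c in self.chromosomes)

    def bins(self) -> pd.DataFrame:
        """Dense bin table with columns chrom, start, end, index."""
        rows = []
        for chrom, length in self.chromosomes.items():
            starts = np.arange(0, length, self.resolution, dtype=np.int64)
            ends = np.minimum(starts + self.resolution, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        table = pd.concat(rows, ignore_index=True)
        table["index"] = np.arange(len(table), dtype=np.int64)
        return table

    def chrom_slice(self, chrom: str) -> slice:
        """Global-index slice covering one chromosome's bins."""
        offset = 0
        for name in self.chromosomes:
            n = self.nbins_of(name)
            if name == chrom:
                return slice(offset, offset + n)
            offset += n
        raise KeyError(chrom)

    def chrom_of_bins(self) -> np.ndarray:
        """Per-bin chromosome name as an object array (length nbins)."""
        out = np.empty(self.nbins, dtype=object)
        for chrom in self.chromosomes:
            out[self.chrom_slice(chrom)] = chrom
        return out

    def bin_index(self, chrom: str, start: int) -> int:
        if start % self.resolution != 0:
            raise ValueError(
                f"start {start} is not a multiple of resolution {self.resolution}"
            )
        sl = self.chrom_slice(chrom)
        i = start // self.resolution
        if i >= sl.stop - sl.start:
            raise ValueError(f"start {start} beyond chromosome {chrom}")
        return sl.start + i
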