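"""Genome bin tables: the coordinate backbone of binned Hi-C matrices.

A :class:`BinTable` partitions each chromosome into fixed-width bins.
Every bin spans ``resolution`` bp except possibly the last bin of a
chromosome, and the global bin index is sorted by (chromosome order,
start coordinate). All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

__all__ = ["BinTable", "make_bins"]


class BinTable:
    """Tiling of a genome into fixed-width bins.

    Parameters
    ----------
    chrom_sizes
        Mapping of chromosome name to length in bp. Order is preserved
        and defines the global bin order.
    resolution
        Bin width in bp (> 0).
    """

    def __init__(self, chrom_sizes: Mapping[str, int], resolution: int):
        resolution = int(resolution)
        if resolution <= 0:
            raise ValueError(f"resolution must be positive, got {resolution}")
        self.resolution = resolution
        self.chrom_sizes: dict[str, int] = {}
        for chrom, size in chrom_sizes.items():
            size = int(size)
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive size {size}")
            self.chrom_sizes[str(chrom)] = size

        chroms, starts, ends = [], [], []
        self._slices: dict[str, slice] = {}
        offset = 0
        for chrom, size in self.chrom_sizes.items():
            n = -(-size // resolution)  # ceil division
            s = np.arange(n, dtype=np.int64) * resolution
            e = np.minimum(s + resolution, size)
            chroms.extend([chrom] * n)
            starts.append(s)
            ends.append(e)
            self._slices[chrom] = slice(offset, offset + n)
            offset += n
        self.chrom = np.array(chroms, dtype=object)
        self.start = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
        self.end = np.concatenate(ends) if ends else np.empty(0, dtype=np.int64)

    # -- basic container protocol ------------------------------------
    def __len__(self) -> int:
        return self.start.size

    @property
    def n_bins(self) -> int:
        return len(self)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    @property
    def chrom_slices(self) -> dict[str, slice]:
        """Mapping chromosome -> slice of global bin indices."""
        return dict(self._slices)

    def chrom_offset(self, chrom: str) -> int:
        return self._slices[chrom].start

    def n_chrom_bins(self, chrom: str) -> int:
        sl = self._slices[chrom]
        return sl.stop - sl.start

    def chrom_of(self, index: int) -> str:
        if not 0 <= index < len(self):
            raise IndexError(f"bin index {index} out of range")
        return self.chrom[index]

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing genomic position ``pos``."""
        if chrom not in self._slices:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom} (size {self.chrom_sizes[chrom]})")
        return self._slices[chrom].start + pos // self.resolution

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "start": self.start, "end": self.end})

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinTable):
            return NotImplemented
        return self.resolution == other.resolution and self.chrom_sizes == other.chrom_sizes

    def __repr__(self) -> str:
        return (
            f"BinTable({len(self.chrom_sizes)} chromosomes, {len(self)} bins, "
            f"resolution={self.resolution})"
        )


def make_bins(chrom_sizes: Mapping[str, int], resolution: int) -> BinTable:
    """Partition a genome into fixed-width bins.

    The total bin count is ``sum(ceil(size / resolution))`` over
    chromosomes; the last bin of a chromosome may be narrower than
    ``resolution``.
    """
    return BinTable(chrom_sizes, resolution)
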