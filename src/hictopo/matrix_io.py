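"""Contact matrices and the text interchange formats around them.

The on-disk dialects are the ones HiC-Pro emits at the end of its
binning stage: a BED-like bin table (chrom, start, end, 1-based bin id)
plus a whitespace-separated sparse triplet file (id_a, id_b, count,
upper triangle). Internally everything is 0-based, half-open and dense;
conversion happens only at the file boundary. BED3+, BEDPE and bedGraph
readers/writers cover peak intervals, loop anchors and per-bin tracks.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bins import BinTable

__all__ = [
    "ContactMatrix",
    "FormatError",
    "read_sparse_triplet",
    "write_sparse_triplet",
    "read_intervals",
    "read_bedgraph",
    "write_bedgraph",
    "read_dense",
    "write_dense",
]

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass
class ContactMatrix:
    """Symmetric contact counts (or derived values) over a bin table.

    Attributes
    ----------
    bins
        The genome partition the matrix is indexed by.
    counts
        Dense symmetric (n, n) array. Raw counts are non-negative;
        derived matrices (balanced, O/E) may contain NaN for undefined
        pixels.
    mask
        Boolean per-bin exclusion flags (True = excluded from analysis).
    weights
        Optional per-bin balancing weights; positive on unmasked bins,
        NaN on masked bins. The balanced value of pixel (i, j) is
        ``weights[i] * weights[j] * counts[i, j]``.
    meta
        Free-form provenance (seed, value space, convergence flags...).
    """

    bins: BinTable
    counts: np.ndarray
    mask: np.ndarray = None
    weights: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.bins)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (n, n):
            raise ValueError(f"counts shape {self.counts.shape} != ({n}, {n})")
        finite = np.isfinite(self.counts)
        both = finite & finite.T
        if not np.allclose(self.counts[both], self.counts.T[both], rtol=1e-8, atol=1e-8):
            raise ValueError("counts matrix is not symmetric")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ValueError("mask must be a per-bin boolean vector")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (n,):
                raise ValueError("weights must be a per-bin vector")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def is_balanced(self) -> bool:
        return self.weights is not None

    def balanced(self) -> np.ndarray:
        """Dense balanced matrix with NaN on masked rows/columns.

        If no weights are present the (masked) raw counts are returned —
        useful for synthetic matrices that are uniform-coverage by
        construction.
        """
        if self.weights is None:
            out = self.counts.astype(float, copy=True)
        else:
            w = np.where(self.mask, np.nan, self.weights)
            out = self.counts * np.outer(w, w)
        out[self.mask, :] = np.nan
        out[:, self.mask] = np.nan
        return out

    def cis_slice(self, chrom: str) -> slice:
        return self.bins.chrom_slices[chrom]

    def scaled(self, factor: float) -> "ContactMatrix":
        """Raw counts multiplied by a positive scalar (read-depth change)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return ContactMatrix(self.bins, self.counts * factor, self.mask.copy(),
                             None, dict(self.meta))


# ---------------------------------------------------------------------------
# HiC-Pro sparse triplet dialect
# ---------------------------------------------------------------------------

def _bins_from_bed(path) -> BinTable:
    chrom_sizes: dict[str, int] = {}
    widths = []
    expected_id = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns (chrom start end id)")
            chrom, start, end, bid = parts[0], int(parts[1]), int(parts[2]), int(parts[3])
            expected_id += 1
            if bid != expected_id:
                raise FormatError(f"{path}:{lineno}: bin ids must be consecutive and 1-based "
                                  f"(got {bid}, expected {expected_id})")
            if end <= start:
                raise FormatError(f"{path}:{lineno}: empty or inverted bin [{start}, {end})")
            if chrom in chrom_sizes and start != chrom_sizes[chrom]:
                raise FormatError(f"{path}:{lineno}: bins do not tile {chrom} (gap/overlap at {start})")
            if chrom not in chrom_sizes and start != 0:
                raise FormatError(f"{path}:{lineno}: first bin of {chrom} does not start at 0")
            chrom_sizes[chrom] = end
            widths.append(end - start)
    if not chrom_sizes:
        raise FormatError(f"{path}: no bins found")
    resolution = Counter(widths).most_common(1)[0][0]
    table = BinTable(chrom_sizes, resolution)
    if len(table) != expected_id:
        raise FormatError(f"{path}: bin widths inconsistent with a fixed resolution of {resolution}")
    return table


def read_sparse_triplet(bins_path, matrix_path) -> ContactMatrix:
    """Read a HiC-Pro style bin table + sparse triplet matrix.

    Triplets may cover the upper triangle or the full matrix; duplicate
    pairs (including mirrored duplicates) are summed. Unknown bin ids and
    negative counts raise :class:`FormatError` naming the line.
    """
    bins = _bins_from_bed(bins_path)
    n = len(bins)
    counts = np.zeros((n, n))
    with open(matrix_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{matrix_path}:{lineno}: expected 3 columns")
            try:
                a, b, v = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{matrix_path}:{lineno}: {exc}") from None
            if not (1 <= a <= n and 1 <= b <= n):
                raise FormatError(f"{matrix_path}:{lineno}: unknown bin id on line {lineno!r}: "
                                  f"({a}, {b}) with {n} bins")
            if v < 0:
                raise FormatError(f"{matrix_path}:{lineno}: negative count {v}")
            i, j = a - 1, b - 1
            counts[i, j] += v
            if i != j:
                counts[j, i] += v
    return ContactMatrix(bins, counts)


def write_sparse_triplet(matrix: ContactMatrix, bins_path, matrix_path) -> None:
    """Write the HiC-Pro dialect: 1-based ids, upper triangle, zeros omitted."""
    bins = matrix.bins
    with open(bins_path, "w") as fh:
        for i in range(len(bins)):
            fh.write(f"{bins.chrom[i]}\t{bins.start[i]}\t{bins.end[i]}\t{i + 1}\n")
    iu, ju = np.triu_indices(len(bins))
    vals = matrix.counts[iu, ju]
    keep = np.isfinite(vals) & (vals != 0)
    with open(matrix_path, "w") as fh:
        for i, j, v in zip(iu[keep], ju[keep], vals[keep]):
            v_str = str(int(v)) if float(v).is_integer() else repr(float(v))
            fh.write(f"{i + 1}\t{j + 1}\t{v_str}\n")


# ---------------------------------------------------------------------------
# Interval formats
# ---------------------------------------------------------------------------

def read_intervals(path, kind: str = "bed", permissive: bool = False) -> pd.DataFrame:
    """Read BED3+ or BEDPE intervals (0-based half-open).

    BED rows are validated (start < end) and sorted; BEDPE anchor pairs
    are normalized so anchor A <= anchor B. Malformed lines raise
    :class:`FormatError` with the line number unless ``permissive`` is
    set, in which case they are counted and logged.
    """
    if kind not in ("bed", "bedpe"):
        raise ValueError(f"kind must be 'bed' or 'bedpe', got {kind!r}")
    ncol = 3 if kind == "bed" else 6
    rows, rejected = [], 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            try:
                if len(parts) < ncol:
                    raise FormatError(f"{path}:{lineno}: expected >= {ncol} columns")
                if kind == "bed":
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    if start >= end:
                        raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
                    rows.append((chrom, start, end))
                else:
                    c1, s1, e1 = parts[0], int(parts[1]), int(parts[2])
                    c2, s2, e2 = parts[3], int(parts[4]), int(parts[5])
                    if s1 >= e1 or s2 >= e2:
                        raise FormatError(f"{path}:{lineno}: inverted anchor interval")
                    if (c2, s2, e2) < (c1, s1, e1):
                        c1, s1, e1, c2, s2, e2 = c2, s2, e2, c1, s1, e1
                    rows.append((c1, s1, e1, c2, s2, e2))
            except (FormatError, ValueError) as exc:
                if permissive:
                    rejected += 1
                    log.warning("skipping line %d of %s: %s", lineno, path, exc)
                else:
                    if isinstance(exc, FormatError):
                        raise
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
    if kind == "bed":
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    else:
        df = pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"])
        df = df.sort_values(list(df.columns), kind="stable").reset_index(drop=True)
    df.attrs["n_rejected"] = rejected
    return df


# ---------------------------------------------------------------------------
# Per-bin tracks (bedGraph) and dense debug export
# ---------------------------------------------------------------------------

def write_bedgraph(bins: BinTable, values: np.ndarray, path) -> None:
    """Write a per-bin track; NaN (undefined) bins are omitted."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(bins),):
        raise ValueError("values must have one entry per bin")
    with open(path, "w") as fh:
        for i in range(len(bins)):
            if np.isfinite(values[i]):
                fh.write(f"{bins.chrom[i]}\t{bins.start[i]}\t{bins.end[i]}\t{values[i]:.8g}\n")


def read_bedgraph(path, bins: BinTable) -> np.ndarray:
    """Read a per-bin track onto ``bins``; uncovered bins become NaN."""
    values = np.full(len(bins), np.nan)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom, start = parts[0], int(parts[1])
            try:
                idx = bins.bin_index(chrom, start)
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            values[idx] = float(parts[3])
    return values


def write_dense(matrix: ContactMatrix | np.ndarray, path, bins: BinTable | None = None) -> None:
    """Tab-separated dense export with bin labels as header row/column."""
    if isinstance(matrix, ContactMatrix):
        bins, data = matrix.bins, matrix.counts
    else:
        data = np.asarray(matrix, dtype=float)
    if bins is not None:
        labels = [f"{c}:{s}-{e}" for c, s, e in zip(bins.chrom, bins.start, bins.end)]
    else:
        labels = [str(i) for i in range(data.shape[0])]
    pd.DataFrame(data, index=labels, columns=labels).to_csv(path, sep="\t", na_rep="nan")


def read_dense(path, bins: BinTable) -> ContactMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    data = df.to_numpy(dtype=float)
    if data.shape != (len(bins), len(bins)):
        raise FormatError(f"{path}: dense matrix shape {data.shape} does not match bin table")
    return ContactMatrix(bins, data)
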