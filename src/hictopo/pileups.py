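"""Boundary pileups, log2 ratio maps, aggregate peak analysis (APA) and
contact-frequency-versus-distance scaling curves.

A pileup averages anchor-centered submatrices; around TAD boundaries it
shows the two within-TAD blocks and the depleted inter-TAD quadrants.
APA averages O/E submatrices centered on loop pixels: the centre-versus-
corner contrast quantifies aggregate loop strength, and comparing two
conditions yields the loop-intensity change. The scaling curve P(s) is
the mean balanced contact as a function of genomic separation; its
log-log slope is the decay exponent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bins import BinTable
from .matrix_io import ContactMatrix

__all__ = [
    "PileupResult",
    "boundary_pileup",
    "log2_ratio_map",
    "APAResult",
    "apa",
    "apa_differential",
    "ScalingCurve",
    "scaling_curve",
]


def _values_of(matrix) -> np.ndarray:
    if isinstance(matrix, ContactMatrix):
        return matrix.balanced()
    return np.asarray(matrix, dtype=float)


@dataclass
class PileupResult:
    """Mean anchor-centered submatrix: (2F+1) x (2F+1) with F =
    flank / resolution, the per-pixel defined count, and anchor
    bookkeeping (anchors within the flank of a chromosome end are
    excluded and counted)."""

    matrix: np.ndarray
    defined: np.ndarray
    n_anchors: int
    n_excluded: int
    flank_bins: int


def boundary_pileup(matrix, bins: BinTable, anchors, flank: int,
                    resolution: int | None = None) -> PileupResult:
    """Average submatrices of half-width ``flank`` centered on anchors.

    ``matrix`` is a :class:`ContactMatrix` (its balanced values are
    used) or a plain array on the same bins; ``anchors`` are global bin
    indices or a boundary frame with a ``bin`` column. Undefined pixels
    are excluded per pixel. Raises if no anchor is usable.
    """
    if isinstance(matrix, ContactMatrix):
        bins = matrix.bins
    res = resolution or bins.resolution
    if flank % res:
        raise ValueError(f"flank {flank} must be a multiple of the resolution {res}")
    F = flank // res
    V = _values_of(matrix)
    if isinstance(anchors, pd.DataFrame):
        anchors = anchors["bin"].to_numpy()
    anchors = np.asarray(anchors, dtype=np.int64)

    size = 2 * F + 1
    total = np.zeros((size, size))
    count = np.zeros((size, size), dtype=np.int64)
    used = excluded = 0
    for a in anchors:
        sl = bins.chrom_slices[bins.chrom_of(int(a))]
        if a - F < sl.start or a + F >= sl.stop:
            excluded += 1
            continue
        sub = V[a - F:a + F + 1, a - F:a + F + 1]
        finite = np.isfinite(sub)
        total[finite] += sub[finite]
        count += finite
        used += 1
    if used == 0:
        raise ValueError(f"no usable anchors ({excluded} excluded at chromosome ends)")
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return PileupResult(mean, count, used, excluded, F)


def log2_ratio_map(a, b, pseudocount: float = 0.0) -> np.ndarray:
    """Per-pixel log2((a + pc) / (b + pc)); NaN where either side is
    undefined. Typical pseudocounts: 1 count-equivalent for raw maps,
    1e-4 for O/E. Shapes must match."""
    a = a.matrix if isinstance(a, PileupResult) else np.asarray(a, dtype=float)
    b = b.matrix if isinstance(b, PileupResult) else np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.log2((a + pseudocount) / (b + pseudocount))
    out[~np.isfinite(out)] = np.nan
    return out


@dataclass
class APAResult:
    """Aggregate O/E pileup around loop pixels.

    ``matrix`` is (2F+1) x (2F+1) (21 x 21 at the default 250-kb flank /
    25-kb resolution). The centre window is the central 3x3; the
    background corner is the lower-left 6x6 (the short-distance corner).
    ``enrichment`` — the loop-intensity score used for differential
    comparisons — is the central pixel over the corner mean.
    """

    matrix: np.ndarray
    defined: np.ndarray
    n_loops: int
    n_filtered_diag: int
    n_filtered_edge: int
    flank_bins: int

    def _center_window(self) -> np.ndarray:
        F = self.flank_bins
        return self.matrix[F - 1:F + 2, F - 1:F + 2]

    def _corner_window(self) -> np.ndarray:
        return self.matrix[-6:, :6]

    @property
    def center(self) -> float:
        return float(np.nanmean(self._center_window()))

    @property
    def center_pixel(self) -> float:
        F = self.flank_bins
        return float(self.matrix[F, F])

    @property
    def corner_mean(self) -> float:
        return float(np.nanmean(self._corner_window()))

    @property
    def corner_sd(self) -> float:
        return float(np.nanstd(self._corner_window()))

    @property
    def apa_zscore(self) -> float:
        return (self.center - self.corner_mean) / self.corner_sd

    @property
    def apa_log2fc(self) -> float:
        return float(np.log2(self.center / self.corner_mean))

    @property
    def enrichment(self) -> float:
        return self.center_pixel / self.corner_mean


def _loops_to_bins(loops, bins: BinTable) -> list[tuple[int, int]]:
    """Map loop anchors to bin pairs. Accepts a BEDPE frame (anchor
    midpoints are binned) or (bin_a, bin_b) pairs."""
    pairs = []
    if isinstance(loops, pd.DataFrame):
        for row in loops.itertuples(index=False):
            if row.chrom1 != row.chrom2:
                continue  # APA is a cis analysis
            a = bins.bin_index(row.chrom1, (row.start1 + row.end1) // 2)
            b = bins.bin_index(row.chrom2, (row.start2 + row.end2) // 2)
            if a != b:
                pairs.append((min(a, b), max(a, b)))
    else:
        for a, b, *_ in loops:
            pairs.append((min(int(a), int(b)), max(int(a), int(b))))
    return pairs


def apa(oe: ContactMatrix, loops, flank: int = 250_000) -> APAResult:
    """Aggregate peak analysis on a cis O/E matrix.

    Loops closer than ``2*flank + 3`` bins to the diagonal are filtered
    (the background corner must stay off the diagonal), as are loops
    whose window leaves the chromosome. Raises — listing filter counts —
    if nothing survives.
    """
    bins = oe.bins
    res = bins.resolution
    if flank % res:
        raise ValueError(f"flank {flank} must be a multiple of the resolution {res}")
    F = flank // res
    V = oe.counts
    size = 2 * F + 1
    total = np.zeros((size, size))
    count = np.zeros((size, size), dtype=np.int64)
    used = near_diag = off_edge = 0
    for a, b in _loops_to_bins(loops, bins):
        ca, cb = bins.chrom_of(a), bins.chrom_of(b)
        if ca != cb:
            continue
        if b - a < 2 * F + 3:
            near_diag += 1
            continue
        sl = bins.chrom_slices[ca]
        if a - F < sl.start or b + F >= sl.stop:
            off_edge += 1
            continue
        sub = V[a - F:a + F + 1, b - F:b + F + 1]
        finite = np.isfinite(sub)
        total[finite] += sub[finite]
        count += finite
        used += 1
    if used == 0:
        raise ValueError(
            f"all loops filtered: {near_diag} within 2*flank+3 bins of the "
            f"diagonal, {off_edge} at chromosome edges")
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return APAResult(mean, count, used, near_diag, off_edge, F)


def apa_differential(trt: APAResult, ctrl: APAResult) -> dict[str, float]:
    """Treatment-versus-control loop-intensity change.

    ``pct_change`` is the percent decrease of the loop-intensity score
    (central pixel over corner background); ``delta_log2fc`` is the
    difference of the centre-window log2 fold changes.
    """
    return {
        "delta_log2fc": trt.apa_log2fc - ctrl.apa_log2fc,
        "pct_change": 100.0 * (1.0 - trt.enrichment / ctrl.enrichment),
        "ctrl_enrichment": ctrl.enrichment,
        "trt_enrichment": trt.enrichment,
    }


@dataclass
class ScalingCurve:
    """Mean balanced contact per geometric distance bin, plus the
    fitted log-log slope over ``fit_range``."""

    distance_bp: np.ndarray
    mean_contact: np.ndarray
    n_pixels: np.ndarray
    slope: float
    fit_range: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "distance_bp": self.distance_bp,
            "mean_contact": self.mean_contact,
            "n_pixels": self.n_pixels,
        })


def scaling_curve(matrix: ContactMatrix, max_dist: int, n_logbins: int = 25,
                  fit_min: int = 200_000) -> ScalingCurve:
    """Contact frequency versus genomic distance, pooled over
    chromosomes, with geometric distance bins up to ``max_dist`` and a
    least-squares log-log slope fitted over [``fit_min``, ``max_dist``].
    Empty distance bins are dropped. A constant matrix yields slope 0.
    """
    bins = matrix.bins
    res = bins.resolution
    exclude = int(matrix.meta.get("exclude_diags", 2))
    max_bins = max_dist // res
    B = matrix.balanced()

    dmax = 0
    sums = np.zeros(max_bins + 1)
    counts = np.zeros(max_bins + 1)
    for sl in bins.chrom_slices.values():
        block = B[sl, sl]
        nc = block.shape[0]
        for d in range(exclude, min(nc, max_bins + 1)):
            diag = np.diagonal(block, offset=d)
            vals = diag[np.isfinite(diag)]
            if vals.size:
                sums[d] += vals.sum()
                counts[d] += vals.size
                dmax = max(dmax, d)
    if dmax < exclude + 1:
        raise ValueError("chromosomes too short for the requested distance range")

    edges = np.geomspace(exclude * res, (dmax + 1) * res, n_logbins + 1)
    dist_bp = np.arange(max_bins + 1) * res
    which = np.clip(np.searchsorted(edges, dist_bp, side="right") - 1, 0, n_logbins - 1)
    bs = np.zeros(n_logbins)
    bc = np.zeros(n_logbins)
    bd = np.zeros(n_logbins)
    for d in range(exclude, dmax + 1):
        if counts[d]:
            g = which[d]
            bs[g] += sums[d]
            bc[g] += counts[d]
            bd[g] += dist_bp[d] * counts[d]
    keep = bc > 0
    mean = bs[keep] / bc[keep]
    dist = bd[keep] / bc[keep]
    npix = bc[keep]

    hi = dmax * res
    in_fit = (dist >= fit_min) & (dist <= hi) & (mean > 0)
    if in_fit.sum() >= 2:
        slope = float(np.polyfit(np.log10(dist[in_fit]), np.log10(mean[in_fit]), 1)[0])
    else:
        slope = np.nan
    return ScalingCurve(dist, mean, npix, slope, (float(fit_min), float(hi)))
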