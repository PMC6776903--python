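"""Matrix correction and the expected / observed-over-expected /
correlation transforms that insulation, compartment and saddle analyses
are built on.

Balancing is iterative correction (ICE): per-bin weights are updated
until every unmasked bin has the same weighted marginal, which removes
coverage bias including read depth. Expected profiles are per-distance
means in cis and per-chromosome-pair means in trans; dividing by them
yields the distance-normalized observed/expected (O/E) matrix whose
row-row Pearson correlations expose the compartment plaid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bins import BinTable
from .matrix_io import ContactMatrix

__all__ = [
    "ice_balance",
    "ExpectedProfile",
    "expected_by_distance",
    "observed_over_expected",
    "CorrelationMaps",
    "pearson_correlation_map",
]


def _near_diagonal_mask(bins: BinTable, exclude_diags: int) -> np.ndarray:
    """Boolean (n, n) array flagging cis pixels with |i-j| < exclude_diags."""
    n = len(bins)
    out = np.zeros((n, n), dtype=bool)
    if exclude_diags <= 0:
        return out
    for sl in bins.chrom_slices.values():
        nc = sl.stop - sl.start
        idx = np.arange(nc)
        d = np.abs(idx[:, None] - idx[None, :])
        out[sl, sl] = d < exclude_diags
    return out


def ice_balance(
    matrix: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    low_coverage_quantile: float = 0.02,
    exclude_diags: int = 2,
) -> ContactMatrix:
    """Iterative correction: equalize weighted marginals of unmasked bins.

    Bins with zero coverage, or in the lowest ``low_coverage_quantile``
    of nonzero coverage, are masked before iterating. Cis pixels with
    ``|i-j| < exclude_diags`` are excluded from the marginals (self /
    adjacent-ligation artifacts); set ``exclude_diags=0`` to include
    everything. Weights are scaled so unmasked balanced marginals equal
    1, making balanced values invariant to a global depth rescaling.

    Returns a new matrix carrying the raw counts, the mask, the weights,
    and ``meta['ice_converged']``; non-convergence after ``max_iter``
    iterations emits a warning rather than failing silently.
    """
    n = matrix.n_bins
    counts = matrix.counts
    if not np.all(np.isfinite(counts)):
        raise ValueError("ice_balance expects a raw count matrix without NaN")
    include = ~_near_diagonal_mask(matrix.bins, exclude_diags)

    coverage = (counts * include).sum(axis=1)
    mask = matrix.mask | (coverage == 0)
    nonzero = coverage[~mask]
    if nonzero.size:
        cutoff = np.quantile(nonzero, low_coverage_quantile)
        mask |= coverage < cutoff
    if mask.all():
        raise ValueError("all bins masked; nothing to balance")

    work = np.where(include, counts, 0.0)
    work[mask, :] = 0.0
    work[:, mask] = 0.0
    w = np.ones(n)
    converged = False
    for _ in range(max_iter):
        marg = w * (work @ w)
        m = marg[~mask]
        mean = m.mean()
        if mean <= 0:
            raise ValueError("degenerate matrix: zero mean marginal")
        cv = m.std() / mean
        if cv < tol:
            converged = True
            break
        w[~mask] /= m / mean
    final = w * (work @ w)
    mean = final[~mask].mean()
    w /= np.sqrt(mean)  # unit unmasked marginals

    if not converged:
        warnings.warn(
            f"ICE did not reach tol={tol} within {max_iter} iterations "
            f"(marginal CV {cv:.2e})", RuntimeWarning, stacklevel=2)
    weights = np.where(mask, np.nan, w)
    meta = dict(matrix.meta)
    meta.update(ice_converged=converged, exclude_diags=exclude_diags, space="counts")
    return ContactMatrix(matrix.bins, counts.copy(), mask, weights, meta)


@dataclass
class ExpectedProfile:
    """Per-distance mean balanced contact in cis; scalar mean per
    chromosome pair in trans. Distances in bins; index d of a cis array
    is separation d."""

    bins: BinTable
    cis: dict[str, np.ndarray] = field(default_factory=dict)
    trans: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, arr in self.cis.items():
            for d, v in enumerate(arr):
                if np.isfinite(v):
                    rows.append((chrom, d * self.bins.resolution, v))
        return pd.DataFrame(rows, columns=["chrom", "distance_bp", "expected"])


def expected_by_distance(matrix: ContactMatrix, exclude_diags: int | None = None) -> ExpectedProfile:
    """Mean balanced contact per bin-distance (cis, per chromosome) and
    per chromosome pair (trans). Distances below ``exclude_diags``
    (default: the value used at balancing time, else 2) are undefined.
    """
    if exclude_diags is None:
        exclude_diags = int(matrix.meta.get("exclude_diags", 2))
    B = matrix.balanced()
    bins = matrix.bins
    profile = ExpectedProfile(bins)
    for chrom, sl in bins.chrom_slices.items():
        nc = sl.stop - sl.start
        block = B[sl, sl]
        exp = np.full(nc, np.nan)
        for d in range(exclude_diags, nc):
            diag = np.diagonal(block, offset=d)
            vals = diag[np.isfinite(diag)]
            if vals.size:
                exp[d] = vals.mean()
        profile.cis[chrom] = exp
    chroms = bins.chroms
    for i, ca in enumerate(chroms):
        for cb in chroms[i + 1:]:
            block = B[bins.chrom_slices[ca], bins.chrom_slices[cb]]
            vals = block[np.isfinite(block)]
            profile.trans[(ca, cb)] = float(vals.mean()) if vals.size else np.nan
    return profile


def observed_over_expected(matrix: ContactMatrix, profile: ExpectedProfile) -> ContactMatrix:
    """Divide balanced contacts by expected at their distance (cis) or by
    the chromosome-pair mean (trans). Pixels whose expected value is zero
    or undefined become NaN, never infinite. Masked bins stay NaN.
    """
    B = matrix.balanced()
    bins = matrix.bins
    oe = np.full_like(B, np.nan)
    for chrom, sl in bins.chrom_slices.items():
        nc = sl.stop - sl.start
        exp = profile.cis.get(chrom)
        if exp is None:
            continue
        idx = np.arange(nc)
        d = np.abs(idx[:, None] - idx[None, :])
        denom = np.where((d < len(exp)), exp[np.minimum(d, len(exp) - 1)], np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            block = B[sl, sl] / denom
        block[~np.isfinite(block)] = np.nan
        oe[sl, sl] = block
    chroms = bins.chroms
    for i, ca in enumerate(chroms):
        for cb in chroms[i + 1:]:
            sa, sb = bins.chrom_slices[ca], bins.chrom_slices[cb]
            denom = profile.trans.get((ca, cb), np.nan)
            if not np.isfinite(denom) or denom == 0:
                continue
            block = B[sa, sb] / denom
            oe[sa, sb] = block
            oe[sb, sa] = block.T
    meta = dict(matrix.meta)
    meta["space"] = "oe"
    return ContactMatrix(bins, oe, matrix.mask.copy(), None, meta)


@dataclass
class CorrelationMaps:
    """Per-chromosome Pearson correlation matrices of O/E rows.

    Values lie in [-1, 1]; rows that are masked, near-constant, or have
    fewer than two jointly defined entries with a partner are NaN.
    ``degenerate`` flags chromosomes whose map is entirely undefined.
    """

    bins: BinTable
    maps: dict[str, np.ndarray] = field(default_factory=dict)
    degenerate: dict[str, bool] = field(default_factory=dict)


def pearson_correlation_map(oe: ContactMatrix, min_valid: int = 2) -> CorrelationMaps:
    """Pearson correlation between cis O/E rows, per chromosome.

    For a row pair (i, j) the correlation is computed over columns where
    both rows are defined, excluding columns i and j themselves (a bin
    pair's own pixels would otherwise correlate trivially). Constant
    rows yield undefined (NaN) correlations and are flagged.
    """
    bins = oe.bins
    result = CorrelationMaps(bins)
    for chrom, sl in bins.chrom_slices.items():
        block = oe.counts[sl, sl]
        nc = block.shape[0]
        corr = np.full((nc, nc), np.nan)
        finite = np.isfinite(block)
        for i in range(nc):
            if not finite[i].any():
                continue
            corr[i, i] = 1.0
            for j in range(i + 1, nc):
                valid = finite[i] & finite[j]
                valid[i] = valid[j] = False
                if valid.sum() < max(min_valid, 2):
                    continue
                x, y = block[i, valid], block[j, valid]
                sx, sy = x.std(), y.std()
                if sx == 0 or sy == 0:
                    continue
                corr[i, j] = corr[j, i] = float(
                    ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
        off_diag = ~np.eye(nc, dtype=bool)
        result.maps[chrom] = corr
        result.degenerate[chrom] = bool(np.all(~np.isfinite(corr[off_diag]))) if nc > 1 else False
    return result
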