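"""A/B compartment eigenvectors, saddle plots and switching analysis.

The first principal component of the per-chromosome O/E correlation map
captures the plaid pattern of compartmental interactions: its per-bin
entries ("first eigenvalues") are positive in A-type (active, gene-rich)
and negative in B-type (inactive) compartments once the sign is oriented
against a reference activity track. Saddle plots rank bins by
eigenvector value, cut them into quantile groups, and average O/E
between groups; the corners summarize AA, BB and AB interaction
strength. Switching analysis compares reproducible compartment labels
between conditions against a label-permutation null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .bins import BinTable
from .balance import CorrelationMaps
from .matrix_io import ContactMatrix

__all__ = [
    "EigenTrack",
    "compartment_eigenvector",
    "trans_eigenvector",
    "SaddleResult",
    "saddle",
    "SwitchSummary",
    "compartment_switching",
]

log = logging.getLogger(__name__)


@dataclass
class EigenTrack:
    """Per-bin first-eigenvector values with A/B labels.

    ``values`` is NaN on undefined bins; a bin is A-type iff its value is
    positive. ``ambiguous`` flags chromosomes where the reference track
    correlated too weakly (|r| < 0.1) to fix the sign.
    """

    bins: BinTable
    values: np.ndarray
    provenance: str            # 'cis' | 'trans'
    resolution: int
    ambiguous: dict[str, bool] = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        out = np.full(len(self.bins), "", dtype=object)
        out[np.nan_to_num(self.values) > 0] = "A"
        out[np.nan_to_num(self.values) < 0] = "B"
        out[~np.isfinite(self.values)] = ""
        return out


def _orient(vec: np.ndarray, ref: np.ndarray, what: str) -> tuple[np.ndarray, bool]:
    """Flip ``vec`` so it correlates positively with ``ref``.

    Returns (vector, ambiguous). Needs the reference on >= 50% of the
    defined bins; weak correlation (|r| < 0.1) leaves the sign as
    computed and flags ambiguity.
    """
    both = np.isfinite(vec) & np.isfinite(ref)
    if both.sum() < 0.5 * np.isfinite(vec).sum() or both.sum() < 2:
        raise ValueError(f"reference track covers too few defined bins for {what}")
    x, y = vec[both], ref[both]
    sx, sy = x.std(), y.std()
    r = 0.0 if sx == 0 or sy == 0 else float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    if abs(r) < 0.1:
        warnings.warn(f"eigenvector orientation ambiguous for {what} "
                      f"(|r|={abs(r):.3f} with reference)", RuntimeWarning, stacklevel=3)
        return vec, True
    return (-vec if r < 0 else vec), False


def compartment_eigenvector(corr: CorrelationMaps, reference: np.ndarray) -> EigenTrack:
    """First principal component of each chromosome's correlation map.

    The correlation map is double-centered, its leading eigenvector is
    scaled by the square root of the eigenvalue, and the sign is chosen
    per chromosome so the track correlates positively with the reference
    activity track (A = active). Masked bins stay NaN.
    """
    bins = corr.bins
    reference = np.asarray(reference, dtype=float)
    values = np.full(len(bins), np.nan)
    ambiguous: dict[str, bool] = {}
    for chrom, sl in bins.chrom_slices.items():
        M = corr.maps[chrom]
        defined = np.isfinite(M).sum(axis=1) >= 2
        if defined.sum() < 3:
            ambiguous[chrom] = True
            continue
        sub = M[np.ix_(defined, defined)].copy()
        sub[~np.isfinite(sub)] = 0.0
        row = sub.mean(axis=1, keepdims=True)
        centered = sub - row - row.T + sub.mean()
        evals, evecs = np.linalg.eigh(centered)
        vec = evecs[:, -1] * np.sqrt(max(evals[-1], 0.0))
        full = np.full(sl.stop - sl.start, np.nan)
        full[defined] = vec
        oriented, amb = _orient(full, reference[sl], chrom)
        values[sl] = oriented
        ambiguous[chrom] = amb
    return EigenTrack(bins, values, "cis", bins.resolution, ambiguous)


def trans_eigenvector(trans_oe: ContactMatrix, reference: np.ndarray) -> EigenTrack:
    """First eigenvector of the trans-only interaction structure.

    The genome-wide O/E matrix is centered (O/E - 1) on defined trans
    pixels, cis blocks and masked bins are zeroed, and the leading
    eigenvector (by eigenvalue magnitude) is scaled by sqrt(|eigenvalue|)
    and oriented against the reference. Bins of chromosomes without any
    trans coverage are undefined.
    """
    bins = trans_oe.bins
    n = len(bins)
    M = np.zeros((n, n))
    has_trans = np.zeros(n, dtype=bool)
    chroms = bins.chroms
    for i, ca in enumerate(chroms):
        for cb in chroms[i + 1:]:
            sa, sb = bins.chrom_slices[ca], bins.chrom_slices[cb]
            block = trans_oe.counts[sa, sb]
            finite = np.isfinite(block)
            if not finite.any():
                continue
            vals = np.where(finite, block - 1.0, 0.0)
            M[sa, sb] = vals
            M[sb, sa] = vals.T
            has_trans[sa] |= finite.any(axis=1)
            has_trans[sb] |= finite.any(axis=0)
    defined = has_trans & ~trans_oe.mask
    if defined.sum() < 3:
        raise ValueError("no usable trans coverage")
    sub = M[np.ix_(defined, defined)]
    evals, evecs = np.linalg.eigh(sub)
    # the block structure (zero cis blocks) yields +-eigenvalue pairs;
    # the largest *positive* eigenvalue carries the consistent
    # inter-chromosomal sign coupling
    vec = evecs[:, -1] * np.sqrt(max(evals[-1], 0.0))
    values = np.full(n, np.nan)
    values[defined] = vec
    oriented, amb = _orient(values, np.asarray(reference, dtype=float), "trans")
    return EigenTrack(bins, oriented, "trans", bins.resolution,
                      {c: amb for c in chroms})


@dataclass
class SaddleResult:
    """Q x Q mean O/E between eigenvector quantile groups, ordered most-B
    to most-A, with per-entry pixel counts and corner summaries over the
    5 extreme quantiles."""

    matrix: np.ndarray
    counts: np.ndarray
    scope: str
    n_quantiles: int
    corner_size: int = 5

    @property
    def corners(self) -> dict[str, float]:
        k = self.corner_size
        S, C = self.matrix, self.counts

        def wmean(rows, cols):
            s, c = S[rows, cols], C[rows, cols]
            ok = np.isfinite(s) & (c > 0)
            return float((s[ok] * c[ok]).sum() / c[ok].sum()) if c[ok].sum() else np.nan

        bb = wmean(np.s_[:k], np.s_[:k])
        aa = wmean(np.s_[-k:], np.s_[-k:])
        ab = wmean(np.s_[:k], np.s_[-k:])
        return {"AA": aa, "BB": bb, "AB": ab}


def _quantile_groups(values: np.ndarray, defined: np.ndarray, q: int) -> np.ndarray:
    """Group id per bin (-1 = ungrouped), most-B first; sizes differ by
    at most one; ties broken by bin index (stable sort)."""
    idx = np.flatnonzero(defined)
    if idx.size < q:
        raise ValueError(f"only {idx.size} defined bins for {q} quantiles")
    order = idx[np.argsort(values[idx], kind="stable")]
    gid = np.full(values.size, -1, dtype=np.int64)
    for g, chunk in enumerate(np.array_split(order, q)):
        gid[chunk] = g
    return gid


def saddle(eigen: EigenTrack, oe: ContactMatrix, scope: str = "cis",
           n_quantiles: int = 30) -> SaddleResult:
    """Mean O/E between eigenvector quantile groups.

    Bins are ranked by eigenvector value and cut into ``n_quantiles``
    near-equal groups. Entry (p, q) averages all defined O/E pixels with
    one bin in group p and the other in q — distance-normalized cis
    pixels for ``scope='cis'``, chromosome-pair-normalized trans pixels
    for ``scope='trans'``.
    """
    if scope not in ("cis", "trans"):
        raise ValueError(f"scope must be 'cis' or 'trans', got {scope!r}")
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    bins = eigen.bins
    if bins != oe.bins:
        raise ValueError("eigenvector and O/E matrix must share bins")
    defined = np.isfinite(eigen.values) & ~oe.mask
    gid = _quantile_groups(eigen.values, defined, n_quantiles)

    S = np.zeros((n_quantiles, n_quantiles))
    C = np.zeros((n_quantiles, n_quantiles))
    chroms = bins.chroms
    blocks = []
    if scope == "cis":
        blocks = [(bins.chrom_slices[c], bins.chrom_slices[c]) for c in chroms]
    else:
        for i, ca in enumerate(chroms):
            for cb in chroms[i + 1:]:
                blocks.append((bins.chrom_slices[ca], bins.chrom_slices[cb]))
    for sa, sb in blocks:
        block = oe.counts[sa, sb]
        ga, gb = gid[sa], gid[sb]
        ii, jj = np.nonzero(np.isfinite(block))
        if sa == sb:
            keep = jj > ii  # upper triangle once; O/E already NaN near diagonal
            ii, jj = ii[keep], jj[keep]
        keep = (ga[ii] >= 0) & (gb[jj] >= 0)
        ii, jj = ii[keep], jj[keep]
        v = block[ii, jj]
        p, q = ga[ii], gb[jj]
        np.add.at(S, (p, q), v)
        np.add.at(C, (p, q), 1)
        np.add.at(S, (q, p), v)
        np.add.at(C, (q, p), 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(C > 0, S / np.maximum(C, 1), np.nan)
    return SaddleResult(mean, C, scope, n_quantiles)


@dataclass
class SwitchSummary:
    """Observed compartment stability/switching fractions over jointly
    reproducible bins, with a label-permutation baseline (mean +- sd)."""

    fractions: dict[str, float]          # stable_A, stable_B, A_to_B, B_to_A
    random_mean: dict[str, float]
    random_sd: dict[str, float]
    n_bins: int
    n_rand: int

    @property
    def stable_fraction(self) -> float:
        return self.fractions["stable_A"] + self.fractions["stable_B"]


def _fractions(sc: np.ndarray, st: np.ndarray) -> dict[str, float]:
    n = sc.size
    return {
        "stable_A": float(((sc > 0) & (st > 0)).sum() / n),
        "stable_B": float(((sc < 0) & (st < 0)).sum() / n),
        "A_to_B": float(((sc > 0) & (st < 0)).sum() / n),
        "B_to_A": float(((sc < 0) & (st > 0)).sum() / n),
    }


def compartment_switching(
    ctrl: tuple[EigenTrack, EigenTrack],
    trt: tuple[EigenTrack, EigenTrack],
    n_rand: int = 100,
    seed: int = 0,
) -> SwitchSummary:
    """Compartment switching between two conditions with two replicates.

    A bin is reproducible in a condition iff both replicates agree in
    sign; fractions are computed over bins reproducible in both
    conditions (and sum to 1). The randomized baseline permutes the
    treatment labels across those bins (preserving the A/B counts)
    ``n_rand`` times.
    """
    tracks = list(ctrl) + list(trt)
    n = len(tracks[0].bins)
    for t in tracks:
        if len(t.bins) != n:
            raise ValueError("all eigen tracks must share bins")
    c1, c2 = np.sign(ctrl[0].values), np.sign(ctrl[1].values)
    t1, t2 = np.sign(trt[0].values), np.sign(trt[1].values)
    rep_c = np.isfinite(c1) & np.isfinite(c2) & (c1 == c2) & (c1 != 0)
    rep_t = np.isfinite(t1) & np.isfinite(t2) & (t1 == t2) & (t1 != 0)
    joint = rep_c & rep_t
    if not joint.any():
        raise ValueError("no jointly reproducible bins between conditions")
    sc, st = c1[joint], t1[joint]
    observed = _fractions(sc, st)

    rng = np.random.default_rng(seed)
    rand = {k: [] for k in observed}
    for _ in range(n_rand):
        perm = rng.permutation(st)
        for k, v in _fractions(sc, perm).items():
            rand[k].append(v)
    return SwitchSummary(
        fractions=observed,
        random_mean={k: float(np.mean(v)) for k, v in rand.items()},
        random_sd={k: float(np.std(v)) for k, v in rand.items()},
        n_bins=int(joint.sum()),
        n_rand=n_rand,
    )
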