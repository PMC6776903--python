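"""Statistical comparisons for the control-versus-treatment analyses:
Wilcoxon rank-sum tests, boundary-score stratification by motif-site
counts, and replicate eigenvector dissimilarity with hierarchical
clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

__all__ = [
    "RankTestResult",
    "wilcoxon_rank_sum",
    "count_sites_per_boundary",
    "compare_stratified",
    "replicate_dissimilarity",
]

log = logging.getLogger(__name__)

EXACT_MAX_N = 20  # exact enumeration for untied samples up to this combined size


@dataclass
class RankTestResult:
    """Wilcoxon rank-sum test outcome.

    ``statistic`` is the rank sum W of the first sample (mid-ranks for
    ties); the p-value comes from exact enumeration when the combined
    sample is small and untied, otherwise from the normal approximation
    with continuity and tie correction.
    """

    statistic: float
    pvalue: float
    method: str                # 'exact' | 'normal'
    n_x: int
    n_y: int
    degenerate: bool = False


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> RankTestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration is used iff ``n_x + n_y <= 20`` and the combined
    sample has no ties; otherwise the normal approximation with
    continuity correction and tie-corrected variance. Two identical
    constant samples are degenerate: p = 1, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    w = float(ranks[: x.size].sum())
    if np.all(combined == combined[0]):
        return RankTestResult(w, 1.0, "normal", x.size, y.size, degenerate=True)
    ties = np.unique(combined).size < combined.size
    exact = (x.size + y.size) <= EXACT_MAX_N and not ties
    res = sps.mannwhitneyu(
        x, y, alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return RankTestResult(w, float(res.pvalue), "exact" if exact else "normal",
                          x.size, y.size)


def count_sites_per_boundary(boundaries: pd.DataFrame, sites: pd.DataFrame,
                             resolution: int | None = None) -> pd.DataFrame:
    """Count motif/peak sites overlapping each boundary bin by >= 1 bp.

    ``boundaries`` needs chrom/start/end columns (a frame from
    ``call_boundaries``); ``sites`` is a BED frame. Adds
    ``n_motif_sites`` and a ``site_category`` of "<=1" or ">=2".
    A site spanning a bin edge counts for both bins.
    """
    out = boundaries.copy()
    counts = np.zeros(len(out), dtype=np.int64)
    by_chrom = {c: g for c, g in sites.groupby("chrom")}
    for k, row in enumerate(out.itertuples(index=False)):
        g = by_chrom.get(row.chrom)
        if g is None:
            continue
        counts[k] = int(((g["start"] < row.end) & (g["end"] > row.start)).sum())
    out["n_motif_sites"] = counts
    out["site_category"] = np.where(counts >= 2, ">=2", "<=1")
    return out


def compare_stratified(
    scores: dict[tuple[str, str], np.ndarray],
    control: str,
    treatment: str,
    categories: tuple[str, str] = ("<=1", ">=2"),
    adjust: str | None = None,
) -> pd.DataFrame:
    """Pairwise rank-sum tests over a condition x site-category partition.

    ``scores`` maps (condition, category) to boundary-score arrays. The
    table reports control-vs-treatment within each category and
    low-vs-high category within each condition, with medians and IQRs;
    comparisons with an empty cell are reported as skipped. Raw p-values
    are reported by default; ``adjust='bh'`` adds a Benjamini-Hochberg
    ``pvalue_adj`` column.
    """
    def cell(cond, cat):
        return np.asarray(scores.get((cond, cat), []), dtype=float)

    def describe(v):
        if v.size == 0:
            return (0, np.nan, np.nan)
        q1, q3 = np.percentile(v, [25, 75])
        return (v.size, float(np.median(v)), float(q3 - q1))

    comparisons = [(f"{control} vs {treatment} | sites {cat}",
                    cell(control, cat), cell(treatment, cat)) for cat in categories]
    comparisons += [(f"sites {categories[0]} vs {categories[1]} | {cond}",
                     cell(cond, categories[0]), cell(cond, categories[1]))
                    for cond in (control, treatment)]
    rows = []
    for name, a, b in comparisons:
        na, med_a, iqr_a = describe(a)
        nb, med_b, iqr_b = describe(b)
        if na == 0 or nb == 0:
            rows.append((name, na, nb, med_a, med_b, iqr_a, iqr_b,
                         np.nan, np.nan, True))
            continue
        res = wilcoxon_rank_sum(a, b)
        rows.append((name, na, nb, med_a, med_b, iqr_a, iqr_b,
                     res.statistic, res.pvalue, False))
    table = pd.DataFrame(rows, columns=[
        "comparison", "n_a", "n_b", "median_a", "median_b", "iqr_a", "iqr_b",
        "statistic", "pvalue", "skipped"])
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests
        done = table["pvalue"].notna()
        adj = np.full(len(table), np.nan)
        if done.any():
            adj[done.to_numpy()] = multipletests(
                table.loc[done, "pvalue"], method="fdr_bh")[1]
        table["pvalue_adj"] = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table


def _to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"


def replicate_dissimilarity(
    tracks: dict[str, np.ndarray],
    linkage_method: str = "average",
) -> tuple[pd.DataFrame, list[tuple[frozenset, frozenset]], str, list[tuple[str, str]]]:
    """Replicate dissimilarity (1 - Pearson r of first-eigenvector
    tracks) and its dendrogram.

    Returns the symmetric dissimilarity table, the merge order as a list
    of label-set pairs (first merge first), a Newick string, and the
    pairs flagged low-confidence (joint coverage < 50% of the bins
    defined in either track). d lies in [0, 2]: 0 for identical tracks,
    2 for a track and its negation.
    """
    names = list(tracks)
    if len(names) < 2:
        raise ValueError("need at least two tracks")
    arrays = {k: np.asarray(v, dtype=float) for k, v in tracks.items()}
    n = len(names)
    D = np.zeros((n, n))
    low_conf = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrays[names[i]], arrays[names[j]]
            if a.shape != b.shape:
                raise ValueError("tracks must share bins")
            fin_a, fin_b = np.isfinite(a), np.isfinite(b)
            joint = fin_a & fin_b
            union = fin_a | fin_b
            if union.sum() and joint.sum() / union.sum() < 0.5:
                low_conf.append((names[i], names[j]))
            if joint.sum() < 2:
                d = np.nan
            else:
                xa, xb = a[joint], b[joint]
                sa, sb = xa.std(), xb.std()
                r = 0.0 if sa == 0 or sb == 0 else float(
                    ((xa - xa.mean()) * (xb - xb.mean())).mean() / (sa * sb))
                d = 1.0 - r
            D[i, j] = D[j, i] = d
    frame = pd.DataFrame(D, index=names, columns=names)

    condensed = D[np.triu_indices(n, k=1)]
    Z = hierarchy.linkage(condensed, method=linkage_method)
    Z[:, 2] = np.maximum(Z[:, 2], 0.0)  # guard float eps on identical tracks
    members: list[frozenset] = [frozenset([name]) for name in names]
    merge_order = []
    for a_id, b_id, *_ in Z:
        sa, sb = members[int(a_id)], members[int(b_id)]
        merge_order.append((sa, sb))
        members.append(sa | sb)
    tree = hierarchy.to_tree(Z)
    newick = _to_newick(tree, names) + ";"
    return frame, merge_order, newick, low_conf
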