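"""Rank tests, site-count stratification, replicate dissimilarity."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import hictopo as h
from tests_oracles import exact_rank_sum_p


class TestWilcoxonRankSum:
    def test_fully_separated_small_samples_exact(self):
        # 20 equally likely assignments of ranks; 2 are as extreme
        res = h.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.1)
        assert res.statistic == 6.0

    def test_identical_multisets_give_unit_p(self):
        res = h.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.pvalue == pytest.approx(1.0)

    def test_degenerate_constant_samples_flagged(self):
        res = h.wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.degenerate and res.pvalue == 1.0

    def test_method_selection_rule(self, rng):
        small = h.wilcoxon_rank_sum(rng.normal(size=8), rng.normal(size=8))
        assert small.method == "exact"
        large = h.wilcoxon_rank_sum(rng.normal(size=15), rng.normal(size=15))
        assert large.method == "normal"
        tied = h.wilcoxon_rank_sum([1, 2, 2, 3], [2, 4, 5])
        assert tied.method == "normal"

    def test_normal_approximation_close_to_enumeration(self, rng):
        from scipy.stats import mannwhitneyu
        worst = 0.0
        for _ in range(60):
            x = rng.normal(size=8)
            y = rng.normal(size=8) + rng.uniform(-1, 1)
            p_exact = exact_rank_sum_p(x, y)
            p_norm = mannwhitneyu(x, y, method="asymptotic",
                                  use_continuity=True).pvalue
            worst = max(worst, abs(p_exact - p_norm))
        assert worst < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            h.wilcoxon_rank_sum([], [1.0])


class TestSiteCounting:
    def bed(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def bounds(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "bin", "start", "end"])
        df["score"] = 1.0
        return df

    def test_two_sites_in_bin(self):
        bounds = self.bounds([("chr1", 1, 40_000, 80_000)])
        sites = self.bed([("chr1", 50_000, 50_200), ("chr1", 60_000, 60_200)])
        out = h.count_sites_per_boundary(bounds, sites)
        assert out.loc[0, "n_motif_sites"] == 2
        assert out.loc[0, "site_category"] == ">=2"

    def test_no_overlap_low_category(self):
        bounds = self.bounds([("chr1", 1, 40_000, 80_000)])
        sites = self.bed([("chr2", 50_000, 50_200), ("chr1", 90_000, 90_500)])
        out = h.count_sites_per_boundary(bounds, sites)
        assert out.loc[0, "n_motif_sites"] == 0
        assert out.loc[0, "site_category"] == "<=1"

    def test_edge_spanning_site_counts_for_both_bins(self):
        bounds = self.bounds([("chr1", 1, 40_000, 80_000),
                              ("chr1", 2, 80_000, 120_000)])
        sites = self.bed([("chr1", 79_900, 80_100)])
        out = h.count_sites_per_boundary(bounds, sites)
        assert list(out["n_motif_sites"]) == [1, 1]


class TestCompareStratified:
    def test_identical_conditions_nonsignificant(self, rng):
        v1, v2 = rng.uniform(1, 3, 20), rng.uniform(1, 3, 15)
        scores = {("CTRL", "<=1"): v1, ("TRT", "<=1"): v1,
                  ("CTRL", ">=2"): v2, ("TRT", ">=2"): v2}
        table = h.compare_stratified(scores, "CTRL", "TRT")
        ctrl_vs_trt = table[table["comparison"].str.startswith("CTRL vs")]
        assert (ctrl_vs_trt["pvalue"] > 0.9).all()

    def test_empty_cell_skipped_and_reported(self, rng):
        scores = {("CTRL", "<=1"): rng.uniform(1, 3, 10),
                  ("TRT", "<=1"): rng.uniform(1, 3, 10),
                  ("CTRL", ">=2"): np.array([]),
                  ("TRT", ">=2"): rng.uniform(1, 3, 5)}
        table = h.compare_stratified(scores, "CTRL", "TRT")
        skipped = table[table["skipped"]]
        assert len(skipped) == 2  # the >=2 contrast and CTRL's category contrast

    def test_uniform_weakening_significant_in_both_strata(self, rng):
        # boundary weakening applied regardless of site category
        ctrl = rng.normal(5, 0.5, 40)
        trt = ctrl * 0.5 + rng.normal(0, 0.1, 40)
        cat = rng.choice(["<=1", ">=2"], size=40)
        scores = {(cond, c): vals[cat == c]
                  for cond, vals in (("CTRL", ctrl), ("TRT", trt))
                  for c in ("<=1", ">=2")}
        table = h.compare_stratified(scores, "CTRL", "TRT")
        ctrl_vs_trt = table[table["comparison"].str.startswith("CTRL vs")]
        assert (ctrl_vs_trt["pvalue"] < 0.01).all()
        assert (ctrl_vs_trt["median_a"] > ctrl_vs_trt["median_b"]).all()

    def test_stronger_boundaries_with_more_sites(self, tad_setup):
        # plant stronger insulation (lower permeability) at ">=2"
        # boundaries: their scores come out higher in the same track
        s = tad_setup
        truth = s["truth"]
        n_b = truth.tad_boundaries.size
        rng = np.random.default_rng(4)
        strong = rng.random(n_b) < 0.5
        perms = np.where(strong, 0.1, 0.45)
        import dataclasses
        t2 = dataclasses.replace(truth,
                                 boundary_permeability=perms,
                                 tad_boundaries=truth.tad_boundaries.copy(),
                                 compartment_profile=truth.compartment_profile.copy(),
                                 loops=list(truth.loops))
        mat = h.simulate_contacts(t2, s["bins"], 88)
        track = h.insulation_track(h.ice_balance(mat))
        scores = h.boundary_scores_at(track, truth.tad_boundaries)
        ok = np.isfinite(scores)
        res = h.wilcoxon_rank_sum(scores[ok & strong], scores[ok & ~strong])
        assert np.median(scores[ok & strong]) > np.median(scores[ok & ~strong])
        assert res.pvalue < 0.01

    def test_bh_adjustment_column(self, rng):
        scores = {("CTRL", "<=1"): rng.uniform(1, 3, 12),
                  ("TRT", "<=1"): rng.uniform(1, 3, 12) + 2,
                  ("CTRL", ">=2"): rng.uniform(1, 3, 12),
                  ("TRT", ">=2"): rng.uniform(1, 3, 12)}
        table = h.compare_stratified(scores, "CTRL", "TRT", adjust="bh")
        ok = table["pvalue"].notna()
        assert (table.loc[ok, "pvalue_adj"] >= table.loc[ok, "pvalue"] - 1e-12).all()
        with pytest.raises(ValueError, match="adjustment"):
            h.compare_stratified(scores, "CTRL", "TRT", adjust="holm")

    def test_stratification_conserves_counts(self, rng):
        bounds = pd.DataFrame({
            "chrom": ["chr1"] * 10, "bin": range(10),
            "start": np.arange(10) * 40_000,
            "end": (np.arange(10) + 1) * 40_000, "score": rng.uniform(1, 5, 10)})
        sites = pd.DataFrame({
            "chrom": ["chr1"] * 6,
            "start": rng.integers(0, 390_000, 6)})
        sites["end"] = sites["start"] + 200
        out = h.count_sites_per_boundary(bounds, sites)
        assert len(out) == 10
        assert ((out["site_category"] == "<=1") | (out["site_category"] == ">=2")).all()


class TestReplicateDissimilarity:
    def test_identity_and_negation_bounds(self, rng):
        v = rng.normal(size=50)
        w = rng.normal(size=50)
        frame, merges, newick, low = h.replicate_dissimilarity(
            {"a": v, "b": v.copy(), "c": -v, "d": w})
        assert frame.loc["a", "b"] == pytest.approx(0.0)
        assert frame.loc["a", "c"] == pytest.approx(2.0)
        assert ((frame.values >= -1e-9) & (frame.values <= 2 + 1e-9)).all()
        assert np.allclose(frame.values, frame.values.T)
        assert newick.endswith(";")

    def test_replicates_merge_before_conditions(self, rng):
        # two underlying profiles, two noisy replicates each: the
        # dendrogram pairs replicates first
        base1 = np.sign(rng.normal(size=80))
        base2 = np.sign(rng.normal(size=80))
        tracks = {
            "c1_r1": base1 + rng.normal(0, 0.2, 80),
            "c1_r2": base1 + rng.normal(0, 0.2, 80),
            "c2_r1": base2 + rng.normal(0, 0.2, 80),
            "c2_r2": base2 + rng.normal(0, 0.2, 80),
        }
        _, merges, _, _ = h.replicate_dissimilarity(tracks)
        first_two = {frozenset(a | b) for a, b in merges[:2]}
        assert first_two == {frozenset({"c1_r1", "c1_r2"}),
                             frozenset({"c2_r1", "c2_r2"})}

    def test_low_coverage_pair_flagged(self, rng):
        v = rng.normal(size=40)
        w = v.copy()
        w[:25] = np.nan
        _, _, _, low = h.replicate_dissimilarity({"a": v, "b": w})
        assert ("a", "b") in low
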