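"""Eigenvector compartment calling, saddle plots, switching."""

import numpy as np
import pytest

import hictopo as h
from hictopo.balance import CorrelationMaps
from hictopo.compartments import EigenTrack, _quantile_groups


class TestEigenvector:
    def test_planted_sign_pattern_recovered(self, comp_setup):
        s = comp_setup
        vals, c = s["eig"].values, s["truth"].compartment_profile
        ok = np.isfinite(vals) & (c != 0)
        assert (np.sign(vals[ok]) == np.sign(c[ok])).mean() > 0.95

    def test_labels_match_sign(self, comp_setup):
        eig = comp_setup["eig"]
        labels = eig.labels
        pos = np.nan_to_num(eig.values) > 0
        assert np.all(labels[pos] == "A")

    def test_negated_reference_flips_track(self, comp_setup):
        s = comp_setup
        flipped = h.compartment_eigenvector(s["corr"],
                                            -s["truth"].compartment_profile)
        np.testing.assert_allclose(flipped.values, -s["eig"].values,
                                   equal_nan=True)

    def test_permutation_equivariance(self, comp_setup):
        s = comp_setup
        bins = s["bins"]
        rng = np.random.default_rng(1)
        perm = np.concatenate([
            sl.start + rng.permutation(sl.stop - sl.start)
            for sl in bins.chrom_slices.values()])
        maps = {}
        for chrom, sl in bins.chrom_slices.items():
            local = perm[sl] - sl.start
            maps[chrom] = s["corr"].maps[chrom][np.ix_(local, local)]
        permuted = CorrelationMaps(bins, maps, dict(s["corr"].degenerate))
        eig_p = h.compartment_eigenvector(
            permuted, s["truth"].compartment_profile[perm])
        unpermuted = np.full_like(eig_p.values, np.nan)
        unpermuted[perm] = eig_p.values
        np.testing.assert_allclose(unpermuted, s["eig"].values,
                                   rtol=1e-8, atol=1e-10, equal_nan=True)

    def test_uninformative_reference_flagged_ambiguous(self, comp_setup):
        s = comp_setup
        flat = np.zeros(len(s["bins"]))   # carries no orientation signal
        with pytest.warns(RuntimeWarning, match="ambiguous"):
            eig = h.compartment_eigenvector(s["corr"], flat)
        assert all(eig.ambiguous.values())


class TestTransEigenvector:
    def test_trans_track_correlates_with_cis(self, comp_setup):
        s = comp_setup
        teig = h.trans_eigenvector(s["oe"], s["truth"].compartment_profile)
        both = np.isfinite(teig.values) & np.isfinite(s["eig"].values)
        r = np.corrcoef(teig.values[both], s["eig"].values[both])[0, 1]
        assert r > 0.8

    def test_no_trans_plaid_is_ambiguous(self):
        bins = h.make_bins({"chr1": 10_000_000, "chr2": 10_000_000}, 500_000)
        cfg = h.GeneratorConfig(
            chrom_sizes={"chr1": 10_000_000, "chr2": 10_000_000},
            with_tads=False, n_loops=0, plaid_strength=0.0, depth=5e5,
            compartment_block_mean=3_000_000, compartment_block_min=1_500_000)
        truth = h.plant_truth(bins, cfg, 8)
        mat = h.simulate_contacts(truth, bins, 9)
        bal = h.ice_balance(mat)
        oe = h.observed_over_expected(bal, h.expected_by_distance(bal))
        with pytest.warns(RuntimeWarning, match="ambiguous"):
            teig = h.trans_eigenvector(oe, np.zeros(len(bins)))
        assert all(teig.ambiguous.values())

    def test_rnase_contracts_negative_trans_eigenvalues(self, comp_setup):
        from scipy.stats import mannwhitneyu
        s = comp_setup
        pert = h.apply_perturbation(s["truth"], "rnase_like", f_bb=0.5)
        mat = h.simulate_contacts(pert, s["bins"], 14)
        bal = h.ice_balance(mat)
        oe = h.observed_over_expected(bal, h.expected_by_distance(bal))
        te_pert = h.trans_eigenvector(oe, s["truth"].compartment_profile)
        te_ctrl = h.trans_eigenvector(s["oe"], s["truth"].compartment_profile)
        neg_c = te_ctrl.values[np.nan_to_num(te_ctrl.values) < 0]
        neg_p = te_pert.values[np.nan_to_num(te_pert.values) < 0]
        # B-type values move toward zero (one-sided rank test)
        assert mannwhitneyu(neg_p, neg_c, alternative="greater").pvalue < 0.01


class TestSaddle:
    def test_unit_oe_gives_unit_saddle(self, comp_setup):
        bins = comp_setup["bins"]
        oe = h.ContactMatrix(bins, np.ones((len(bins), len(bins))))
        rng = np.random.default_rng(3)
        eig = EigenTrack(bins, rng.normal(size=len(bins)), "cis", 500_000)
        sad = h.saddle(eig, oe, "cis", 10)
        vals = sad.matrix[np.isfinite(sad.matrix)]
        assert np.allclose(vals, 1.0)

    def test_quantile_partition_sizes(self):
        values = np.arange(61, dtype=float)
        gid = _quantile_groups(values, np.ones(61, dtype=bool), 30)
        sizes = np.bincount(gid[gid >= 0])
        assert sizes.min() >= 2 and sizes.max() <= 3 and sizes.sum() == 61

    def test_too_few_bins_rejected(self, comp_setup):
        bins = comp_setup["bins"]
        vals = np.full(len(bins), np.nan)
        vals[:10] = np.arange(10)
        eig = EigenTrack(bins, vals, "cis", 500_000)
        with pytest.raises(ValueError, match="quantiles"):
            h.saddle(eig, comp_setup["oe"], "cis", 30)

    def test_planted_plaid_corner_ordering(self, comp_setup):
        s = comp_setup
        for scope in ("cis", "trans"):
            sad = h.saddle(s["eig"], s["oe"], scope, 10)
            corners = sad.corners
            assert corners["BB"] > corners["AB"]
            assert corners["AA"] > corners["AB"]

    def test_saddle_mean_conserved(self, comp_setup):
        sad = h.saddle(comp_setup["eig"], comp_setup["oe"], "cis", 10)
        ok = np.isfinite(sad.matrix) & (sad.counts > 0)
        weighted = (sad.matrix[ok] * sad.counts[ok]).sum() / sad.counts[ok].sum()
        assert weighted == pytest.approx(1.0, abs=0.05)

    def test_orientation_invariance_of_corners(self, comp_setup):
        s = comp_setup
        flipped = h.compartment_eigenvector(s["corr"],
                                            -s["truth"].compartment_profile)
        a = h.saddle(s["eig"], s["oe"], "cis", 10).corners
        b = h.saddle(flipped, s["oe"], "cis", 10).corners
        # a global flip consistent with the reference swaps A and B
        # labels; quantile boundaries shift by at most one bin per group
        # when the group sizes are uneven, hence the small tolerance
        assert a["AA"] == pytest.approx(b["BB"], rel=0.05)
        assert a["BB"] == pytest.approx(b["AA"], rel=0.05)


def _track(bins, values):
    return EigenTrack(bins, np.asarray(values, dtype=float), "cis", bins.resolution)


@pytest.fixture(scope="module")
def bins():
    return h.make_bins({"chr1": 10_000_000}, 500_000)


class TestSwitching:

    def test_identical_conditions_fully_stable(self, bins, rng):
        v = rng.normal(size=20)
        summary = h.compartment_switching((_track(bins, v), _track(bins, v)),
                                          (_track(bins, v), _track(bins, v)),
                                          n_rand=10, seed=0)
        assert summary.stable_fraction == 1.0
        assert summary.fractions["A_to_B"] == 0.0

    def test_sign_flip_fully_switched(self, bins, rng):
        v = rng.normal(size=20)
        summary = h.compartment_switching((_track(bins, v), _track(bins, v)),
                                          (_track(bins, -v), _track(bins, -v)),
                                          n_rand=10, seed=0)
        assert summary.stable_fraction == 0.0
        assert summary.fractions["A_to_B"] + summary.fractions["B_to_A"] == 1.0

    def test_fractions_sum_to_one(self, bins, rng):
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        summary = h.compartment_switching((_track(bins, a), _track(bins, a)),
                                          (_track(bins, b), _track(bins, b)),
                                          n_rand=10, seed=0)
        assert sum(summary.fractions.values()) == pytest.approx(1.0)

    def test_permutation_null_matches_closed_form(self):
        # 50/50 A/B labels: expected stable fraction under permutation
        # is pA^2 + pB^2 = 0.5
        bins = h.make_bins({"chr1": 50_000_000}, 500_000)
        v = np.where(np.arange(100) % 2 == 0, 1.0, -1.0)
        summary = h.compartment_switching((_track(bins, v), _track(bins, v)),
                                          (_track(bins, v), _track(bins, v)),
                                          n_rand=400, seed=1)
        rand_stable = (summary.random_mean["stable_A"]
                       + summary.random_mean["stable_B"])
        assert rand_stable == pytest.approx(0.5, abs=0.02)

    def test_no_joint_bins_rejected(self, bins):
        v = np.full(20, np.nan)
        with pytest.raises(ValueError, match="reproducible"):
            h.compartment_switching((_track(bins, v), _track(bins, v)),
                                    (_track(bins, v), _track(bins, v)))
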