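"""Generator: planted structure, Poisson sampling, perturbation models."""

import dataclasses

import numpy as np
import pytest

import hictopo as h
from hictopo.synthetic import IntensityModel

GENOME = {"chr1": 20_000_000, "chr2": 20_000_000}


class TestPlantTruth:
    def test_deterministic_given_seed(self):
        bins = h.make_bins(GENOME, 40_000)
        cfg = h.GeneratorConfig()
        assert h.plant_truth(bins, cfg, 5) == h.plant_truth(bins, cfg, 5)
        assert h.plant_truth(bins, cfg, 5) != h.plant_truth(bins, cfg, 6)

    def test_zero_loops_config(self):
        bins = h.make_bins(GENOME, 40_000)
        truth = h.plant_truth(bins, h.GeneratorConfig(n_loops=0), 1)
        assert truth.loops == []

    def test_small_tads_rejected(self):
        bins = h.make_bins(GENOME, 500_000)
        cfg = h.GeneratorConfig(tad_size_min=1_000_000)  # 2 bins at 500 kb
        with pytest.raises(ValueError, match="TAD"):
            h.plant_truth(bins, cfg, 1)

    def test_boundary_spacing_matches_config(self):
        # mean TAD 1 Mb on 20 Mb chromosomes -> ~19 boundaries each,
        # mean spacing ~25 bins at 40 kb
        bins = h.make_bins(GENOME, 40_000)
        cfg = h.GeneratorConfig(n_loops=0)
        spacings, counts = [], []
        for seed in range(100):
            truth = h.plant_truth(bins, cfg, seed)
            for sl in bins.chrom_slices.values():
                local = truth.tad_boundaries[
                    (truth.tad_boundaries >= sl.start) & (truth.tad_boundaries < sl.stop)]
                counts.append(local.size)
                spacings.extend(np.diff(local))
        assert abs(np.mean(spacings) - 25) < 2.5      # within 10% of 1 Mb
        assert abs(np.mean(counts) - 19) < 2

    def test_truth_roundtrip_serialization(self, tmp_path):
        bins = h.make_bins(GENOME, 25_000)
        truth = h.plant_truth(bins, h.GeneratorConfig(), 9)
        h.save_truth(truth, tmp_path / "truth.txt")
        assert h.load_truth(tmp_path / "truth.txt") == truth


class TestSimulateContacts:
    def test_seed_reproducibility(self):
        bins = h.make_bins({"chr1": 4_000_000}, 500_000)
        cfg = h.GeneratorConfig(chrom_sizes={"chr1": 4_000_000}, with_tads=False,
                                n_loops=0, compartment_block_mean=2_000_000,
                                compartment_block_min=1_000_000)
        truth = h.plant_truth(bins, cfg, 1)
        m1 = h.simulate_contacts(truth, bins, 7)
        m2 = h.simulate_contacts(truth, bins, 7)
        np.testing.assert_array_equal(m1.counts, m2.counts)
        m3 = h.simulate_contacts(truth, bins, 8)
        assert not np.array_equal(m1.counts, m3.counts)

    def test_diagonal_means_match_analytic_decay(self):
        # decay-only surface: per-diagonal mean ~ depth-scaled d^-alpha
        sizes = {"chr1": 20_000_000}
        bins = h.make_bins(sizes, 40_000)
        cfg = h.GeneratorConfig(chrom_sizes=sizes, with_tads=False, n_loops=0,
                                plaid_strength=0.0, trans_depth=0.0)
        truth = h.plant_truth(bins, cfg, 2)
        lam = IntensityModel(truth, bins).cis("chr1")
        mat = h.simulate_contacts(truth, bins, 3)
        for d in (2, 5, 20, 100):
            obs = np.diagonal(mat.counts, offset=d)
            exp = np.diagonal(lam, offset=d)
            se = np.sqrt(exp.sum()) / exp.size
            assert abs(obs.mean() - exp.mean()) < 3 * se

    def test_moment_recovery_overall(self):
        # aggregate relative error of per-diagonal means < 5% at depth 2e6
        sizes = {"chr1": 20_000_000}
        bins = h.make_bins(sizes, 40_000)
        cfg = h.GeneratorConfig(chrom_sizes=sizes, trans_depth=0.0, n_loops=0)
        truth = h.plant_truth(bins, cfg, 4)
        lam = IntensityModel(truth, bins).cis("chr1")
        mat = h.simulate_contacts(truth, bins, 5)
        rel = []
        for d in range(2, 400, 7):
            obs = np.diagonal(mat.counts, offset=d).mean()
            exp = np.diagonal(lam, offset=d).mean()
            rel.append(abs(obs - exp) / exp)
        assert np.median(rel) < 0.05

    def test_depth_doubling_doubles_counts(self):
        sizes = {"chr1": 10_000_000}
        bins = h.make_bins(sizes, 40_000)
        base = dict(chrom_sizes=sizes, with_tads=False, n_loops=0, trans_depth=0.0)
        t1 = h.plant_truth(bins, h.GeneratorConfig(**base, depth=5e5), 1)
        t2 = h.plant_truth(bins, h.GeneratorConfig(**base, depth=1e6), 1)
        c1 = h.simulate_contacts(t1, bins, 2).counts.sum()
        c2 = h.simulate_contacts(t2, bins, 3).counts.sum()
        assert abs(c2 / c1 - 2.0) < 0.02

    def test_replicate_eigenvector_consistency(self, comp_setup):
        # two replicates from the same truth agree on the 1st eigenvector
        s = comp_setup
        mat2 = h.simulate_contacts(s["truth"], s["bins"], 13)
        bal2 = h.ice_balance(mat2)
        oe2 = h.observed_over_expected(bal2, h.expected_by_distance(bal2))
        eig2 = h.compartment_eigenvector(
            h.pearson_correlation_map(oe2), s["truth"].compartment_profile)
        both = np.isfinite(s["eig"].values) & np.isfinite(eig2.values)
        r = np.corrcoef(s["eig"].values[both], eig2.values[both])[0, 1]
        assert r > 0.9


@pytest.fixture(scope="module")
def truth():
    bins = h.make_bins(GENOME, 25_000)
    return h.plant_truth(bins, h.GeneratorConfig(), 3)


class TestPerturbations:

    def test_rnase_identity_at_unit_factor(self, truth):
        assert h.apply_perturbation(truth, "rnase_like", f_bb=1.0) == truth

    def test_rnase_touches_only_bb_attenuation(self, truth):
        pert = h.apply_perturbation(truth, "rnase_like", f_bb=0.6)
        assert pert.bb_attenuation == pytest.approx(0.6)
        np.testing.assert_array_equal(pert.tad_boundaries, truth.tad_boundaries)
        np.testing.assert_array_equal(pert.boundary_permeability,
                                      truth.boundary_permeability)
        assert pert.loops == truth.loops

    def test_actd_touches_only_tads_and_loops(self, truth):
        pert = h.apply_perturbation(truth, "actd_like",
                                    permeability_rescue=0.5, loop_retain=0.5)
        np.testing.assert_array_equal(pert.compartment_profile,
                                      truth.compartment_profile)
        assert pert.plaid_strength == truth.plaid_strength
        assert pert.bb_attenuation == truth.bb_attenuation
        p = truth.boundary_permeability
        np.testing.assert_allclose(pert.boundary_permeability, p + 0.5 * (1 - p))
        for (_, _, e0), (_, _, e1) in zip(truth.loops, pert.loops):
            assert e1 == pytest.approx(1 + 0.5 * (e0 - 1))

    def test_input_not_modified(self, truth):
        snapshot = dataclasses.replace(truth)
        h.apply_perturbation(truth, "actd_like", permeability_rescue=1.0)
        assert truth == snapshot

    def test_unknown_kind_rejected(self, truth):
        with pytest.raises(ValueError, match="unknown perturbation"):
            h.apply_perturbation(truth, "heat_shock")
        with pytest.raises(ValueError):
            h.apply_perturbation(truth, "rnase_like", f_bb=0.0)
        with pytest.raises(ValueError):
            h.apply_perturbation(truth, "rnase_like", nonsense=1)

    def test_full_permeability_rescue_erases_insulation(self):
        # all permeabilities -> 1: insulation contrast at planted
        # boundaries collapses to ~0
        sizes = {"chr1": 20_000_000}
        bins = h.make_bins(sizes, 40_000)
        cfg = h.GeneratorConfig(chrom_sizes=sizes, n_loops=0, tad_boost=1.0,
                                trans_depth=0.0)
        truth = h.plant_truth(bins, cfg, 6)
        flat = h.apply_perturbation(truth, "actd_like",
                                    permeability_rescue=1.0, loop_retain=1.0)
        assert np.all(flat.boundary_permeability == 1.0)
        mat = h.simulate_contacts(flat, bins, 7)
        track = h.insulation_track(h.ice_balance(mat))
        scores = h.boundary_scores_at(track, truth.tad_boundaries)
        assert np.nanmedian(np.abs(scores)) < 0.3
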