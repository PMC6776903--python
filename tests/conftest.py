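"""Shared fixtures: one simulated study per analysis resolution, reused
across test modules to keep the suite fast."""

import numpy as np
import pytest

import hictopo as h

GENOME = {"chr1": 20_000_000, "chr2": 20_000_000}


@pytest.fixture(scope="session")
def comp_setup():
    """Compartment-resolution (500 kb) study: plaid only, no TADs/loops."""
    bins = h.make_bins(GENOME, 500_000)
    cfg = h.GeneratorConfig(with_tads=False, n_loops=0, depth=1e6)
    truth = h.plant_truth(bins, cfg, 11)
    mat = h.simulate_contacts(truth, bins, 12)
    bal = h.ice_balance(mat)
    oe = h.observed_over_expected(bal, h.expected_by_distance(bal))
    corr = h.pearson_correlation_map(oe)
    eig = h.compartment_eigenvector(corr, truth.compartment_profile)
    return dict(bins=bins, cfg=cfg, truth=truth, mat=mat, bal=bal, oe=oe,
                corr=corr, eig=eig)


@pytest.fixture(scope="session")
def tad_setup():
    """TAD-resolution (40 kb) study: decay + TADs + plaid, no loops."""
    bins = h.make_bins(GENOME, 40_000)
    cfg = h.GeneratorConfig(n_loops=0)
    truth = h.plant_truth(bins, cfg, 21)
    mat = h.simulate_contacts(truth, bins, 22)
    bal = h.ice_balance(mat)
    track = h.insulation_track(bal)
    bounds = h.call_boundaries(track)
    return dict(bins=bins, cfg=cfg, truth=truth, mat=mat, bal=bal,
                track=track, bounds=bounds)


@pytest.fixture(scope="session")
def apa_setup():
    """Loop-resolution (25 kb) study with 40 planted loops at 3-fold."""
    bins = h.make_bins(GENOME, 25_000)
    cfg = h.GeneratorConfig()
    truth = h.plant_truth(bins, cfg, 31)
    mat = h.simulate_contacts(truth, bins, 32)
    bal = h.ice_balance(mat)
    oe = h.observed_over_expected(bal, h.expected_by_distance(bal))
    return dict(bins=bins, cfg=cfg, truth=truth, bal=bal, oe=oe)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
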