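import math

import numpy as np
import pytest

import resikit as rk
from resikit.errors import ValidationError


class TestLayouts:
    def test_pair_grid_geometry(self):
        lay = rk.make_layout("pair_grid", n_pairs=6, pitch=20.0, pair_offset=0.7)
        assert lay.n_sites == 12
        sites = lay.sites
        # pair k occupies rows (2k, 2k+1) at the designed offset
        for k in range(6):
            d = np.linalg.norm(sites[2 * k] - sites[2 * k + 1])
            assert d == pytest.approx(0.7, abs=1e-12)
        # pair centres sit on a 20 nm grid
        centres = 0.5 * (sites[0::2] + sites[1::2])
        diffs = np.linalg.norm(centres[1] - centres[0])
        assert diffs == pytest.approx(20.0)

    def test_pair_grid_subnanometre_offset(self):
        lay = rk.make_layout("pair_grid", pair_offset=0.7)
        d = np.linalg.norm(lay.sites[0] - lay.sites[1])
        assert d == pytest.approx(0.7)

    def test_ring_complex_geometry(self):
        lay = rk.make_layout("ring_complex")
        assert lay.n_sites == 32
        assert lay.is_3d
        sites = lay.sites
        # pairs are consecutive rows; lateral split 11.9 nm, axial 5.4 nm
        for k in range(16):
            a, b = sites[2 * k], sites[2 * k + 1]
            lateral = np.linalg.norm(a[:2] - b[:2])
            axial = abs(a[2] - b[2])
            assert lateral == pytest.approx(11.9, rel=1e-3)
            assert axial == pytest.approx(5.4, abs=1e-9)
        # two rings, eight pairs each, eightfold symmetric
        z_levels = np.unique(np.round(0.5 * (sites[0::2, 2] + sites[1::2, 2]), 6))
        assert len(z_levels) == 2

    def test_csr_zero_density(self):
        lay = rk.make_layout("csr", density=0.0, area=100.0, seed=1)
        assert lay.n_sites == 0

    def test_csr_poisson_mean(self):
        """Site count over many seeds matches Poisson mean = density * area."""
        counts = [
            rk.make_layout("csr", density=200.0, area=25.0, seed=s).n_sites
            for s in range(1000)
        ]
        mean = np.mean(counts)
        se = math.sqrt(5000.0 / 1000)  # Poisson s.e. of the mean
        assert abs(mean - 5000.0) < 3 * se

    def test_invalid_params(self):
        with pytest.raises(ValidationError):
            rk.make_layout("grid", pitch=-5.0)
        with pytest.raises(ValidationError):
            rk.make_layout("csr", density=-1.0, area=10.0)
        with pytest.raises(ValidationError):
            rk.make_layout("csr", density=1.0, area=0.0)


class TestAssignChannels:
    def test_single_round_all_zero(self):
        lay = rk.make_layout("grid", nx=5, ny=5)
        out = rk.assign_channels(lay, 1, seed=0)
        assert (out.channel_of_site == 0).all()

    def test_uniform_frequencies(self):
        lay = rk.make_layout("csr", density=1000.0, area=100.0, seed=2)
        out = rk.assign_channels(lay, 4, seed=3)
        n = out.n_sites
        freqs = np.bincount(out.channel_of_site, minlength=4) / n
        se = math.sqrt(0.25 * 0.75 / n)
        assert np.all(np.abs(freqs - 0.25) < 3 * se)

    def test_pair_distinct_fraction(self):
        """Fraction of site pairs with distinct channels ~ 1 - 1/4 = 75%."""
        lay = rk.make_layout("pair_grid", n_pairs=6)
        distinct = total = 0
        for seed in range(2000):
            out = rk.assign_channels(lay, 4, seed=seed)
            ch = out.channel_of_site
            distinct += int(np.sum(ch[0::2] != ch[1::2]))
            total += 6
        frac = distinct / total
        se = math.sqrt(0.75 * 0.25 / total)
        assert abs(frac - 0.75) < 3 * se

    def test_reproducible(self):
        lay = rk.make_layout("grid", nx=10, ny=10)
        a = rk.assign_channels(lay, 4, seed=5)
        b = rk.assign_channels(lay, 4, seed=5)
        assert (a.channel_of_site == b.channel_of_site).all()


class TestSampleLocalizations:
    def test_scatter_sigma(self):
        lay = rk.GroundTruthLayout(np.zeros((1, 2)), np.zeros(1, int))
        (tab,) = rk.sample_localizations(lay, 3.0, locs_per_site=10_000, seed=1)
        sd = tab.locs["x"].std(ddof=1)
        se = 3.0 / math.sqrt(2 * 10_000)
        assert abs(sd - 3.0) < 3 * se
        assert (tab.locs["lp"] == 3.0).all()

    def test_uniform_mean_frame(self):
        lay = rk.GroundTruthLayout(np.zeros((1, 2)), np.zeros(1, int))
        meta = rk.AcquisitionMeta(n_frames=10_000)
        (tab,) = rk.sample_localizations(lay, 3.0, locs_per_site=1000, meta=meta, seed=2)
        mean_frame = tab.locs["frame"].mean()
        se = 10_000 / math.sqrt(12 * 1000)
        assert abs(mean_frame - 5000) < 3 * se

    def test_default_axial_spread_twofold(self):
        lay = rk.GroundTruthLayout(np.zeros((1, 3)), np.zeros(1, int))
        (tab,) = rk.sample_localizations(lay, 3.0, locs_per_site=10_000, seed=3)
        sd_z = tab.locs["z"].std(ddof=1)
        se = 6.0 / math.sqrt(2 * 10_000)
        assert abs(sd_z - 6.0) < 3 * se

    def test_empty_layout_gives_empty_tables(self):
        lay = rk.GroundTruthLayout(np.empty((0, 2)), np.empty(0, int), n_rounds=2)
        tabs = rk.sample_localizations(lay, 3.0, seed=0)
        assert len(tabs) == 2 and all(len(t) == 0 for t in tabs)

    def test_bit_reproducible(self):
        lay = rk.assign_channels(rk.make_layout("grid", nx=3, ny=3), 2, seed=1)
        a = rk.sample_localizations(lay, 2.0, locs_per_site=50, seed=9)
        b = rk.sample_localizations(lay, 2.0, locs_per_site=50, seed=9)
        for ta, tb in zip(a, b):
            assert ta.locs.equals(tb.locs)

    def test_sticking_frames_within_span(self):
        lay = rk.GroundTruthLayout(np.zeros((20, 2)), np.zeros(20, int))
        blink = rk.BlinkModel(sticking_fraction=1.0, sticking_span=300)
        meta = rk.AcquisitionMeta(n_frames=10_000)
        (tab,) = rk.sample_localizations(lay, 2.0, locs_per_site=50, blink=blink,
                                         meta=meta, seed=4)
        # 20 true sites + ~20 artifacts; artifacts occupy rows after the sites
        frames = tab.locs["frame"].to_numpy()
        art = frames[20 * 50:]
        assert len(art) > 0
        # each artifact cluster of 50 consecutive rows spans <= 300 frames
        for i in range(0, len(art), 50):
            chunk = art[i : i + 50]
            assert chunk.max() - chunk.min() < 300


class TestSimulateMixture:
    def test_zero_labelling_efficiency(self):
        mp = rk.MixtureParams(density_monomers=100.0, labelling_efficiency=0.0, area=10.0)
        assert len(rk.simulate_mixture(mp, seed=0)) == 0

    def test_csr_null_model_density(self):
        """RTX comparison parameters: 212 monomers/um2, no dimers, 50%
        efficiency -> observed density ~ 106/um2."""
        mp = rk.MixtureParams(density_monomers=212.0, density_dimers=0.0,
                              uncertainty=5.0, labelling_efficiency=0.5, area=100.0)
        pts = rk.simulate_mixture(mp, seed=1)
        observed = len(pts) / 100.0
        se = math.sqrt(106.0 * 100.0) / 100.0
        assert abs(observed - 106.0) < 3 * se

    def test_intra_pair_distance(self):
        """Dimer-only, zero uncertainty: intra-pair distance is exactly D on
        average (sample mean over ~1e5 pairs)."""
        mp = rk.MixtureParams(density_dimers=100.0, dimer_distance=13.5,
                              uncertainty=0.0, labelling_efficiency=1.0, area=1000.0)
        pts, labels = rk.simulate_mixture(mp, seed=2, return_labels=True)
        dists = []
        order = np.argsort(labels)
        labels_s, pts_s = labels[order], pts[order]
        # complete pairs only (both members inside the core window)
        uniq, counts = np.unique(labels_s, return_counts=True)
        full = set(uniq[counts == 2])
        by_label = {}
        for lab, p in zip(labels_s, pts_s):
            by_label.setdefault(lab, []).append(p)
        dists = [np.linalg.norm(v[0] - v[1]) for k, v in by_label.items() if k in full]
        assert len(dists) > 50_000
        assert np.mean(dists) == pytest.approx(13.5, abs=1e-6)

    def test_thinning_expectation(self):
        mp_full = rk.MixtureParams(density_monomers=200.0, labelling_efficiency=1.0,
                                   area=100.0)
        mp_half = rk.MixtureParams(density_monomers=200.0, labelling_efficiency=0.5,
                                   area=100.0)
        n_full = np.mean([len(rk.simulate_mixture(mp_full, seed=s)) for s in range(20)])
        n_half = np.mean([len(rk.simulate_mixture(mp_half, seed=s)) for s in range(20)])
        assert n_half / n_full == pytest.approx(0.5, rel=0.05)

    def test_reproducible(self):
        mp = rk.MixtureParams(density_monomers=50.0, density_dimers=20.0,
                              dimer_distance=10.0, uncertainty=3.0,
                              labelling_efficiency=0.7, area=50.0)
        a = rk.simulate_mixture(mp, seed=3)
        b = rk.simulate_mixture(mp, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_invalid_area(self):
        with pytest.raises(ValidationError):
            rk.MixtureParams(area=0.0)


def test_mixture_from_fit_params_density_bookkeeping():
    """Observed density = ground-truth molecule density * labelling
    efficiency, with the monomer/dimer split given by frac_of_dimers."""
    mp = rk.mixture_from_fit_params(13.5, 5.5, 47.0, 50.0, 0.5, 420.0)
    rho_total = mp.density_monomers + 2 * mp.density_dimers
    assert rho_total * 0.5 == pytest.approx(50.0)
    assert 2 * mp.density_dimers / rho_total == pytest.approx(0.47)
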