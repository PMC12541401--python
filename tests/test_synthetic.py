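"""Imaging calibrations, phantom generation and observable recovery."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oxydrop.observables import core_radius_profile
from oxydrop.synthetic import (
    PhantomConfig,
    beer_lambert,
    beer_lambert_inverse,
    henry_concentration,
    henry_pressure,
    phantom_droplet,
    recover_observables,
    rudpp_fluorescence,
    rudpp_inverse,
    sector_average,
)


class TestBeerLambert:
    def test_no_cells_full_transmission(self):
        assert beer_lambert(0.0, 130.0, 0.5) == 1.0

    def test_half_attenuation(self):
        # eps*c*path = ln 2 transmits exactly one half
        assert beer_lambert(math.log(2) / 130.0, 130.0, 1.0) == pytest.approx(0.5)

    @given(st.floats(1e-6, 1.0), st.floats(10, 500), st.floats(1e-3, 10))
    def test_round_trip(self, c, path, eps):
        T = beer_lambert(c, path, eps)
        if T > 0:  # extreme attenuation underflows to 0
            assert beer_lambert_inverse(T, path, eps) == pytest.approx(c, rel=1e-9)

    def test_inverse_domain(self):
        with pytest.raises(ValueError):
            beer_lambert_inverse(1.5, 130.0, 1.0)
        with pytest.raises(ValueError):
            beer_lambert_inverse(0.0, 130.0, 1.0)


class TestRudpp:
    def test_anoxic_and_quenched_limits(self):
        assert rudpp_fluorescence(0.0) == pytest.approx(7.5)
        assert rudpp_fluorescence(1e6) == pytest.approx(1.0)

    def test_reference_point(self):
        assert rudpp_fluorescence(3.0) == pytest.approx(1 + 6.5 / math.e, rel=1e-12)
        assert rudpp_fluorescence(3.0) == pytest.approx(3.391, abs=1e-3)

    @given(st.floats(0.0, 60.0))
    def test_round_trip(self, p):
        # (I-1) cancellation limits absolute accuracy at high pO2
        assert rudpp_inverse(rudpp_fluorescence(p)) == pytest.approx(p, abs=1e-6)

    def test_inverse_domain(self):
        with pytest.raises(ValueError):
            rudpp_inverse(1.0)  # at/below the fully quenched asymptote
        with pytest.raises(ValueError):
            rudpp_inverse(8.0)


class TestHenry:
    def test_atmospheric_anchor(self):
        # H = cO2_sat/160 mmHg maps atmospheric pO2 to saturation
        H = 250.0 / 160.0
        assert henry_concentration(160.0, H) == pytest.approx(250.0)

    @given(st.floats(0, 200), st.floats(0.1, 10))
    def test_linearity_and_round_trip(self, p, H):
        c = henry_concentration(p, H)
        assert c == pytest.approx(H * p)
        assert henry_pressure(c, H) == pytest.approx(p, rel=1e-12, abs=1e-12)

    def test_rejects_bad_H(self):
        with pytest.raises(ValueError):
            henry_concentration(10.0, 0.0)


class TestSectorAverage:
    def _radial_image(self, n=201, px=1.0):
        x = (np.arange(n) - n // 2) * px
        X, Y = np.meshgrid(x, x)
        r = np.hypot(X, Y)
        return 1.0 + 0.01 * r, r

    def test_recovers_radial_function(self):
        img, r = self._radial_image()
        edges = np.linspace(0, 90, 31)
        prof, counts = sector_average(img, (100, 100), math.pi / 8, edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        assert np.all(counts[3:] > 0)
        assert np.allclose(prof[3:], 1.0 + 0.01 * centers[3:], atol=5e-3)

    def test_rotation_invariance_on_symmetric_image(self):
        img, _ = self._radial_image()
        edges = np.linspace(0, 90, 31)
        p0, _ = sector_average(img, (100, 100), math.pi / 8, edges, angle=0.0)
        p1, _ = sector_average(img, (100, 100), math.pi / 8, edges, angle=math.pi / 3)
        assert np.allclose(p0[3:], p1[3:], atol=5e-3)

    def test_perturbed_rim_bounded_by_eps_R(self):
        """Two sectors 60 degrees apart on an m=3 phantom differ near the rim
        by the geometric shift of order eps*R."""
        cfg = PhantomConfig(R_um=1000.0, pixel_size_um=10.0, eps_boundary=0.03,
                            mode=3, noise=0.0, seed=0)
        r = np.linspace(5, 1000, 100)
        prof = np.linspace(1.0, 0.0, 100)[None, :] * 0.05  # radial ramp of cells
        ph = phantom_droplet(r, prof, np.full((1, 100), 250.0), [0.0], cfg)
        img = ph["brightfield"][0]
        n = img.shape[0]
        edges = np.linspace(0, 1000, 51) / 10.0
        pa, _ = sector_average(img, (n // 2, n // 2), math.pi / 24, edges, angle=0.0)
        pb, _ = sector_average(img, (n // 2, n // 2), math.pi / 24, edges, angle=math.pi / 3)
        # crest vs trough of cos(3 theta): the pattern shifts radially by
        # ~2 eps R near the rim, while the center is barely affected
        rim_diff = np.max(np.abs(pa[40:48] - pb[40:48]))
        center_diff = np.max(np.abs(pa[:10] - pb[:10]))
        assert rim_diff > 5 * center_diff
        # translate the intensity difference into a radial shift using the
        # image's own radial slope near the rim, and bound it by the geometry
        slope = np.abs(np.gradient(pa, 20.0))[40:48].max()  # per μm (20 μm bins)
        shift = rim_diff / slope
        eps_R = 0.03 * 1000.0
        assert 0.3 * eps_R < shift < 3.0 * eps_R


class TestPhantom:
    def _small_stack(self, noise, seed, eps=0.0):
        r = np.linspace(2, 700, 120)
        cells = np.where(r < 400, 0.08, 0.02)[None, :]
        oxy = np.clip((r - 350) / 350, 0, 1)[None, :] * 250.0
        cfg = PhantomConfig(R_um=700.0, pixel_size_um=10.0, eps_boundary=eps,
                            mode=3, noise=noise, seed=seed)
        return phantom_droplet(r, cells, oxy, [0.0], cfg), (r, cells, oxy)

    def test_deterministic_given_seed(self):
        a, _ = self._small_stack(0.05, 42)
        b, _ = self._small_stack(0.05, 42)
        assert np.array_equal(a["brightfield"], b["brightfield"])
        assert np.array_equal(a["fluorescence"], b["fluorescence"])
        c, _ = self._small_stack(0.05, 43)
        assert not np.array_equal(a["brightfield"], c["brightfield"])

    def test_metadata_records_calibration(self):
        ph, _ = self._small_stack(0.0, 0)
        m = ph["meta"]
        assert m["seed"] == 0 and m["eps_att"] > 0
        # densest column transmits ~20% by the auto-calibration
        assert math.exp(-m["eps_att"] * 0.08 * m["path_um"]) == pytest.approx(0.2, rel=1e-6)

    def test_noiseless_round_trip(self):
        """With no noise and a circular droplet, recovery reproduces the
        generating profiles to within pixel-discretization error."""
        ph, (r, cells, oxy) = self._small_stack(0.0, 0)
        rec = recover_observables(ph, c_crit_uM=0.3, n_bins=70)
        sel = (rec["r_um"] > 30) & (rec["r_um"] < 650) & (np.abs(rec["r_um"] - 400) > 30)
        ci = np.interp(rec["r_um"], r, cells[0])
        assert np.allclose(rec["kymo_cell"][sel, 0], ci[sel], rtol=0.02)
        oi = np.interp(rec["r_um"], r, oxy[0])
        # probe-sensitive band only; the exponential calibration's convexity
        # across a bin limits the O2 channel to ~10% on this steep profile
        band = sel & (oi > 5) & (oi < 60)
        assert np.allclose(rec["kymo_oxy"][band, 0], oi[band], rtol=0.12)

    def test_profiles_must_cover_droplet(self):
        r = np.linspace(0, 300, 30)
        cfg = PhantomConfig(R_um=700.0, pixel_size_um=10.0)
        with pytest.raises(ValueError):
            phantom_droplet(r, np.ones((1, 30)), np.ones((1, 30)), [0.0], cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PhantomConfig(R_um=700.0, eps_boundary=0.2)
        with pytest.raises(ValueError):
            PhantomConfig(R_um=700.0, noise=-0.1)


@pytest.fixture(scope="module")
def phantom_and_truth(transient_traj):
    """5%-noise phantom of the small concentrated droplet trajectory."""
    p = transient_traj.params
    g = transient_traj.grid
    frames = slice(0, transient_traj.n_states, 8)
    r_um = g.centers * p.l_O2
    cc = transient_traj.c_cell[frames] * 0.04
    co = transient_traj.c_oxy[frames] * 250.0
    times_s = transient_traj.times[frames] * p.tau
    cfg = PhantomConfig(R_um=1400.0, pixel_size_um=10.0, eps_boundary=0.03,
                        mode=3, noise=0.05, seed=11)
    ph = phantom_droplet(r_um, cc, co, times_s, cfg)
    rec = recover_observables(ph, c_crit_uM=0.3)
    rtruth = np.array([core_radius_profile(c, r_um, 1400.0, 0.3) for c in co])
    return rec, rtruth, (r_um, co, times_s)


class TestRecoveryFromSimulation:
    @staticmethod
    def _vanish_time(r_core, times):
        formed = np.nonzero(r_core > 0)[0]
        gone = np.nonzero(r_core[formed[0]:] == 0)[0]
        return times[formed[0] + gone[0]]

    def test_ell_init_within_ten_percent(self, phantom_and_truth):
        rec, rtruth, _ = phantom_and_truth
        truth = 1400.0 - rtruth.max()
        assert abs(rec["ell_init_um"] - truth) / truth < 0.10

    def test_vanishing_time_within_fifteen_percent(self, phantom_and_truth):
        rec, rtruth, (_, _, times_s) = phantom_and_truth
        tv_t = self._vanish_time(rtruth, times_s)
        tv_r = self._vanish_time(rec["r_core_um"], times_s)
        assert abs(tv_r - tv_t) / tv_t < 0.15

    def test_total_oxygen_within_five_percent_after_formation(self, phantom_and_truth):
        rec, rtruth, (r_um, co, _) = phantom_and_truth
        truth = np.array(
            [
                np.sum(co[k][r_um >= rtruth[k]] * r_um[r_um >= rtruth[k]])
                / (250.0 * np.sum(r_um[r_um >= rtruth[k]]))
                for k in range(len(co))
            ]
        )
        post = np.nonzero(rtruth > 0)[0][0]
        assert np.max(np.abs(rec["total_o2"][post:] - truth[post:])) < 0.05

    def test_recovered_rim_saturated_early_and_core_anoxic(self, phantom_and_truth):
        rec, rtruth, _ = phantom_and_truth
        # early frames: recovered oxygen near the rim is at least at the
        # probe's sensitivity ceiling; core periphery reads ~0
        k = 3
        rim = rec["r_um"] > 1300.0
        assert np.nanmean(rec["kymo_oxy"][rim, 0]) > 50.0
        core = rec["r_um"] < rtruth[k] - 100.0
        assert np.nanmean(rec["kymo_oxy"][core, k]) < 0.3


class TestPhantomIO:
    def test_tiff_round_trip(self, tmp_path):
        from oxydrop.synthetic import load_phantom, save_phantom

        r = np.linspace(2, 700, 50)
        cells = np.full((2, 50), 0.03)
        oxy = np.full((2, 50), 100.0)
        cfg = PhantomConfig(R_um=700.0, pixel_size_um=25.0, noise=0.02, seed=3)
        ph = phantom_droplet(r, cells, oxy, [0.0, 60.0], cfg)
        save_phantom(ph, tmp_path / "ph")
        back = load_phantom(tmp_path / "ph")
        # float32 TIFF storage bounds the round-trip error
        assert np.allclose(back["brightfield"], ph["brightfield"], atol=1e-6)
        assert np.allclose(back["fluorescence"], ph["fluorescence"], atol=1e-6)
        assert back["meta"]["seed"] == 3
        assert np.allclose(back["truth"]["c_oxy"], oxy)
        assert np.allclose(back["truth"]["times_s"], [0.0, 60.0])
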