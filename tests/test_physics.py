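"""Phantom construction, Compton/Klein-Nishina physics, and the
single-scatter forward model."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from scatterct.exceptions import InvalidArgumentError
from scatterct.mask import PatternMatrix
from scatterct.physics import (
    COMPTON_WAVELENGTH_PM,
    ELECTRON_RADIUS_M,
    BucketSeries,
    Phantom,
    ResponseMap,
    ScatterGeometry,
    bucket_signals,
    compton_wavelength,
    energy_to_wavelength_pm,
    klein_nishina,
    make_bone_phantom,
    mc_budget,
    read_buckets,
    read_phantom,
    rotate_volume_z,
    scatter_response_map,
    transmission_projection,
    write_buckets,
    write_phantom,
)


def _hole_run_length(slice2d):
    """Zero-valued run through the center of a phantom slice, in voxels."""
    row = slice2d[slice2d.shape[0] // 2]
    c = row.shape[0] // 2
    lo = c
    while lo > 0 and row[lo - 1] == 0:
        lo -= 1
    hi = c
    while hi < row.shape[0] - 1 and row[hi + 1] == 0:
        hi += 1
    return hi - lo + 1 if row[c] == 0 else 0


class TestBonePhantom:
    def test_hole_diameters_match_voxel_arithmetic(self):
        ph = make_bone_phantom((64, 64, 64), 0.25, 2000.0, 1200.0, 0.1, 1.0, 0)
        # 2000 um / 250 um = 8 voxels at the top; 1200/250 ~ 5 at the bottom
        assert _hole_run_length(ph.mu[0]) == pytest.approx(8, abs=1)
        assert _hole_run_length(ph.mu[-1]) == pytest.approx(5, abs=1)

    def test_zero_hole_gives_solid_interior(self):
        ph = make_bone_phantom((16, 16, 16), 0.5, 0.0, 0.0, 0.1, 1.0, 0,
                               texture=0.0)
        assert _hole_run_length(ph.mu[0]) == 0
        assert ph.mu[8, 8, 8] > 0

    def test_scatter_mass_decreases_with_hole_size(self):
        masses = []
        for top in (0.0, 1000.0, 2000.0, 3000.0):
            ph = make_bone_phantom((16, 16, 16), 0.25, top, top, 0.1, 1.0, 0)
            masses.append(ph.rho_e.sum() * ph.voxel_mm**3)
        assert all(a > b for a, b in zip(masses, masses[1:]))

    def test_background_is_zero(self):
        ph = make_bone_phantom((16, 16, 16), 0.25, 1000.0, 500.0)
        assert ph.mu[0, 0, 0] == 0 and ph.rho_e[0, 0, 0] == 0

    def test_hole_exceeding_phantom_invalid(self):
        with pytest.raises(InvalidArgumentError):
            make_bone_phantom((16, 16, 16), 0.25, 9000.0, 1200.0)

    def test_negative_fields_rejected(self):
        with pytest.raises(InvalidArgumentError):
            Phantom(mu=-np.ones((2, 2, 2)), rho_e=np.ones((2, 2, 2)),
                    voxel_mm=1.0)


class TestComptonWavelength:
    def test_forward_scatter_unshifted(self):
        assert compton_wavelength(20.0, 0.0) == pytest.approx(20.0)

    def test_ninety_degrees_adds_compton_wavelength(self):
        lam_c = 2.42631023538  # h/(m_e c) in pm, from CODATA constants
        assert compton_wavelength(20.0, 90.0) == pytest.approx(20.0 + lam_c,
                                                               rel=1e-9)

    def test_backscatter_adds_twice(self):
        out = compton_wavelength(20.0, 180.0)
        assert out == pytest.approx(20.0 + 2 * COMPTON_WAVELENGTH_PM, rel=1e-12)

    def test_positive_wavelength_required(self):
        with pytest.raises(InvalidArgumentError):
            compton_wavelength(0.0, 90.0)


class TestKleinNishina:
    def test_forward_value_is_re_squared(self):
        lam = energy_to_wavelength_pm(80.0)
        assert klein_nishina(lam, 0.0) == pytest.approx(ELECTRON_RADIUS_M**2,
                                                        rel=1e-12)

    @pytest.mark.parametrize("theta", [0.0, 30.0, 60.0, 90.0, 120.0, 180.0])
    def test_thomson_limit_at_long_wavelength(self, theta):
        thomson = 0.5 * ELECTRON_RADIUS_M**2 * (1 + np.cos(np.deg2rad(theta)) ** 2)
        assert klein_nishina(1e9, theta) == pytest.approx(thomson, rel=1e-6)

    def test_side_scatter_smaller_than_forward_cone(self):
        lam = energy_to_wavelength_pm(80.0)
        assert klein_nishina(lam, 90.0) < klein_nishina(lam, 30.0)

    def test_maximal_at_zero_and_symmetric(self):
        lam = energy_to_wavelength_pm(60.0)
        thetas = np.linspace(-180, 180, 73)
        vals = np.array([klein_nishina(lam, t) for t in thetas])
        assert vals.argmax() == len(thetas) // 2  # theta = 0
        assert np.allclose(vals, vals[::-1], rtol=1e-12)


class TestScatterResponseMap:
    def test_unattenuated_slab_is_uniform(self):
        # mu = 0, rho = 1 over t voxels -> response = t * voxel * KN everywhere
        t = 5
        mu = np.zeros((4, 8, 6))
        rho = np.zeros_like(mu)
        rho[:, 1 : 1 + t, :] = 1.0
        ph = Phantom(mu=mu, rho_e=rho, voxel_mm=0.5)
        geom = ScatterGeometry(photon_energy_keV=60.0, detector_angle_deg=90.0)
        resp = scatter_response_map(ph, geom)
        expected = t * 0.5 * klein_nishina(geom.wavelength_pm, 90.0)
        assert np.allclose(resp.values, expected, rtol=1e-12)

    def test_single_voxel_closed_form_and_ray_marcher(self):
        # one scattering voxel in a uniform absorber: closed-form Beer-Lambert
        # along measured path lengths, plus a 10x-finer-step marching oracle
        nz, ny, nx = 1, 9, 9
        mu_val = 0.3
        mu = np.full((nz, ny, nx), mu_val)
        rho = np.zeros_like(mu)
        k, j = 4, 6  # depth along beam, transverse position
        rho[0, k, j] = 2.0
        ph = Phantom(mu=mu, rho_e=rho, voxel_mm=0.5)
        geom = ScatterGeometry(photon_energy_keV=60.0, detector_angle_deg=90.0)
        resp = scatter_response_map(ph, geom)
        kn = klein_nishina(geom.wavelength_pm, 90.0)
        L_in = (k + 0.5) * 0.5
        L_out = (nx - 1 - j + 0.5) * 0.5
        closed = 2.0 * np.exp(-mu_val * L_in) * kn * np.exp(-mu_val * L_out) * 0.5
        assert resp.values[0, j] == pytest.approx(closed, rel=1e-10)
        # brute-force marcher: integrate mu at 10x finer steps along both paths
        step = 0.05
        path_in = sum(mu_val * step for _ in np.arange(0, L_in, step))
        path_out = sum(mu_val * step for _ in np.arange(0, L_out, step))
        marched = 2.0 * np.exp(-path_in) * kn * np.exp(-path_out) * 0.5
        assert resp.values[0, j] == pytest.approx(marched, rel=1e-6)

    def test_self_attenuation_monotonicity(self):
        ph = make_bone_phantom((8, 8, 8), 0.5, 1000.0, 500.0, 0.1, 1.0, 0)
        ph2 = Phantom(mu=2 * ph.mu, rho_e=ph.rho_e, voxel_mm=ph.voxel_mm)
        geom = ScatterGeometry()
        r1 = scatter_response_map(ph, geom).values
        r2 = scatter_response_map(ph2, geom).values
        assert np.all(r2 <= r1 + 1e-15)

    def test_rotation_full_turn_consistency(self):
        ph = make_bone_phantom((8, 8, 8), 0.5, 1000.0, 500.0)
        a = scatter_response_map(ph, ScatterGeometry(rotation_angle_deg=0.0))
        b = scatter_response_map(ph, ScatterGeometry(rotation_angle_deg=360.0))
        assert np.allclose(a.values, b.values, atol=1e-6)

    def test_empty_phantom_all_zero(self):
        ph = Phantom(mu=np.zeros((4, 4, 4)), rho_e=np.zeros((4, 4, 4)),
                     voxel_mm=1.0)
        assert np.all(scatter_response_map(ph, ScatterGeometry()).values == 0)

    def test_oblique_exit_attenuates_more_than_none(self):
        ph = make_bone_phantom((8, 8, 8), 0.5, 0.0, 0.0, 0.2, 1.0, 0)
        r45 = scatter_response_map(ph, ScatterGeometry(detector_angle_deg=45.0))
        ph0 = Phantom(mu=np.zeros_like(ph.mu), rho_e=ph.rho_e, voxel_mm=0.5)
        r45_free = scatter_response_map(ph0, ScatterGeometry(detector_angle_deg=45.0))
        assert np.all(r45.values <= r45_free.values + 1e-15)

    def test_voxel_refinement_converges(self):
        # same smooth physical object sampled at h and h/2: responses within
        # 2% (a sharp-edged object would add partial-volume error on top)
        def blob(n, voxel):
            yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
            r = np.hypot(yy - (n - 1) / 2, xx - (n - 1) / 2) * voxel
            dens = np.exp(-(r / 1.5) ** 2)
            mu = np.broadcast_to(0.05 * dens, (n, n, n)).copy()
            return Phantom(mu=mu, rho_e=mu / 0.05, voxel_mm=voxel)

        geom = ScatterGeometry(detector_angle_deg=90.0)
        coarse = scatter_response_map(blob(16, 0.5), geom).values
        fine = scatter_response_map(blob(32, 0.25), geom).values
        fine_avg = fine.reshape(16, 2, 16, 2).mean(axis=(1, 3))
        sel = coarse > 0.2 * coarse.max()
        rel = np.abs(fine_avg[sel] - coarse[sel]) / coarse[sel].max()
        assert rel.max() < 0.02


class TestTransmission:
    def test_vacuum_is_unity(self):
        ph = Phantom(mu=np.zeros((4, 4, 4)), rho_e=np.zeros((4, 4, 4)),
                     voxel_mm=1.0)
        assert np.allclose(transmission_projection(ph).values, 1.0)

    def test_uniform_slab_closed_form(self):
        mu = np.full((4, 6, 4), 0.2)
        ph = Phantom(mu=mu, rho_e=np.zeros_like(mu), voxel_mm=0.5)
        assert np.allclose(transmission_projection(ph).values,
                           np.exp(-0.2 * 6 * 0.5), rtol=1e-12)

    def test_hole_footprint_brighter_than_bone(self):
        ph = make_bone_phantom((32, 32, 32), 0.25, 2000.0, 2000.0, 0.1, 1.0, 0)
        t = transmission_projection(ph).values
        c = 16
        assert t[2, c] > t[2, c - 6]  # through the hole vs through solid bone


class TestBucketSignals:
    def test_identity_patterns_return_image(self):
        A = PatternMatrix(values=np.eye(9, dtype=int), pattern_shape=(3, 3),
                          pitch_um=1.0)
        x = np.arange(9, dtype=float).reshape(3, 3)
        S = bucket_signals(A, x)
        assert np.array_equal(S.values, x.ravel())

    def test_all_ones_row_sums_image(self):
        A = PatternMatrix(values=np.ones((1, 9), dtype=int), pattern_shape=(3, 3),
                          pitch_um=1.0)
        x = np.random.default_rng(0).random((3, 3))
        assert bucket_signals(A, x).values[0] == pytest.approx(x.sum())

    def test_matches_brute_force_dot_products(self):
        rng = np.random.default_rng(5)
        vals = (rng.random((12, 16)) < 0.5).astype(int)
        A = PatternMatrix(values=vals, pattern_shape=(4, 4), pitch_um=1.0)
        x = rng.random((4, 4))
        S = bucket_signals(A, x)
        for i in range(12):
            expected = sum(vals[i, j] * x.ravel()[j] for j in range(16))
            assert S.values[i] == pytest.approx(expected, rel=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        vals = (rng.random((20, 16)) < 0.5).astype(int)
        A = PatternMatrix(values=vals, pattern_shape=(4, 4), pitch_um=1.0)
        x1, x2 = rng.random((4, 4)), rng.random((4, 4))
        s12 = bucket_signals(A, x1 + x2).values
        s1 = bucket_signals(A, x1).values
        s2 = bucket_signals(A, x2).values
        assert np.allclose(s12, s1 + s2, rtol=1e-10)

    def test_poisson_seeded_and_nonnegative(self):
        rng = np.random.default_rng(3)
        vals = (rng.random((10, 16)) < 0.5).astype(int)
        A = PatternMatrix(values=vals, pattern_shape=(4, 4), pitch_um=1.0)
        x = rng.random((4, 4))
        a = bucket_signals(A, x, noise="poisson", scale=1e3, seed=9)
        b = bucket_signals(A, x, noise="poisson", scale=1e3, seed=9)
        assert np.array_equal(a.values, b.values)
        assert np.all(a.values >= 0)
        assert a.noise_model.startswith("poisson")

    def test_shape_mismatch(self):
        A = PatternMatrix(values=np.eye(9, dtype=int), pattern_shape=(3, 3),
                          pitch_um=1.0)
        with pytest.raises(InvalidArgumentError):
            bucket_signals(A, np.ones((4, 4)))

    @given(seed=st.integers(0, 1000))
    def test_normalization_divides_by_row_sums(self, seed):
        rng = np.random.default_rng(seed)
        vals = (rng.random((6, 9)) < 0.5).astype(int)
        vals[0] = 1  # ensure at least one nonzero row
        A = PatternMatrix(values=vals, pattern_shape=(3, 3), pitch_um=1.0)
        x = rng.random((3, 3))
        raw = bucket_signals(A, x).values
        norm = bucket_signals(A, x, normalize=True).values
        sums = vals.sum(axis=1)
        expect = np.divide(raw, sums, out=np.zeros_like(raw), where=sums > 0)
        assert np.allclose(norm, expect)


def test_mc_budget_bookkeeping():
    assert mc_budget(2000, 1e6) == 2e9


def test_phantom_io_round_trip(tmp_path):
    ph = make_bone_phantom((8, 8, 8), 0.5, 1000.0, 500.0, seed=4)
    p = tmp_path / "phantom.h5"
    write_phantom(ph, p)
    back = read_phantom(p)
    assert np.array_equal(back.mu, ph.mu)
    assert np.array_equal(back.rho_e, ph.rho_e)
    assert back.voxel_mm == ph.voxel_mm


def test_buckets_io_round_trip(tmp_path):
    s = BucketSeries(values=np.array([1.5, 2.25, 0.0]), angle_deg=45.0,
                     noise_model="none")
    p = tmp_path / "buckets.csv"
    write_buckets(s, p)
    back = read_buckets(p)
    assert np.array_equal(back.values, s.values)
    assert back.angle_deg == 45.0


def test_rotate_multiples_of_90_are_exact():
    vol = np.random.default_rng(0).random((3, 8, 8))
    r = rotate_volume_z(vol, 90.0)
    assert np.array_equal(rotate_volume_z(r, 270.0), rotate_volume_z(vol, 0.0))
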