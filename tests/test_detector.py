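import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgtkit import detector as det
from pgtkit.constants import CONSTANTS

LSO2 = det.RESOLUTION_PRESETS["LSO2"]
BGO1 = det.RESOLUTION_PRESETS["BGO1"]


class TestResolutionFits:
    def test_lso2_printed_round_numbers(self):
        assert round(det.energy_resolution(LSO2, 4.4)) == 7
        assert round(det.energy_resolution(LSO2, 0.511)) == 11

    def test_bgo1_at_high_energy(self):
        assert round(det.energy_resolution(BGO1, 4.4)) == 8

    def test_asymptotes(self):
        assert det.energy_resolution(LSO2, 1e9) == pytest.approx(5.6, abs=1e-3)
        assert det.time_resolution(LSO2, 1e9) == pytest.approx(80.0, abs=0.1)

    def test_time_resolution_direct_evaluation(self):
        assert det.time_resolution(LSO2, 4.0) == pytest.approx(460.0 / 2 + 80.0)
        assert det.time_resolution(BGO1, 4.0) == pytest.approx(4900.0 / 2 + 10.0)

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            det.ResolutionFit(-1.0, 5.0, 400.0, 80.0)


class TestFomBsr:
    def test_perfect_timing(self):
        assert det.fom_bsr(0.0, 0.0, 10.0) == 1.0

    def test_three_four_five(self):
        assert det.fom_bsr(3.0, 4.0, 10.0) == pytest.approx(0.5)

    def test_lso2_formula_value(self):
        # detector term from the printed fit at 4 MeV, 2 ns bunch, 106 MHz
        sigma_det = det.time_resolution(LSO2, 4.0) / 1000.0
        value = det.fom_bsr(sigma_det, 2.0, 1000.0 / 106.0)
        assert value == pytest.approx(1.0 - 2.0239 / 9.434, abs=5e-4)

    def test_clipped_at_zero(self):
        assert det.fom_bsr(50.0, 0.0, 10.0) == 0.0

    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0), st.floats(0.01, 5.0),
           st.floats(6.0, 20.0))
    @settings(max_examples=50, deadline=None)
    def test_monotonicity(self, s1, s2, ds, t):
        assert det.fom_bsr(s1 + ds, s2, t) <= det.fom_bsr(s1, s2, t)
        assert det.fom_bsr(s1, s2 + ds, t) <= det.fom_bsr(s1, s2, t)
        assert det.fom_bsr(s1, s2, t + 1.0) >= det.fom_bsr(s1, s2, t)


@pytest.fixture(scope="module")
def pb():
    return det.load_attenuation_table("pb")


@pytest.fixture(scope="module")
def csi():
    return det.load_attenuation_table("csi")


class TestAttenuation:
    def test_grid_point_is_exact_reciprocal(self, pb):
        e = pb.energies[5]
        mu = pb.mu_over_rho[5]
        assert det.mean_free_path(pb, e) == pytest.approx(1.0 / (mu * pb.rho), rel=1e-12)

    def test_lambda_grows_with_energy(self, pb):
        assert det.mean_free_path(pb, 4.0) > det.mean_free_path(pb, 0.14)

    def test_density_scaling(self, pb):
        halved = det.AttenuationTable("pb2", pb.energies, pb.mu_over_rho, pb.rho * 2)
        assert det.mean_free_path(halved, 1.0) == pytest.approx(
            det.mean_free_path(pb, 1.0) / 2)

    def test_zero_thickness(self, pb):
        assert det.attenuation_fraction(pb, 0.0, 0.14) == 0.0

    def test_pb_2mm_140kev(self, pb):
        assert det.attenuation_fraction(pb, 0.2, 0.14) >= 99.0

    def test_pb_2mm_4p4mev(self, pb):
        assert det.attenuation_fraction(pb, 0.2, 4.4) == pytest.approx(9.0, abs=2.0)

    def test_csi_1cm_table_oracle(self, csi):
        # hand computation from the same table rows it interpolates
        e = np.asarray(csi.energies)
        m = np.asarray(csi.mu_over_rho)
        mu = math.exp(np.interp(math.log(0.14), np.log(e), np.log(m))) * csi.rho
        expect = 100.0 * (1.0 - math.exp(-mu * 1.0))
        got = det.attenuation_fraction(csi, 1.0, 0.14)
        assert got == pytest.approx(expect, rel=1e-12)
        assert got == pytest.approx(98.0, abs=2.0)

    def test_csi_1cm_4p4mev(self, csi):
        assert det.attenuation_fraction(csi, 1.0, 4.4) == pytest.approx(15.0, abs=2.0)

    def test_stacked_slabs_additive(self, pb):
        a = det.attenuation_fraction(pb, 0.3, 1.0) / 100.0
        b = det.attenuation_fraction(pb, 0.5, 1.0) / 100.0
        ab = det.attenuation_fraction(pb, 0.8, 1.0) / 100.0
        assert 1.0 - ab == pytest.approx((1.0 - a) * (1.0 - b), rel=1e-12)

    def test_out_of_range_energy(self, pb):
        with pytest.raises(ValueError):
            det.mean_free_path(pb, 100.0)


class TestComptonKinematics:
    def test_forward_scattering_limit(self):
        cos_t, valid = det.compton_cos_theta(1e-9, 4.4)
        assert valid
        assert cos_t == pytest.approx(1.0, abs=1e-6)

    def test_ninety_degrees_at_4p4(self):
        # E' for theta = 90 deg: E/(1 + E/mec2)
        e_prime = det.compton_scattered_energy(4.4, math.pi / 2)
        cos_t, valid = det.compton_cos_theta(4.4 - e_prime, e_prime)
        assert valid
        assert cos_t == pytest.approx(0.0, abs=1e-12)
        assert e_prime == pytest.approx(0.4578, abs=5e-4)

    def test_backscatter_minimum_forbidden(self):
        e = 4.4
        e_min = e / (1.0 + 2.0 * e / CONSTANTS.m_e_c2)
        _, valid = det.compton_cos_theta(e - 0.9 * e_min, 0.9 * e_min)
        assert not valid
        _, valid = det.compton_cos_theta(e - 1.1 * e_min, 1.1 * e_min)
        assert valid

    def test_invalid_deposits(self):
        with pytest.raises(ValueError):
            det.compton_cos_theta(0.0, 1.0)

    @given(st.floats(0.05, math.pi - 0.05), st.floats(1.0, 8.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_theta(self, theta, e_gamma):
        e_prime = det.compton_scattered_energy(e_gamma, theta)
        cos_t, valid = det.compton_cos_theta(e_gamma - e_prime, e_prime)
        assert valid
        assert math.acos(np.clip(cos_t, -1, 1)) == pytest.approx(theta, abs=1e-12)


def _make_event(source, r_s, theta, e_gamma=4.4, dist=60.0, seed=0):
    """Forward-simulate one noiseless Compton event from a point source."""
    rng = np.random.default_rng(seed)
    u = (np.asarray(r_s) - np.asarray(source))
    u = u / np.linalg.norm(u)  # photon travel direction
    # orthonormal frame around u
    a = np.array([1.0, 0.0, 0.0])
    if abs(u @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    phi = rng.uniform(0, 2 * math.pi)
    w = math.cos(theta) * u + math.sin(theta) * (math.cos(phi) * e1 + math.sin(phi) * e2)
    r_a = np.asarray(r_s) + dist * w
    e_prime = det.compton_scattered_energy(e_gamma, theta)
    return det.ComptonEvent(tuple(r_s), tuple(r_a), e_gamma - e_prime, e_prime)


class TestCones:
    def test_axis_geometry(self):
        theta = math.pi / 6
        e_prime = det.compton_scattered_energy(4.4, theta)
        ev = det.ComptonEvent((0, 0, 0), (0, 0, -50.0), 4.4 - e_prime, e_prime)
        cone = det.cone_from_event(ev)
        assert np.allclose(cone.axis, (0, 0, 1))
        assert cone.half_angle == pytest.approx(theta, abs=1e-12)

    def test_degenerate_positions_rejected(self):
        with pytest.raises(ValueError):
            det.ComptonEvent((1, 2, 3), (1, 2, 3), 1.0, 1.0)

    def test_source_on_cone_surface(self):
        source = np.array([5.0, -3.0, -120.0])
        rng = np.random.default_rng(1)
        for i in range(20):
            r_s = np.array([rng.uniform(-20, 20), rng.uniform(-20, 20), 0.0])
            theta = rng.uniform(0.1, 1.2)
            ev = _make_event(source, r_s, theta, seed=i)
            cone = det.cone_from_event(ev)
            v = source - np.asarray(cone.vertex)
            ang = math.acos(np.clip(v @ np.asarray(cone.axis) / np.linalg.norm(v), -1, 1))
            assert ang == pytest.approx(cone.half_angle, abs=1e-9)


class TestBackprojection:
    def test_point_source_recovery_noiseless(self):
        source = np.array([0.0, 0.0, -100.0])
        rng = np.random.default_rng(2)
        cones = []
        for i in range(100):
            r_s = np.array([rng.uniform(-25, 25), rng.uniform(-25, 25), 0.0])
            theta = rng.uniform(0.15, 1.0)
            cones.append(det.cone_from_event(_make_event(source, r_s, theta, seed=100 + i)))
        axis = np.linspace(-40.0, 40.0, 41)
        pts = det.plane_grid(axis, axis, -100.0)
        img = det.backproject(cones, pts, angular_tolerance=0.02).reshape(41, 41)
        i, j = np.unravel_index(np.argmax(img), img.shape)
        assert axis[i] == pytest.approx(0.0, abs=2.0)
        assert axis[j] == pytest.approx(0.0, abs=2.0)

    def test_single_cone_ring(self):
        cone = det.cone_from_event(_make_event([0, 0, -100.0], [0, 0, 0.0], 0.5))
        axis = np.linspace(-60.0, 60.0, 61)
        pts = det.plane_grid(axis, axis, -100.0)
        img = det.backproject([cone], pts, angular_tolerance=0.03)
        assert set(np.unique(img)) <= {0.0, 1.0}
        assert img.sum() > 10  # a locus of grid points, not a single spot

    def test_smeared_recovery(self):
        source = np.array([0.0, 0.0, -100.0])
        rng = np.random.default_rng(3)
        cones = []
        for i in range(500):
            r_s = np.array([rng.uniform(-25, 25), rng.uniform(-25, 25), 0.0])
            theta = rng.uniform(0.15, 1.0)
            e_gamma = 4.4
            e_prime = det.compton_scattered_energy(e_gamma, theta)
            # smear deposits with the LSO2 energy resolution
            def smear(e):
                s = det.energy_resolution(LSO2, e) / 100.0 / 2.355 * e
                return max(e + rng.normal(0.0, s), 1e-3)
            ev = _make_event(source, r_s, theta, seed=500 + i)
            try:
                ev = det.ComptonEvent(ev.r_s, ev.r_a, smear(ev.L_s), smear(ev.L_a))
                cones.append(det.cone_from_event(ev))
            except ValueError:
                continue
        axis = np.linspace(-40.0, 40.0, 41)  # 2 mm voxels
        pts = det.plane_grid(axis, axis, -100.0)
        img = det.backproject(cones, pts, angular_tolerance=0.05).reshape(41, 41)
        i, j = np.unravel_index(np.argmax(img), img.shape)
        assert abs(axis[i]) <= 4.0 and abs(axis[j]) <= 4.0  # within 2 voxels

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            det.backproject([], np.zeros((5, 3)))
        cone = det.cone_from_event(_make_event([0, 0, -100.0], [0, 0, 0.0], 0.5))
        with pytest.raises(ValueError):
            det.backproject([cone], np.zeros((0, 3)))


class TestAngerLogic:
    def test_equal_shares_center(self):
        assert det.anger_position(1, 1, 1, 1) == (0.5, 0.5)

    def test_corners(self):
        assert det.anger_position(1, 0, 0, 0) == (0.0, 0.0)
        assert det.anger_position(0, 0, 0, 1) == (1.0, 1.0)
        assert det.anger_position(0, 1, 0, 0) == (1.0, 0.0)
        assert det.anger_position(0, 0, 1, 0) == (0.0, 1.0)

    def test_zero_light_rejected(self):
        with pytest.raises(ValueError):
            det.anger_position(0, 0, 0, 0)

    @given(st.tuples(*[st.floats(0.0, 10.0)] * 4))
    @settings(max_examples=50, deadline=None)
    def test_rotation_invariance(self, shares):
        p1, p2, p3, p4 = shares
        if p1 + p2 + p3 + p4 == 0:
            return
        x, y = det.anger_position(p1, p2, p3, p4)
        # 90 deg CCW rotation of the block: labels permute (2,4,1,3) and the
        # position maps (x, y) -> (y, 1-x)
        xr, yr = det.anger_position(p2, p4, p1, p3)
        assert xr == pytest.approx(y, abs=1e-12)
        assert yr == pytest.approx(1.0 - x, abs=1e-12)


class TestFloodMap:
    @staticmethod
    def _mean_spot_width(hist, n_pixels):
        """Average per-spot std of the X marginal, segment by segment."""
        marginal = hist.sum(axis=1)
        edges = np.linspace(0.0, 1.0, len(marginal) + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        widths = []
        for k in range(n_pixels):
            seg = (centers >= k / n_pixels) & (centers < (k + 1) / n_pixels)
            w = marginal[seg]
            if w.sum() == 0:
                continue
            c = centers[seg]
            m = np.sum(c * w) / w.sum()
            widths.append(math.sqrt(np.sum((c - m) ** 2 * w) / w.sum()))
        return float(np.mean(widths))

    def test_noiseless_delta_spots(self):
        hist = det.simulate_flood_map(4, 4.4, LSO2, 4000, seed=0, noise_scale=0.0)
        assert np.count_nonzero(hist) == 16

    def test_sharper_at_high_energy(self):
        w511 = self._mean_spot_width(det.simulate_flood_map(8, 0.511, LSO2, 60000, 1), 8)
        w4400 = self._mean_spot_width(det.simulate_flood_map(8, 4.4, LSO2, 60000, 1), 8)
        assert w4400 < w511

    def test_width_scaling_sqrt_energy(self):
        # pure-statistical fit (no intrinsic constant term)
        fit = det.ResolutionFit(3.8, 0.0, 460.0, 0.0)
        w1 = self._mean_spot_width(
            det.simulate_flood_map(8, 1.0, fit, 100000, 2, n_hist_bins=512), 8)
        w4 = self._mean_spot_width(
            det.simulate_flood_map(8, 4.0, fit, 100000, 2, n_hist_bins=512), 8)
        assert w1 / w4 == pytest.approx(2.0, rel=0.2)

    def test_min_pixels_guard(self):
        with pytest.raises(ValueError):
            det.simulate_flood_map(1, 4.4, LSO2, 100, 0)
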