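"""Forward-model unit and property tests: spectrum, heel, filtration, kerma."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kerma_rbf import physics
from kerma_rbf.grid import DetectorPoint
from kerma_rbf.physics import (
    AttenuationTable,
    BeamDirection,
    ConfigError,
    EnergyRangeError,
    EnergySpectrum,
    GeometryError,
    OutsideBeamError,
    TubeConfig,
    air_kerma_at_point,
    bremsstrahlung_spectrum,
    emitted_spectrum,
    filter_spectrum,
    heel_path_length,
    interpolate_mu,
)


# ---------------------------------------------------------------------------
# bremsstrahlung spectrum
# ---------------------------------------------------------------------------

class TestBremsstrahlung:
    def test_endpoint_fluence_is_zero(self):
        spec = bremsstrahlung_spectrum(TubeConfig(kvp=100))
        assert spec.fluence[spec.bin_centers >= 100].sum() == 0.0

    def test_kramers_ratio_between_bins(self):
        # fluence ~ Z(kVp-E)/E: (60/40)/(20/80) = 6 at E=40 vs 80 for 100 kVp
        spec = bremsstrahlung_spectrum(TubeConfig(kvp=100))
        f40 = spec.fluence[spec.bin_centers == 40.0][0]
        f80 = spec.fluence[spec.bin_centers == 80.0][0]
        assert f40 / f80 == pytest.approx(6.0)

    def test_no_fluence_at_or_above_kvp(self):
        spec = bremsstrahlung_spectrum(TubeConfig(kvp=40))
        assert np.all(spec.fluence[spec.bin_centers >= 40.0] == 0.0)
        assert np.all(spec.fluence[spec.bin_centers < 40.0] > 0.0)

    def test_bins_are_1_kev_from_10(self):
        spec = bremsstrahlung_spectrum(TubeConfig(kvp=60))
        assert spec.bin_centers[0] == 10.0
        assert spec.bin_centers[-1] == 60.0
        assert np.allclose(np.diff(spec.bin_centers), 1.0)

    def test_invalid_kvp_rejected(self):
        with pytest.raises(ConfigError):
            TubeConfig(kvp=10)
        with pytest.raises(ConfigError):
            TubeConfig(kvp=150)


# ---------------------------------------------------------------------------
# attenuation table interpolation
# ---------------------------------------------------------------------------

class TestInterpolateMu:
    def test_exact_at_knots(self, toy_table):
        for e, mu in zip(toy_table.energies, toy_table.mu_over_rho):
            assert interpolate_mu(toy_table, e) == pytest.approx(mu)

    def test_geometric_mean_at_geometric_midpoint(self, toy_table):
        e = np.sqrt(10.0 * 40.0)
        assert interpolate_mu(toy_table, e) == pytest.approx(np.sqrt(8.0 * 1.0))

    def test_against_hand_piecewise_computation(self, toy_table):
        # independent hand computation on the 40-160 segment at E = 80:
        # slope = ln(0.125/1)/ln(160/40) = -1.5, mu = 1 * (80/40)^-1.5
        assert interpolate_mu(toy_table, 80.0) == pytest.approx(2.0 ** -1.5)

    def test_value_between_bracketing_knots(self, toy_table):
        v = interpolate_mu(toy_table, 23.0)
        assert 1.0 < v < 8.0

    def test_out_of_range_raises(self, toy_table):
        with pytest.raises(EnergyRangeError):
            interpolate_mu(toy_table, 9.0)
        with pytest.raises(EnergyRangeError):
            interpolate_mu(toy_table, 161.0)

    def test_bundled_tables_span_and_kinds(self, tables):
        for name in ("tungsten", "beryllium", "air"):
            assert tables[name].e_min <= 10.0
            assert tables[name].e_max >= 150.0
        assert tables["air"].kind == "energy-absorption"
        assert tables["tungsten"].kind == "attenuation"


# ---------------------------------------------------------------------------
# heel geometry
# ---------------------------------------------------------------------------

class TestHeelPathLength:
    cfg = TubeConfig(kvp=80, production_depth_um=3.0, takeoff_floor_deg=0.0)

    def test_central_axis_closed_form(self):
        L = heel_path_length(BeamDirection(0.0, 0.0), self.cfg)
        assert L == pytest.approx(3.0 / np.sin(np.deg2rad(20.0)))
        assert L == pytest.approx(2.924 * 3.0, rel=1e-3)

    def test_half_takeoff_doubles_depth(self):
        # theta=10 away from the anode: takeoff 30 deg, L = 2 d
        L = heel_path_length(BeamDirection(10.0, 180.0), self.cfg)
        assert L == pytest.approx(6.0)

    def test_anode_side_longer_than_cathode_side(self):
        toward = heel_path_length(BeamDirection(10.0, 0.0), self.cfg)
        away = heel_path_length(BeamDirection(10.0, 180.0), self.cfg)
        assert toward > away

    def test_grazing_ray_raises_without_floor(self):
        with pytest.raises(GeometryError):
            heel_path_length(BeamDirection(20.0, 0.0), self.cfg)

    def test_floor_caps_grazing_path(self):
        cfg = TubeConfig(kvp=80, production_depth_um=3.0, takeoff_floor_deg=2.0)
        L = heel_path_length(BeamDirection(20.0, 0.0), cfg)
        assert L == pytest.approx(3.0 / np.sin(np.deg2rad(2.0)))

    @given(theta=st.floats(0.0, 18.0), phi=st.floats(0.0, 360.0))
    @settings(max_examples=50, deadline=None)
    def test_path_increases_as_takeoff_decreases(self, theta, phi):
        d = BeamDirection(theta, phi)
        alpha = physics.takeoff_angle_deg(d, self.cfg)
        L = heel_path_length(d, self.cfg)
        central = heel_path_length(BeamDirection(0.0, 0.0), self.cfg)
        if alpha < 20.0:
            assert L > central
        else:
            assert L <= central + 1e-12


# ---------------------------------------------------------------------------
# filtration
# ---------------------------------------------------------------------------

class TestFilterSpectrum:
    def test_zero_path_is_identity(self, toy_table):
        spec = bremsstrahlung_spectrum(TubeConfig(kvp=100))
        out = filter_spectrum(spec, toy_table, 1850.0, 0.0)
        assert np.array_equal(out.fluence, spec.fluence)

    def test_ln2_attenuation_halves_single_bin(self):
        table = AttenuationTable("x", [10.0, 100.0], [1.0, 1.0])
        spec = EnergySpectrum(np.array([50.0]), np.array([1.0]))
        # (mu/rho) rho path = 1 * 1 g/cm3 * ln2 cm
        out = filter_spectrum(spec, table, 1000.0, 10.0 * np.log(2.0))
        assert out.fluence[0] == pytest.approx(0.5)

    def test_doubled_path_squares_transmission(self, tables):
        spec = bremsstrahlung_spectrum(TubeConfig(kvp=80))
        once = filter_spectrum(spec, tables["beryllium"], 1850.0, 1.0)
        twice = filter_spectrum(spec, tables["beryllium"], 1850.0, 2.0)
        mask = spec.fluence > 0
        t1 = once.fluence[mask] / spec.fluence[mask]
        t2 = twice.fluence[mask] / spec.fluence[mask]
        np.testing.assert_allclose(t2, t1**2, rtol=1e-12)

    def test_negative_path_rejected(self, toy_table):
        spec = EnergySpectrum(np.array([50.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            filter_spectrum(spec, toy_table, 1850.0, -1.0)


# ---------------------------------------------------------------------------
# air kerma
# ---------------------------------------------------------------------------

class TestAirKerma:
    def test_inverse_square_exact(self, tables):
        cfg = TubeConfig(kvp=80)
        k1 = air_kerma_at_point(cfg, DetectorPoint(50.0, 10.0, 45.0), tables)
        k2 = air_kerma_at_point(cfg, DetectorPoint(100.0, 10.0, 45.0), tables)
        assert k2 == pytest.approx(k1 / 4.0, rel=1e-12)

    def test_monoenergetic_closed_form(self):
        # single 60 keV bin, unit fluence, r = 1: K = 60 * (mu_en/rho)(60)
        t = 0.0304
        air = AttenuationTable("air", [10.0, 60.0, 150.0], [4.7, t, 0.025],
                               kind="energy-absorption")
        spec = EnergySpectrum(np.array([60.0]), np.array([1.0]))
        k = physics.kerma_from_spectrum(spec, air, 1.0)
        assert k == pytest.approx(60.0 * t)

    def test_three_bin_hand_computed_oracle(self):
        """air_kerma on a toy 3-bin problem equals an explicit hand sum."""
        energies = np.array([10.0, 50.0, 150.0])
        w = AttenuationTable("tungsten", energies, [10.0, 2.0, 0.5])
        be = AttenuationTable("beryllium", energies, [0.6, 0.15, 0.12])
        air = AttenuationTable("air", energies, [4.7, 0.04, 0.025],
                               kind="energy-absorption")
        tables = {"tungsten": w, "beryllium": be, "air": air}
        cfg = TubeConfig(kvp=140, anode_angle_deg=20.0, window_thickness_mm=1.0,
                         production_depth_um=3.0, n_energy_bins=3,
                         takeoff_floor_deg=0.0)
        point = DetectorPoint(75.0, 10.0, 180.0)

        # --- independent hand computation --------------------------------
        bins = np.linspace(10.0, 140.0, 3)            # 10, 75, 140
        kramers = 74 * (140.0 - bins) / bins
        kramers[bins >= 140.0] = 0.0
        alpha = np.deg2rad(20.0 - 10.0 * np.cos(np.pi))   # 30 deg
        heel_cm = (3.0 / np.sin(alpha)) * 1e-4
        loglin = lambda tab, e: np.exp(np.interp(
            np.log(e), np.log(tab.energies), np.log(tab.mu_over_rho)))
        f = kramers * np.exp(-loglin(w, bins) * 19.29 * heel_cm)
        f = f * np.exp(-loglin(be, bins) * 1.85 * 0.1)
        expected = (f * bins * loglin(air, bins)).sum() / 75.0**2

        assert air_kerma_at_point(cfg, point, tables) == pytest.approx(
            expected, rel=1e-12)

    def test_heel_asymmetry_full_spectrum(self, tables):
        cfg = TubeConfig(kvp=60)
        toward = air_kerma_at_point(cfg, DetectorPoint(75.0, 10.0, 0.0), tables)
        away = air_kerma_at_point(cfg, DetectorPoint(75.0, 10.0, 180.0), tables)
        assert toward < away

    def test_voltage_monotonicity_at_fixed_point(self, tables):
        point = DetectorPoint(75.0, 10.0, 90.0)
        kermas = [air_kerma_at_point(TubeConfig(kvp=v), point, tables)
                  for v in (40, 60, 80, 100, 120, 140)]
        assert np.all(np.diff(kermas) > 0)

    def test_spectrum_hardening_on_anode_side(self, tables):
        cfg = TubeConfig(kvp=80)
        anode = emitted_spectrum(cfg, BeamDirection(10.0, 0.0), tables)
        cathode = emitted_spectrum(cfg, BeamDirection(10.0, 180.0), tables)
        assert anode.mean_energy() > cathode.mean_energy()

    def test_degenerate_and_outside_errors(self, tables):
        cfg = TubeConfig(kvp=80)
        with pytest.raises(ZeroDivisionError):
            air_kerma_at_point(cfg, DetectorPoint(0.0, 0.0, 0.0), tables)
        with pytest.raises(OutsideBeamError):
            air_kerma_at_point(cfg, DetectorPoint(75.0, 25.0, 0.0), tables)

    @given(
        theta=st.floats(0.0, 20.0),
        phi=st.floats(0.0, 360.0),
        kvp=st.floats(20.0, 140.0),
        r=st.floats(10.0, 500.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_inverse_square_and_mirror_symmetry(self, tables, theta, phi, kvp, r):
        cfg = TubeConfig(kvp=kvp)
        k = air_kerma_at_point(cfg, DetectorPoint(r, theta, phi), tables)
        k2 = air_kerma_at_point(cfg, DetectorPoint(2 * r, theta, phi), tables)
        mirror = air_kerma_at_point(
            cfg, DetectorPoint(r, theta, 360.0 - phi), tables)
        assert k > 0
        assert k2 == pytest.approx(k / 4.0, rel=1e-12)
        assert mirror == pytest.approx(k, rel=1e-9)
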