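import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fusedcae.optics import (DiffractionOrder, EmissionSpectrum,
                             MetasurfaceSpec, OpticalSystemSpec, PSFKernel,
                             build_psf, collection_efficiency,
                             critical_angle, diffraction_exit_sine,
                             escape_fraction, kernel_preset, order_table)


class TestEscapeCone:
    @pytest.mark.parametrize("n, expected", [
        (1.0, 90.0),
        (math.sqrt(2.0), 45.0),
        (1.82, math.degrees(math.asin(1.0 / 1.82))),  # ~33.33 deg
    ])
    def test_critical_angle(self, n, expected):
        assert critical_angle(n) == pytest.approx(expected, abs=1e-9)

    def test_escape_fraction_endpoints(self):
        assert escape_fraction(1.0) == pytest.approx(0.5, abs=1e-12)
        assert escape_fraction(1e3) < 1e-5

    def test_ce_yag_photon_loss_rounds_to_92_percent(self):
        lost = 1.0 - escape_fraction(1.82)
        assert round(100.0 * lost) == 92

    @given(st.floats(min_value=1.0001, max_value=5.0),
           st.floats(min_value=0.01, max_value=1.0))
    def test_escape_fraction_strictly_decreasing(self, n, dn):
        assert escape_fraction(n + dn) < escape_fraction(n)

    @pytest.mark.parametrize("func", [critical_angle, escape_fraction])
    def test_subunity_index_rejected(self, func):
        with pytest.raises(ValueError):
            func(0.9)


class TestGratingEquation:
    def test_normal_incidence_zero_order(self):
        assert diffraction_exit_sine(0.0, 550.0, 300.0, 0) == 0.0

    def test_zero_order_evanescent_beyond_critical(self):
        # at 40 deg incidence in Ce:YAG the refracted (m=0) ray is gone
        s = diffraction_exit_sine(40.0, 550.0, 300.0, 0, 1.82)
        assert abs(s) > 1.0

    def test_first_order_survives_at_70_deg(self):
        s = diffraction_exit_sine(70.0, 550.0, 300.0, 1, 1.82)
        assert s == pytest.approx(-0.1231, abs=5e-4)
        assert abs(s) < 1.0

    @given(st.floats(min_value=-89, max_value=89),
           st.floats(min_value=400, max_value=700),
           st.floats(min_value=100, max_value=1000))
    def test_zero_order_is_snell_independent_of_period(self, theta, lam,
                                                       xi):
        s = diffraction_exit_sine(theta, lam, xi, 0, 1.82)
        assert s == pytest.approx(1.82 * math.sin(math.radians(theta)),
                                  abs=1e-12)

    def test_invalid_period_rejected(self):
        with pytest.raises(ValueError):
            diffraction_exit_sine(10.0, 550.0, 0.0, 1)


class TestOrderTable:
    def test_bare_interface_admission_matches_snell_tir(self):
        # with a full-hemisphere aperture the admitted set is exactly
        # the sub-critical-angle rays of the plain interface
        sys_spec = OpticalSystemSpec(acceptance_half_angle_deg=90.0)
        meta = MetasurfaceSpec(geometry="none")
        spectrum = EmissionSpectrum([(550.0, 1.0)])
        thc = critical_angle(sys_spec.n_scint)
        table = order_table(meta, sys_spec, spectrum, range(0, 90))
        for rec in table:
            assert rec.m == 0
            assert rec.in_acceptance == (rec.incidence_deg < thc)

    def test_300nm_period_admits_only_first_order(self, plain_system,
                                                  visible_spectrum):
        meta = MetasurfaceSpec(period_nm=300.0)
        table = order_table(meta, plain_system, visible_spectrum,
                            range(40, 71))
        admitted = [r for r in table if r.in_acceptance]
        assert admitted
        assert {abs(r.m) for r in admitted} == {1}

    def test_200nm_period_admits_nothing_beyond_critical(self,
                                                         plain_system,
                                                         visible_spectrum):
        meta = MetasurfaceSpec(period_nm=200.0)
        thc = critical_angle(plain_system.n_scint)
        table = order_table(meta, plain_system, visible_spectrum,
                            range(0, 90))
        beyond = [r for r in table
                  if r.incidence_deg > thc and r.in_acceptance]
        assert beyond == []

    def test_order_invariants(self, plain_system, visible_spectrum):
        meta = MetasurfaceSpec(period_nm=400.0)
        for rec in order_table(meta, plain_system, visible_spectrum,
                               range(0, 90, 5)):
            assert rec.propagating == (abs(rec.exit_sine) < 1)
            if rec.in_acceptance:
                assert rec.propagating

    def test_empty_theta_grid_rejected(self, plain_system,
                                       visible_spectrum):
        with pytest.raises(ValueError):
            order_table(MetasurfaceSpec(), plain_system, visible_spectrum,
                        [])


class TestSpectrum:
    def test_weights_normalized(self):
        spec = EmissionSpectrum([(500.0, 2.0), (600.0, 6.0)])
        assert spec.weights.sum() == pytest.approx(1.0)
        assert spec.weights[1] == pytest.approx(0.75)

    def test_uniform_visible_support(self):
        spec = EmissionSpectrum.uniform_visible()
        assert spec.wavelengths_nm.min() == 400.0
        assert spec.wavelengths_nm.max() == 700.0

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            EmissionSpectrum([])


class TestBuildPsf:
    def test_identity_configuration_returns_system_kernel(self):
        sysk = PSFKernel.delta((5, 5), 0.5)
        sys_spec = OpticalSystemSpec(system_kernel=sysk)
        meta = MetasurfaceSpec(geometry="none")
        spectrum = EmissionSpectrum([(550.0, 1.0)])
        psf = build_psf(meta, sys_spec, spectrum,
                        theta_weighting="normal_incidence",
                        grid_shape=(11, 11))
        assert psf.grid[psf.center] == pytest.approx(1.0, abs=1e-12)

    def test_two_spike_oracle(self):
        # single wavelength at normal incidence through a 1D grating with
        # only the +/-1 orders: two equal spikes at the ray-traced offset
        lam, xi, L, pitch = 500.0, 1000.0, 5.0, 0.5
        meta = MetasurfaceSpec(period_nm=xi, geometry="grating_1d",
                               efficiency_model="user_table",
                               order_range=1,
                               efficiency_table={1: 1.0, -1: 1.0, 0: 0.0})
        sys_spec = OpticalSystemSpec(acceptance_half_angle_deg=90.0,
                                     propagation_distance_um=L)
        psf = build_psf(meta, sys_spec, EmissionSpectrum([(lam, 1.0)]),
                        theta_weighting="normal_incidence",
                        grid_shape=(15, 15), pixel_pitch_um=pitch)
        s = lam / xi
        d_px = L * math.tan(math.asin(s)) / pitch
        # closed-form bilinear splat of two half-weight deposits
        expected = np.zeros((15, 15))
        lo = int(math.floor(d_px))
        frac = d_px - lo
        expected[7, 7 + lo] += 0.5 * (1 - frac)
        expected[7, 7 + lo + 1] += 0.5 * frac
        expected[7, 7 - lo] += 0.5 * (1 - frac)
        expected[7, 7 - lo - 1] += 0.5 * frac
        np.testing.assert_allclose(psf.grid, expected, atol=1e-12)

    def test_normalization_and_mirror_symmetry(self, plain_system,
                                               visible_spectrum):
        psf = build_psf(MetasurfaceSpec(period_nm=300.0), plain_system,
                        visible_spectrum, grid_shape=(21, 21))
        assert psf.grid.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(psf.grid, psf.grid[:, ::-1], atol=1e-12)

    def test_undersized_grid_error_names_required_size(self,
                                                       visible_spectrum):
        sys_spec = OpticalSystemSpec(acceptance_half_angle_deg=90.0,
                                     propagation_distance_um=50.0)
        with pytest.raises(ValueError, match="need at least"):
            build_psf(MetasurfaceSpec(period_nm=300.0), sys_spec,
                      visible_spectrum, grid_shape=(5, 5))

    def test_collection_efficiency_ranks_presets(self):
        # the plain escape cone collects least; metasurfaces recover
        # trapped large-angle light
        ce = {name: kernel_preset(name).collection_efficiency
              for name in ("nsys", "k_xi2", "k_xi3", "k_xi5")}
        assert ce["k_xi2"] == pytest.approx(ce["nsys"], rel=1e-9)
        assert ce["k_xi3"] > 2 * ce["nsys"]
        assert ce["k_xi5"] > ce["nsys"]


class TestKernelIO:
    def test_tiff_roundtrip(self, tmp_path, texture_kernel):
        path = tmp_path / "k.tif"
        texture_kernel.save(path, {"note": "test"})
        back = PSFKernel.load(path)
        np.testing.assert_allclose(back.grid, texture_kernel.grid,
                                   atol=1e-7)
        assert back.pixel_pitch_um == texture_kernel.pixel_pitch_um
        assert back.center == texture_kernel.center
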