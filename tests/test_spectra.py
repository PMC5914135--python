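"""Spectral container, Gaussian-band synthesis and band descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from suprafit import (
    GaussianBand,
    SpeciesSpectralModel,
    Spectrum,
    anisotropy_factor,
    band_fwhm,
    band_shift,
    nm_to_wavenumber,
    peak_position,
    read_spectrum_csv,
    synthesize_spectrum,
    write_spectrum_csv,
)
from suprafit.spectra import DEFAULT_GRID


class TestWavenumberConversion:
    @pytest.mark.parametrize("nm, cm", [(1000.0, 10000.0), (656.0, 1e7 / 656.0)])
    def test_values(self, nm, cm):
        assert nm_to_wavenumber(nm) == pytest.approx(cm, rel=1e-12)

    @given(st.floats(min_value=1e-3, max_value=1e6))
    @settings(max_examples=50, derandomize=True)
    def test_involution(self, x):
        assert nm_to_wavenumber(nm_to_wavenumber(x)) == pytest.approx(x, rel=1e-14)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            nm_to_wavenumber(0.0)


class TestSpectrumInvariants:
    def test_rejects_decreasing_grid(self):
        with pytest.raises(ValueError, match="increasing"):
            Spectrum([500.0, 400.0], [1.0, 1.0])

    def test_rejects_negative_epsilon(self):
        with pytest.raises(ValueError):
            Spectrum([400.0, 500.0], [1.0, -0.5])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            Spectrum([400.0, 500.0], [1.0, 1.0], [0.1])

    def test_cd_channel_optional_and_signed(self):
        s = Spectrum([400.0, 500.0], [1.0, 1.0], [-0.2, 0.3])
        assert s.has_cd
        assert not Spectrum([400.0, 500.0], [1.0, 1.0]).has_cd


class TestSynthesis:
    def test_amplitude_at_center_and_half_max(self):
        band = GaussianBand(700.0, 2.5, 500.0)
        nu0 = nm_to_wavenumber(700.0)
        grid = np.array([nm_to_wavenumber(nu0 + 250.0), 700.0,
                         nm_to_wavenumber(nu0 - 250.0)])
        model = SpeciesSpectralModel("monomer", (band,))
        spec = synthesize_spectrum(model, np.sort(grid))
        vals = spec.epsilon[np.argsort(np.argsort(grid))]
        assert vals[1] == pytest.approx(2.5, rel=1e-12)
        # center +- FWHM/2 on the energy axis gives half the amplitude
        assert vals[0] == pytest.approx(1.25, rel=1e-12)
        assert vals[2] == pytest.approx(1.25, rel=1e-12)

    def test_empty_grid_rejected(self):
        model = SpeciesSpectralModel("monomer", (GaussianBand(656.0, 1.0, 450.0),))
        with pytest.raises(ValueError):
            synthesize_spectrum(model, [])

    def test_couplet_sign_structure_enforced(self):
        bands = (GaussianBand(738.0, 1.0, 850.0),)
        with pytest.raises(ValueError, match="couplet"):
            SpeciesSpectralModel("J1", bands,
                                 (GaussianBand(725.0, 1.0, 850.0),))


class TestAnisotropyFactor:
    def test_zero_cd_gives_zero(self):
        wl = np.linspace(700.0, 800.0, 51)
        s = Spectrum(wl, np.ones_like(wl), np.zeros_like(wl))
        assert anisotropy_factor(s, 745.0) == 0.0

    @given(st.floats(min_value=-0.1, max_value=0.1),
           st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=25, derandomize=True)
    def test_proportional_channels_and_scale_invariance(self, r, scale):
        wl = np.linspace(700.0, 800.0, 51)
        eps = 1.0 + 0.5 * np.sin(wl / 10.0) ** 2
        g1 = anisotropy_factor(Spectrum(wl, eps, r * eps), 733.0)
        g2 = anisotropy_factor(Spectrum(wl, scale * eps, scale * r * eps), 733.0)
        assert g1 == pytest.approx(r, rel=1e-12, abs=1e-15)
        assert g2 == pytest.approx(g1, rel=1e-12, abs=1e-15)

    def test_missing_cd_channel_errors(self):
        s = Spectrum([700.0, 800.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="CD"):
            anisotropy_factor(s, 750.0)

    def test_zero_epsilon_errors(self):
        wl = np.linspace(700.0, 800.0, 11)
        s = Spectrum(wl, np.zeros_like(wl), np.ones_like(wl))
        with pytest.raises(ZeroDivisionError):
            anisotropy_factor(s, 750.0)


class TestBandDescriptors:
    @pytest.mark.parametrize("fwhm", [450.0, 510.0, 850.0])
    def test_fwhm_recovered_within_one_percent(self, fwhm, fine_grid):
        model = SpeciesSpectralModel("monomer", (GaussianBand(700.0, 1.0, fwhm),))
        spec = synthesize_spectrum(model, fine_grid)
        assert band_fwhm(spec, (600.0, 800.0)) == pytest.approx(fwhm, rel=0.01)

    def test_fwhm_matches_gaussian_sigma_relation(self, fine_grid):
        # FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian in energy
        sigma_cm = 300.0
        fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma_cm
        model = SpeciesSpectralModel("monomer", (GaussianBand(700.0, 1.0, fwhm),))
        spec = synthesize_spectrum(model, fine_grid)
        assert band_fwhm(spec, (620.0, 790.0)) == pytest.approx(fwhm, rel=0.01)

    def test_truncated_band_errors_name_the_side(self, fine_grid):
        model = SpeciesSpectralModel("monomer", (GaussianBand(700.0, 1.0, 850.0),))
        spec = synthesize_spectrum(model, fine_grid)
        with pytest.raises(ValueError, match="side"):
            band_fwhm(spec, (690.0, 800.0))

    def test_peak_position_subgrid(self):
        # center off the 0.5 nm grid is still recovered by the parabolic fit
        model = SpeciesSpectralModel("monomer", (GaussianBand(700.27, 1.0, 500.0),))
        spec = synthesize_spectrum(model, DEFAULT_GRID)
        assert peak_position(spec, (650.0, 750.0)) == pytest.approx(700.27, abs=0.05)

    def test_monotone_window_errors(self, fine_grid):
        model = SpeciesSpectralModel("monomer", (GaussianBand(700.0, 1.0, 500.0),))
        spec = synthesize_spectrum(model, fine_grid)
        with pytest.raises(ValueError, match="monotone"):
            peak_position(spec, (710.0, 800.0))

    def test_band_shift_antisymmetric(self, presets):
        a = presets.spectrum("J1")
        b = presets.spectrum("J2")
        win = (690.0, 800.0)
        assert band_shift(a, b, win) == pytest.approx(-band_shift(b, a, win))
        assert band_shift(a, a, win) == pytest.approx(0.0, abs=1e-9)


class TestCsvRoundTrip:
    def test_round_trip_preserves_values(self, tmp_path, presets):
        spec = presets.spectrum("J2")
        path = tmp_path / "j2.csv"
        write_spectrum_csv(spec, path)
        back = read_spectrum_csv(path)
        np.testing.assert_allclose(back.wavelengths, spec.wavelengths)
        np.testing.assert_allclose(back.epsilon, spec.epsilon)
        np.testing.assert_allclose(back.delta_epsilon, spec.delta_epsilon)

    def test_cd_column_optional(self, tmp_path):
        path = tmp_path / "abs_only.csv"
        path.write_text("wavelength_nm,epsilon\n400,1.0\n500,2.0\n")
        assert not read_spectrum_csv(path).has_cd

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("wavelength_nm,intensity\n400,1.0\n")
        with pytest.raises(ValueError, match="epsilon"):
            read_spectrum_csv(path)

    def test_decreasing_grid_names_row(self, tmp_path):
        path = tmp_path / "bad_grid.csv"
        path.write_text("wavelength_nm,epsilon\n400,1.0\n500,1.0\n450,1.0\n")
        with pytest.raises(ValueError, match="row 3"):
            read_spectrum_csv(path)
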