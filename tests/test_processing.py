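"""Spectral processing: differential absorbance, baselines, band stats."""

import numpy as np
import pytest

from spphp.polariton import AnalyteLoad, ReststrahlenBand, coupled_reflectance_spectrum
from spphp.processing import (
    als_baseline,
    differential_absorbance,
    figure_of_merit,
    fwhm,
    integrate_band,
    joint_baseline_correct,
    normalized_frequency_shift,
)
from spphp.spectra import ABSORBANCE_MOD, DifferentialSpectrum, Spectrum, resample


def _refl(grid, values):
    return Spectrum(grid, values, "reflectance")


class TestDifferentialAbsorbance:
    def test_identity_gives_zero(self, grid):
        r = _refl(grid, np.full(grid.size, 0.8))
        d = differential_absorbance(r, r)
        assert np.allclose(d.absorbance, 0.0)

    def test_half_reflectance_is_301_mOD(self):
        w = np.array([1000.0, 1100.0, 1200.0])
        d = differential_absorbance(
            _refl(w, [0.5, 0.8, 0.8]), _refl(w, [1.0, 0.8, 0.8])
        )
        assert d.absorbance[0] == pytest.approx(1000 * np.log10(2), rel=1e-9)

    def test_antisymmetry(self, grid, rng):
        a = _refl(grid, rng.uniform(0.3, 0.9, grid.size))
        b = _refl(grid, rng.uniform(0.3, 0.9, grid.size))
        assert np.allclose(
            differential_absorbance(a, b).absorbance,
            -differential_absorbance(b, a).absorbance,
        )

    def test_grid_mismatch_rejected(self, grid):
        r = _refl(grid, np.full(grid.size, 0.8))
        r2 = _refl(grid + 1.0, np.full(grid.size, 0.8))
        with pytest.raises(ValueError, match="identical wavenumber grid"):
            differential_absorbance(r, r2)


class TestAlsBaseline:
    def test_constant_input_recovered(self):
        res = als_baseline(np.full(400, 3.7))
        assert res.converged
        assert np.allclose(res.baseline, 3.7, atol=1e-6)

    def test_line_plus_peak_recovery_within_2_percent(self):
        x = np.linspace(0, 1, 800)
        line = 2.0 + 3.0 * x
        peak = 50.0 * np.exp(-((x - 0.5) ** 2) / (2 * 0.01**2))
        res = als_baseline(line + peak)
        assert np.max(np.abs(res.baseline - line)) < 0.02 * 50.0

    def test_smaller_p_pushes_baseline_down(self):
        x = np.linspace(0, 1, 500)
        peak = 20 * np.exp(-((x - 0.3) ** 2) / 0.005)
        y = 1.0 + x + peak
        baselines = [als_baseline(y, p=p).baseline for p in (0.2, 0.05, 0.01)]
        # strict ordering under the peak and on average; tiny flank
        # crossings (< 2% of peak height) are a known ALS artefact
        tol = 0.02 * peak.max()
        i_peak = int(np.argmax(y))
        for hi, lo in zip(baselines, baselines[1:]):
            assert hi[i_peak] > lo[i_peak]
            assert hi.mean() > lo.mean()
            assert np.all(hi >= lo - tol)

    def test_shift_invariance_under_added_constant(self, rng):
        y = rng.standard_normal(300).cumsum()
        b0 = als_baseline(y).baseline
        b1 = als_baseline(y + 5.0).baseline
        assert np.allclose(b1, b0 + 5.0, atol=1e-8)

    def test_smoothness_energy_not_increased(self, rng):
        y = rng.standard_normal(500).cumsum() + 30 * np.exp(
            -((np.arange(500) - 250) ** 2) / 200.0
        )
        b = als_baseline(y).baseline
        d2 = lambda v: np.sum(np.diff(v, 2) ** 2)
        assert d2(b) <= d2(y)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            als_baseline(np.zeros(10), lam=-1.0)
        with pytest.raises(ValueError):
            als_baseline(np.zeros(10), p=1.5)


class TestIntegrateBand:
    BAND = ReststrahlenBand(1100.0, 1200.0)

    def test_zero_spectrum(self, grid):
        d = DifferentialSpectrum(grid, np.zeros(grid.size))
        assert integrate_band(d, self.BAND).delta_I == 0.0

    def test_rectangle_area(self, grid):
        h = grid[1] - grid[0]
        vals = np.where((grid >= 1120) & (grid <= 1180), 1.0, 0.0)
        d = DifferentialSpectrum(grid, vals)
        width = np.ptp(grid[(grid >= 1120) & (grid <= 1180)])
        assert integrate_band(d, self.BAND).delta_I == pytest.approx(width, abs=1.5 * h)

    def test_matches_refined_grid_quadrature(self):
        coarse = np.linspace(1000.0, 1300.0, 301)
        fine = np.linspace(1000.0, 1300.0, 3001)
        f = lambda w: np.exp(-((w - 1150.0) ** 2) / 2000.0) * (1 + 0.3 * np.sin(w / 40))
        i_coarse = integrate_band(DifferentialSpectrum(coarse, f(coarse)), self.BAND).delta_I
        i_fine = integrate_band(DifferentialSpectrum(fine, f(fine)), self.BAND).delta_I
        assert i_coarse == pytest.approx(i_fine, rel=1e-3)

    def test_linearity(self, grid, rng):
        d1 = rng.standard_normal(grid.size)
        d2 = rng.standard_normal(grid.size)
        a, b = 2.3, -1.7
        lhs = integrate_band(
            DifferentialSpectrum(grid, a * d1 + b * d2), self.BAND
        ).delta_I
        rhs = a * integrate_band(DifferentialSpectrum(grid, d1), self.BAND).delta_I
        rhs += b * integrate_band(DifferentialSpectrum(grid, d2), self.BAND).delta_I
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_band_outside_grid_rejected(self):
        w = np.linspace(1150, 1180, 50)
        with pytest.raises(ValueError, match="outside"):
            integrate_band(DifferentialSpectrum(w, np.zeros(50)), self.BAND)


class TestFwhm:
    def test_lorentzian_width_is_gamma(self):
        w = np.linspace(800, 1600, 4001)
        gamma = 40.0
        vals = (gamma / 2) ** 2 / ((w - 1200.0) ** 2 + (gamma / 2) ** 2)
        s = Spectrum(w, 1e-9 + vals, ABSORBANCE_MOD)
        assert fwhm(s, 1200.0) == pytest.approx(gamma, abs=0.5)

    def test_gaussian_width(self):
        w = np.linspace(1000, 1400, 4001)
        sig = 10.0
        s = Spectrum(w, 1e-9 + np.exp(-((w - 1200.0) ** 2) / (2 * sig**2)), ABSORBANCE_MOD)
        assert fwhm(s, 1200.0) == pytest.approx(2 * np.sqrt(2 * np.log(2)) * sig, abs=0.2)

    def test_amplitude_scale_invariance(self):
        w = np.linspace(1000, 1400, 2001)
        vals = 1e-9 + (20.0) ** 2 / ((w - 1200.0) ** 2 + 20.0**2)
        a = fwhm(Spectrum(w, vals, ABSORBANCE_MOD), 1200.0)
        b = fwhm(Spectrum(w, 7.5 * vals, ABSORBANCE_MOD), 1200.0)
        assert a == pytest.approx(b, rel=1e-9)

    def test_works_for_reflectance_dips(self):
        w = np.linspace(1000, 1400, 2001)
        vals = 1.0 - 0.5 * (30.0 / 2) ** 2 / ((w - 1200.0) ** 2 + (30.0 / 2) ** 2)
        assert fwhm(Spectrum(w, vals, "reflectance"), 1200.0) == pytest.approx(30.0, abs=0.5)

    def test_uncrossed_half_level_raises(self):
        # peak hugging the right edge: the right half-crossing is lost
        w = np.linspace(1000, 1210, 500)
        vals = 1e-9 + np.exp(-((w - 1205.0) ** 2) / (2 * 20.0**2))
        with pytest.raises(ValueError, match="half level"):
            fwhm(Spectrum(w, vals, ABSORBANCE_MOD), 1205.0)


def test_figure_of_merit():
    assert figure_of_merit(400.0, 200.0) == pytest.approx(2.0)
    assert figure_of_merit(400.0, 400.0) == pytest.approx(1.0)
    assert figure_of_merit(0.0, 123.0) == 0.0
    with pytest.raises(ValueError):
        figure_of_merit(400.0, 0.0)


def test_normalized_frequency_shift():
    assert normalized_frequency_shift(1160.0, 1160.0, 1160.0) == 0.0
    assert normalized_frequency_shift(1210.0, 1160.0, 1160.0) == pytest.approx(
        50.0 / 1160.0, rel=1e-9
    )
    assert normalized_frequency_shift(1100.0, 1160.0, 1160.0) < 0


class TestJointBaseline:
    def _measurement(self, system, grid, shift_sensitivity, dn, extra=None):
        """Reflectance of the coupled device at dn, with an optional
        molecular absorbance (mOD) imprinted on it."""
        r = coupled_reflectance_spectrum(system, AnalyteLoad(dn), grid, shift_sensitivity)
        vals = r.values
        if extra is not None:
            vals = vals * 10 ** (-extra / 1000.0)
        return Spectrum(grid, vals, "reflectance")

    def test_analyte_free_spectrum_needs_no_correction(
        self, system, grid, shift_sensitivity, transition
    ):
        ref = self._measurement(system, grid, shift_sensitivity, 0.0)
        corrected, res = joint_baseline_correct(ref.copy(), ref, transition)
        assert res.delta_f == pytest.approx(0.0, abs=shift_sensitivity * 2e-3)
        assert np.max(np.abs(corrected.absorbance)) < 0.5  # mOD

    @pytest.mark.parametrize("dn", [0.05, 0.2, 0.35])
    def test_injected_index_shift_recovered_within_10_percent(
        self, system, grid, shift_sensitivity, transition, dn
    ):
        ref = self._measurement(system, grid, shift_sensitivity, 0.0)
        meas = self._measurement(system, grid, shift_sensitivity, dn)
        _, res = joint_baseline_correct(meas, ref, transition)
        injected = -shift_sensitivity * dn
        assert res.delta_f == pytest.approx(injected, rel=0.10)

    def test_molecular_band_area_more_stable_than_plain_als(
        self, system, grid, shift_sensitivity, transition
    ):
        # a molecular band outside the Reststrahlen band, on a dn=0.2
        # device: the model-informed step removes the platform response,
        # so the residual smoothing is far less smoothness-sensitive
        # than fitting the raw differential with plain ALS
        from spphp.processing import differential_absorbance

        mol = 30.0 * (10.0) ** 2 / ((grid - 1652.0) ** 2 + 10.0**2)
        ref = self._measurement(system, grid, shift_sensitivity, 0.0)
        meas = self._measurement(system, grid, shift_sensitivity, 0.2, extra=mol)
        mask = np.abs(grid - 1652.0) < 60.0
        joint_areas, plain_areas = [], []
        d = differential_absorbance(meas, ref)
        for lam in (1e6, 1e7, 1e8):
            corrected, _ = joint_baseline_correct(meas, ref, transition, lam=lam)
            joint_areas.append(np.trapezoid(corrected.absorbance[mask], grid[mask]))
            plain = d.absorbance - als_baseline(d.absorbance, lam=lam).baseline
            plain_areas.append(np.trapezoid(plain[mask], grid[mask]))
        spread = lambda a: (max(a) - min(a)) / abs(np.mean(a))
        assert spread(joint_areas) < 0.3
        assert spread(plain_areas) > 3.0 * spread(joint_areas)

    def test_out_of_range_intensity_is_clamped(
        self, system, grid, shift_sensitivity, transition
    ):
        ref = self._measurement(system, grid, shift_sensitivity, 0.0)
        # an index load beyond the calibrated span: best match clamps
        # to the edge of the transition curve and is flagged
        meas = self._measurement(system, grid, shift_sensitivity, 0.5)
        _, res = joint_baseline_correct(meas, ref, transition)
        assert res.clamped


def test_resample_round_trip(grid):
    s = Spectrum(grid, 0.5 + 0.3 * np.sin(grid / 50.0), "reflectance")
    coarse = resample(s, grid[::2])
    assert np.allclose(coarse.values, s.values[::2])
    with pytest.raises(ValueError, match="beyond"):
        resample(s, np.linspace(grid[0] - 10, grid[-1], 100))
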