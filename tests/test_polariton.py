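"""Physics core: permittivity, dispersion, hybridization, dI curve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spphp.polariton import (
    DEFAULT_DPI_GRID,
    DEFAULT_G_GRID,
    DEFAULT_SIO2,
    AnalyteLoad,
    CoupledSystem,
    DielectricModel,
    LorentzOscillator,
    PolaritonMode,
    SurfaceResonanceError,
    bare_plasmon_reflectance,
    characteristic_matrix,
    coupled_reflectance_spectrum,
    dressed_frequencies_closed_form,
    dressed_frequencies_radiating,
    g_from_kappa,
    kappa_from_g,
    lorentz_permittivity,
    plasmon_shift_from_index,
    reststrahlen_band,
    sensitivity_map,
    sphp_signal,
    spp_wavevector,
)

OSC = LorentzOscillator(strength=5e5, center=1075.0, damping=5.0)


class TestPermittivity:
    def test_no_oscillators_returns_eps_inf(self):
        m = DielectricModel(2.1)
        assert lorentz_permittivity(m, 1234.5) == pytest.approx(2.1 + 0j)

    def test_static_limit_single_oscillator(self):
        m = DielectricModel(2.1, (OSC,))
        expected = 2.1 + 5e5 / 1075.0**2
        assert lorentz_permittivity(m, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_high_frequency_limit(self):
        m = DielectricModel(2.1, (OSC,))
        assert lorentz_permittivity(m, 1e6) == pytest.approx(2.1, abs=1e-6)

    def test_imag_part_nonnegative_for_passive_medium(self):
        m = DielectricModel(2.1, (OSC,))
        w = np.linspace(1.0, 3000.0, 500)
        assert np.all(lorentz_permittivity(m, w).imag >= 0)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            lorentz_permittivity(DielectricModel(2.1), -1.0)


class TestReststrahlen:
    def test_zero_damping_closed_form_edges(self):
        # gamma -> 0: Re eps < 0 exactly on (w0, sqrt(w0^2 + S/eps_inf))
        eps_inf, w0, S = 2.1, 1072.0, 9e5
        m = DielectricModel(eps_inf, (LorentzOscillator(S, w0, 1e-4),))
        b = reststrahlen_band(m)
        assert b.omega_to == pytest.approx(w0, abs=0.01)
        assert b.omega_lo == pytest.approx(np.sqrt(w0**2 + S / eps_inf), abs=0.01)

    def test_weak_oscillator_has_no_band(self):
        m = DielectricModel(2.1, (LorentzOscillator(10.0, 1100.0, 5.0),))
        with pytest.raises(ValueError, match="no negative-permittivity band"):
            reststrahlen_band(m)

    def test_default_oxide_band_location(self):
        b = reststrahlen_band(DEFAULT_SIO2)
        assert b.omega_to == pytest.approx(1072.0, abs=2.0)
        assert b.omega_lo == pytest.approx(1256.0, abs=2.0)


class TestSppWavevector:
    @pytest.mark.parametrize(
        "eps1, eps2, expected",
        [(-2 + 0j, 1 + 0j, np.sqrt(2)), (1 + 0j, 1 + 0j, np.sqrt(0.5))],
    )
    def test_direct_evaluation(self, eps1, eps2, expected):
        assert spp_wavevector(1.0, eps1, eps2) == pytest.approx(expected, rel=1e-12)

    def test_perfect_conductor_limit(self):
        k = spp_wavevector(1.0, -1e9 + 0j, 2.25 + 0j)
        assert k == pytest.approx(1.5, abs=1e-3)

    def test_pole_raises(self):
        with pytest.raises(SurfaceResonanceError):
            spp_wavevector(1.0, -2.0 + 0j, 2.0 + 0j)

    def test_branch_has_nonnegative_imag(self, rng):
        for _ in range(50):
            e1 = complex(rng.uniform(-10, 10), rng.uniform(0, 3))
            e2 = complex(rng.uniform(1, 5), rng.uniform(0, 1))
            if abs(e1 + e2) < 1e-3:
                continue
            assert spp_wavevector(1.0, e1, e2).imag >= 0


def _sys(wl, gl, ws, gs, g=None, kappa=None):
    return CoupledSystem(PolaritonMode(wl, gl), PolaritonMode(ws, gs), g=g, kappa=kappa)


class TestDressedClosedForm:
    def test_zero_detuning_splitting_is_2g(self):
        dm = dressed_frequencies_closed_form(_sys(1160, 0, 1160, 0, g=50))
        assert dm.plus == pytest.approx(1210 + 0j)
        assert dm.minus == pytest.approx(1110 + 0j)

    def test_uncoupled_limit_returns_bare_modes(self):
        dm = dressed_frequencies_closed_form(_sys(1200, 0, 1100, 0, g=0))
        assert dm.plus == pytest.approx(1200 + 0j)
        assert dm.minus == pytest.approx(1100 + 0j)

    def test_detuned_lossless_closed_form(self):
        dm = dressed_frequencies_closed_form(_sys(1200, 0, 1100, 0, g=50))
        assert dm.plus.real == pytest.approx(1150 + 0.5 * np.sqrt(20000), rel=1e-12)
        assert dm.minus.real == pytest.approx(1150 - 0.5 * np.sqrt(20000), rel=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(
        wl=st.floats(500, 2000),
        ws=st.floats(500, 2000),
        gl=st.floats(0, 400),
        gs=st.floats(0, 100),
        g=st.floats(0, 200),
    )
    def test_eigen_sum_rule(self, wl, ws, gl, gs, g):
        dm = dressed_frequencies_closed_form(_sys(wl, gl, ws, gs, g=g))
        total = dm.plus + dm.minus
        expected = (wl + ws) - 1j * (gl + gs) / 2
        assert abs(total - expected) <= 1e-9 * abs(expected)

    def test_minimum_splitting_over_detuning_sweep_equals_2g(self):
        g = 37.5
        splittings = [
            dressed_frequencies_closed_form(_sys(wl, 0, 1160, 0, g=g)).splitting
            for wl in np.linspace(1060, 1260, 2001)
        ]
        assert min(splittings) == pytest.approx(2 * g, rel=1e-6)


class TestDressedRadiating:
    def test_uncoupled_roots_are_damped_bare_modes(self):
        sys = _sys(1200, 80, 1100, 20, kappa=0.0)
        dm = dressed_frequencies_radiating(sys)
        # each diagonal factor gives w = sqrt(w0^2 - g^2/4) - i g/2
        for mode, root in ((sys.lspp, dm.plus), (sys.sphp, dm.minus)):
            expected = np.sqrt(mode.omega**2 - mode.gamma**2 / 4) - 1j * mode.gamma / 2
            assert root == pytest.approx(expected, rel=1e-9)

    def test_lossless_roots_match_closed_form_within_splitting(self):
        # weak coupling: the closed form is the rotating-wave limit of
        # the radiating model, so positions agree to 1% of the splitting
        g = 40.0
        ws = 1160.0
        sys = _sys(1160, 0, ws, 0, kappa=kappa_from_g(g, ws))
        rad = dressed_frequencies_radiating(sys)
        cf = dressed_frequencies_closed_form(sys.with_g(g))
        split = cf.splitting
        assert abs(rad.plus.real - cf.plus.real) < 0.01 * split
        assert abs(rad.minus.real - cf.minus.real) < 0.01 * split
        # the calibrated splitting itself is exact at any g
        sys60 = _sys(1160, 0, ws, 0, kappa=kappa_from_g(60.0, ws))
        assert dressed_frequencies_radiating(sys60).splitting == pytest.approx(
            120.0, rel=1e-9
        )

    def test_determinant_residual_vanishes_at_roots(self, rng):
        for _ in range(100):
            sys = _sys(
                rng.uniform(900, 1500),
                rng.uniform(0, 300),
                rng.uniform(1000, 1300),
                rng.uniform(0, 60),
                kappa=rng.uniform(0, 2e5),
            )
            dm = dressed_frequencies_radiating(sys)
            for root in (dm.plus, dm.minus):
                h = characteristic_matrix(sys, root)
                assert abs(np.linalg.det(h)) < 1e-8 * np.linalg.norm(h)

    def test_roots_match_independent_polynomial_solver(self, rng):
        sympy = pytest.importorskip("sympy")
        x = sympy.symbols("x")
        for _ in range(15):
            wl = rng.uniform(900, 1500)
            ws = rng.uniform(1000, 1300)
            gl = rng.uniform(0, 300)
            gs = rng.uniform(0, 60)
            kap = rng.uniform(0, 2e5)
            sys = _sys(wl, gl, ws, gs, kappa=kap)
            poly = (wl**2 - x**2 - sympy.I * gl * x) * (
                ws**2 - x**2 - sympy.I * gs * x
            ) - kap**2
            ref = sorted(
                (complex(r) for r in sympy.nroots(sympy.expand(poly), n=20)),
                key=lambda z: -z.real,
            )[:2]
            dm = dressed_frequencies_radiating(sys)
            assert dm.plus == pytest.approx(ref[0], abs=1e-6)
            assert dm.minus == pytest.approx(ref[1], abs=1e-6)


class TestCouplingConversion:
    def test_round_trip(self):
        for g in (10.0, 45.0, 120.0):
            assert g_from_kappa(kappa_from_g(g, 1160.0), 1160.0) == pytest.approx(g, rel=1e-12)

    def test_calibrated_kappa_reproduces_2g_splitting(self):
        g = 45.0
        sys = _sys(1160, 0, 1160, 0, kappa=kappa_from_g(g, 1160.0))
        dm = dressed_frequencies_radiating(sys)
        assert dm.splitting == pytest.approx(2 * g, rel=1e-9)


class TestIndexShift:
    def test_linear_redshift(self):
        assert plasmon_shift_from_index(AnalyteLoad(0.0), 400.0) == 0.0
        assert plasmon_shift_from_index(AnalyteLoad(0.2), 400.0) == pytest.approx(-80.0)
        one = plasmon_shift_from_index(AnalyteLoad(0.1), 400.0)
        two = plasmon_shift_from_index(AnalyteLoad(0.2), 400.0)
        assert two == pytest.approx(2 * one)


class TestReflectanceSurrogate:
    def test_uncoupled_spectrum_has_single_dip_at_plasmon(self, grid):
        sys = _sys(1160, 190, 1160, 8, g=0.0)
        s = coupled_reflectance_spectrum(sys, AnalyteLoad(0.0), grid, 300.0)
        v = s.values
        interior_minima = np.flatnonzero(
            (v[1:-1] < v[:-2]) & (v[1:-1] < v[2:])
        )
        assert interior_minima.size == 1
        assert s.wavenumbers[interior_minima[0] + 1] == pytest.approx(1160.0, abs=1.0)

    def test_reflectance_bounded_for_random_parameters(self, grid, rng):
        for _ in range(200):
            sys = _sys(
                rng.uniform(900, 1600),
                rng.uniform(1, 400),
                rng.uniform(1000, 1300),
                rng.uniform(1, 80),
                g=rng.uniform(0, 150),
            )
            s = coupled_reflectance_spectrum(
                sys, AnalyteLoad(rng.uniform(0, 0.4)), grid, 300.0
            )
            assert np.all(s.values > 0) and np.all(s.values <= 1)

    def test_index_change_is_band_localized(self, system, grid, band):
        s0 = coupled_reflectance_spectrum(system, AnalyteLoad(0.0), grid, 300.0)
        s1 = coupled_reflectance_spectrum(system, AnalyteLoad(0.4), grid, 300.0)
        diff = np.abs(s1.values - s0.values)
        inside = (grid >= band.omega_to) & (grid <= band.omega_lo)
        per_point_in = np.trapezoid(diff[inside], grid[inside]) / band.width
        per_point_out = np.trapezoid(diff[~inside], grid[~inside]) / (
            (grid[-1] - grid[0]) - band.width
        )
        assert per_point_in > per_point_out

    def test_sphp_signal_vanishes_without_coupling(self, grid):
        sys = _sys(1145, 190, 1160, 8, g=0.0)
        sig = sphp_signal(sys, AnalyteLoad(0.2), grid, 300.0)
        assert np.allclose(sig, 0.0, atol=1e-12)


class TestTransitionCurve:
    def test_starts_at_zero_and_increases(self, transition):
        assert transition.delta_I[0] == 0.0
        assert transition.monotone
        assert np.all(np.diff(transition.delta_I) > 0)

    def test_fit_first_order_optimality(self, transition):
        # residuals orthogonal to the fitted-model gradient at the optimum
        dn, di = transition.dn, transition.delta_I
        resid = di - transition.model(dn)
        e = np.exp(-dn / transition.c)
        grads = [np.ones_like(dn), -e, -transition.B * dn * e / transition.c**2]
        scale = np.linalg.norm(resid) * max(np.linalg.norm(g) for g in grads)
        for g in grads:
            assert abs(resid @ g) <= 1e-6 * max(scale, 1.0)

    def test_inversion_round_trip_and_clamping(self, transition):
        di = transition.model(0.2)
        dn, clamped = transition.invert(di)
        assert not clamped
        assert dn == pytest.approx(0.2, rel=1e-9)
        dn_hi, clamped_hi = transition.invert(transition.A * 1.01)
        assert clamped_hi and dn_hi == pytest.approx(0.4)


@pytest.fixture(scope="module")
def sens(system, band, grid):
    return sensitivity_map(system, DEFAULT_G_GRID, DEFAULT_DPI_GRID, band, grid)


class TestSensitivityMap:
    def test_finite_everywhere(self, sens):
        assert np.all(np.isfinite(sens))

    def test_uncoupled_column_is_zero(self, sens):
        assert np.allclose(sens[0], 0.0)

    def test_maximum_in_weak_coupling_regime(self, sens):
        i, _ = np.unravel_index(np.argmax(np.abs(sens)), sens.shape)
        assert DEFAULT_G_GRID[i] < np.median(DEFAULT_G_GRID)
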