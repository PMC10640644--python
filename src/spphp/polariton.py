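"""Coupled plasmon--phonon-polariton physics.

This module is the physics core of the package: Lorentz-oscillator
permittivity, the Reststrahlen band, the surface-polariton dispersion
relation, hybridized (dressed) modes of a coupled LSPP--SPhP system in
both the closed-form and the radiating-oscillator formulation, a
spectral surrogate for the device reflectance, the refractive-index
transition curve of the Reststrahlen band-integral statistic dI, and
the coupling-strength/frequency-shift sensitivity map.

Conventions
-----------
* Wavenumbers everywhere, cm^-1; oscillator strengths cm^-2.
* Time convention exp(-i w t): damping enters the Lorentz denominator
  as -j*w*gamma, so Im eps >= 0 for a passive medium at w > 0, and
  decaying hybrid modes carry Im(w) <= 0.
* A refractive-index load dn redshifts the plasmonic resonance
  linearly, dw = -s*dn, with s the refractometric sensitivity in
  cm^-1 per refractive index unit (RIU).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit

from .spectra import REFLECTANCE, Spectrum

__all__ = [
    "LorentzOscillator",
    "DielectricModel",
    "PolaritonMode",
    "CoupledSystem",
    "DressedModes",
    "ReststrahlenBand",
    "AnalyteLoad",
    "SurfaceResonanceError",
    "lorentz_permittivity",
    "reststrahlen_band",
    "spp_wavevector",
    "dressed_frequencies_closed_form",
    "dressed_frequencies_radiating",
    "characteristic_matrix",
    "kappa_from_g",
    "g_from_kappa",
    "plasmon_shift_from_index",
    "coupled_reflectance_spectrum",
    "bare_plasmon_reflectance",
    "sphp_signal",
    "delta_I_transition_curve",
    "TransitionCurve",
    "sensitivity_map",
    "DEFAULT_SIO2",
    "DEFAULT_SYSTEM",
    "NANOROD_MODE",
    "DEFAULT_G_GRID",
    "DEFAULT_DPI_GRID",
    "DEFAULT_SHIFT_SENSITIVITY",
    "DEFAULT_DIP_DEPTH",
    "default_grid",
]


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class LorentzOscillator:
    """One Lorentz oscillator: strength S (cm^-2), center w0 (cm^-1),
    damping gamma (cm^-1)."""

    strength: float
    center: float
    damping: float

    def __post_init__(self):
        if not (self.strength > 0 and self.center > 0 and self.damping > 0):
            raise ValueError("oscillator strength, center and damping must be > 0")


@dataclass(frozen=True)
class DielectricModel:
    """High-frequency constant plus a collection of Lorentz oscillators."""

    eps_inf: float
    oscillators: tuple[LorentzOscillator, ...] = ()

    def __post_init__(self):
        if self.eps_inf < 1:
            raise ValueError("eps_inf must be >= 1")
        object.__setattr__(self, "oscillators", tuple(self.oscillators))


@dataclass(frozen=True)
class PolaritonMode:
    """A bare polariton mode: resonance w (cm^-1) and damping gamma (cm^-1)."""

    omega: float
    gamma: float

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("mode frequency must be > 0")
        if self.gamma < 0:
            raise ValueError("mode damping must be >= 0")


@dataclass(frozen=True)
class CoupledSystem:
    """Bare LSPP and SPhP modes coupled with splitting g (cm^-1).

    Either ``g`` (closed-form coupling frequency splitting) or ``kappa``
    (radiating-oscillator coupling strength, cm^-2) may be given; the
    other is derived via the documented zero-detuning calibration
    (:func:`kappa_from_g` / :func:`g_from_kappa`).
    """

    lspp: PolaritonMode
    sphp: PolaritonMode
    g: float | None = None
    kappa: float | None = None

    def __post_init__(self):
        if self.g is None and self.kappa is None:
            raise ValueError("one of g or kappa must be set")
        if self.g is not None and self.g < 0:
            raise ValueError("g must be >= 0")
        if self.kappa is not None and self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    @property
    def g_value(self) -> float:
        if self.g is not None:
            return self.g
        return g_from_kappa(self.kappa, self.sphp.omega)

    @property
    def kappa_value(self) -> float:
        if self.kappa is not None:
            return self.kappa
        return kappa_from_g(self.g, self.sphp.omega)

    def with_lspp_omega(self, omega: float) -> "CoupledSystem":
        return replace(self, lspp=replace(self.lspp, omega=omega))

    def with_g(self, g: float) -> "CoupledSystem":
        return replace(self, g=g, kappa=None)


@dataclass(frozen=True)
class DressedModes:
    """Complex hybrid eigenfrequencies; Re(plus) >= Re(minus); a negative
    imaginary part is decay."""

    plus: complex
    minus: complex

    def __post_init__(self):
        if self.plus.real < self.minus.real:
            raise ValueError("dressed modes must be ordered by real part")

    @property
    def splitting(self) -> float:
        return self.plus.real - self.minus.real


@dataclass(frozen=True)
class ReststrahlenBand:
    """Interval (w_TO, w_LO) of negative real permittivity."""

    omega_to: float
    omega_lo: float

    def __post_init__(self):
        if not (0 < self.omega_to < self.omega_lo):
            raise ValueError("need 0 < omega_TO < omega_LO")

    @property
    def width(self) -> float:
        return self.omega_lo - self.omega_to


@dataclass(frozen=True)
class AnalyteLoad:
    """Refractive index change dn (RIU) of the sensing volume; optional
    effective layer thickness in nm (descriptive only)."""

    dn: float
    thickness_nm: float | None = None

    def __post_init__(self):
        if self.dn < 0:
            raise ValueError("dn must be >= 0 in the sensing regime")
        if self.thickness_nm is not None and self.thickness_nm < 0:
            raise ValueError("thickness must be >= 0")


class SurfaceResonanceError(ZeroDivisionError):
    """Raised at the surface-resonance pole eps1 = -eps2."""


# --------------------------------------------------------------------------
# permittivity and dispersion


def lorentz_permittivity(model: DielectricModel, omega):
    """Complex permittivity eps(w) = eps_inf + sum_i S_i/(w0i^2 - w^2 - j*w*g_i).

    ``omega`` may be a scalar or array of non-negative wavenumbers (cm^-1).
    With the exp(-iwt) convention the imaginary part is >= 0 for w > 0.
    """
    w = np.asarray(omega, dtype=float)
    if np.any(w < 0):
        raise ValueError("omega must be >= 0")
    eps = np.full(w.shape, model.eps_inf, dtype=complex)
    for osc in model.oscillators:
        eps = eps + osc.strength / (osc.center**2 - w**2 - 1j * w * osc.damping)
    if np.isscalar(omega):
        return complex(eps)
    return eps


def reststrahlen_band(
    model: DielectricModel,
    omega_max: float | None = None,
    n_scan: int = 20001,
) -> ReststrahlenBand:
    """Locate the contiguous interval where Re eps(w) < 0.

    A sign-change scan on a fine grid brackets the two crossings, which
    are then refined by bisection. Raises ``ValueError`` when the model
    never reaches negative real permittivity.
    """
    if not model.oscillators:
        raise ValueError("no negative-permittivity band: model has no oscillators")
    if omega_max is None:
        omega_max = 2.0 * max(o.center for o in model.oscillators)
    grid = np.linspace(1e-6, omega_max, n_scan)
    re = lorentz_permittivity(model, grid).real
    neg = np.flatnonzero(re < 0)
    if neg.size == 0:
        raise ValueError("no negative-permittivity band: Re eps never crosses zero")

    f = lambda w: lorentz_permittivity(model, float(w)).real
    i0, i1 = neg[0], neg[-1]
    lo = brentq(f, grid[i0 - 1], grid[i0]) if i0 > 0 else grid[0]
    hi = brentq(f, grid[i1], grid[i1 + 1]) if i1 + 1 < grid.size else grid[-1]
    return ReststrahlenBand(lo, hi)


def spp_wavevector(omega: float, eps1: complex, eps2: complex) -> complex:
    """Surface-polariton wavevector k = (w/c) sqrt(eps1*eps2/(eps1+eps2)).

    ``omega`` is given in reduced units of w/c (pass the wavenumber to get
    k in cm^-1 up to the 2*pi convention). The principal branch with
    Im(k) >= 0 (decaying surface wave) is returned. The surface-resonance
    pole eps1 = -eps2 raises :class:`SurfaceResonanceError`.
    """
    eps1 = complex(eps1)
    eps2 = complex(eps2)
    denom = eps1 + eps2
    scale = max(abs(eps1), abs(eps2), 1.0)
    if abs(denom) < 1e-12 * scale:
        raise SurfaceResonanceError("surface-resonance singularity: eps1 = -eps2")
    k = omega * np.sqrt(eps1 * eps2 / denom)
    if k.imag < 0:
        k = -k
    return complex(k)


# --------------------------------------------------------------------------
# dressed modes


def dressed_frequencies_closed_form(sys: CoupledSystem) -> DressedModes:
    """Closed-form dressed frequencies of the coupled two-mode system:

    w_pm = (wL+wS)/2 - i(gL+gS)/4
           +/- 1/2 sqrt(4g^2 + [(wL-wS) - i(gL-gS)/2]^2)
    """
    wl, gl = sys.lspp.omega, sys.lspp.gamma
    ws, gs = sys.sphp.omega, sys.sphp.gamma
    g = sys.g_value
    mean = (wl + ws) / 2 - 1j * (gl + gs) / 4
    root = 0.5 * np.sqrt(4 * g**2 + ((wl - ws) - 1j * (gl - gs) / 2) ** 2 + 0j)
    a, b = mean + root, mean - root
    if a.real < b.real:
        a, b = b, a
    return DressedModes(complex(a), complex(b))


def characteristic_matrix(sys: CoupledSystem, omega: complex) -> np.ndarray:
    """The 2x2 radiating-oscillator matrix H(w) whose singularity defines
    the hybrid modes; diagonal damping enters as i*gamma*w/(w_mode + w)."""
    wl, gl = sys.lspp.omega, sys.lspp.gamma
    ws, gs = sys.sphp.omega, sys.sphp.gamma
    k = sys.kappa_value
    return np.array(
        [
            [wl - omega - 1j * gl * omega / (wl + omega), k / (wl + omega)],
            [k / (ws + omega), ws - omega - 1j * gs * omega / (ws + omega)],
        ],
        dtype=complex,
    )


def _radiating_polynomial(sys: CoupledSystem) -> np.ndarray:
    """Coefficients (highest first) of the cleared-denominator
    characteristic polynomial

        (wL^2 - w^2 - i gL w)(wS^2 - w^2 - i gS w) - kappa^2 = 0.
    """
    wl, gl = sys.lspp.omega, sys.lspp.gamma
    ws, gs = sys.sphp.omega, sys.sphp.gamma
    k = sys.kappa_value
    A, B = wl**2, ws**2
    return np.array(
        [
            1.0,
            1j * (gl + gs),
            -(A + B + gl * gs),
            -1j * (gl * B + gs * A),
            A * B - k**2,
        ],
        dtype=complex,
    )


def dressed_frequencies_radiating(sys: CoupledSystem) -> DressedModes:
    """Hybrid modes from the radiating-oscillator characteristic equation
    |H - wI| = 0, solved via companion-matrix eigenvalues of the
    cleared-denominator quartic.

    The two physically relevant roots (positive real part) are returned;
    the quartic's root set is symmetric under w -> -conj(w), so exactly
    two such roots exist for positive bare frequencies.
    """
    roots = np.roots(_radiating_polynomial(sys))
    phys = sorted((r for r in roots if r.real > 0), key=lambda r: -r.real)
    if len(phys) != 2:
        raise ArithmeticError(
            f"root finder found {len(phys)} physical roots, expected 2"
        )
    return DressedModes(complex(phys[0]), complex(phys[1]))


def kappa_from_g(g: float, omega_ref: float) -> float:
    """Radiating coupling kappa (cm^-2) whose zero-detuning splitting at
    bare frequency ``omega_ref`` equals 2g: kappa = 2g*sqrt(omega_ref^2 - g^2).

    Derivation: at zero detuning and zero damping the quartic factorizes
    into w^2 = w0^2 +/- kappa, and requiring
    sqrt(w0^2+kappa) - sqrt(w0^2-kappa) = 2g gives the closed form.
    """
    if not 0 <= g < omega_ref:
        raise ValueError("need 0 <= g < omega_ref")
    return 2.0 * g * float(np.sqrt(omega_ref**2 - g**2))


def g_from_kappa(kappa: float, omega_ref: float) -> float:
    """Inverse of :func:`kappa_from_g` (smaller branch, g < omega_ref/sqrt(2))."""
    if not 0 <= kappa <= omega_ref**2:
        raise ValueError("need 0 <= kappa <= omega_ref^2")
    return float(np.sqrt((omega_ref**2 - np.sqrt(omega_ref**4 - kappa**2)) / 2.0))


# --------------------------------------------------------------------------
# refractive-index response surrogate


def plasmon_shift_from_index(load: AnalyteLoad, sensitivity: float) -> float:
    """Linear refractometric redshift dw = -s*dn (cm^-1, negative)."""
    if sensitivity <= 0:
        raise ValueError("sensitivity must be > 0")
    return -sensitivity * load.dn


def _hybrid_modes_and_weights(sys: CoupledSystem):
    """Eigenvalues and plasmon fractions of the damped 2x2 mode matrix.

    The LSPP is the bright (radiating) oscillator; each hybrid mode
    couples to the far field in proportion to its plasmon fraction
    |<LSPP|mode>|^2, so a pure phonon mode (g=0) is dark.
    """
    wl, gl = sys.lspp.omega, sys.lspp.gamma
    ws, gs = sys.sphp.omega, sys.sphp.gamma
    g = sys.g_value
    m = np.array(
        [[wl - 1j * gl / 2, g], [g, ws - 1j * gs / 2]], dtype=complex
    )
    vals, vecs = np.linalg.eig(m)
    fracs = np.abs(vecs[0, :]) ** 2 / np.sum(np.abs(vecs) ** 2, axis=0)
    return vals, fracs


def _dip(grid, center, width, depth):
    hw = max(width, 1e-9) / 2.0
    return depth * hw**2 / ((grid - center) ** 2 + hw**2)


DEFAULT_DIP_DEPTH = 0.7


def bare_plasmon_reflectance(
    mode: PolaritonMode,
    load: AnalyteLoad,
    grid,
    sensitivity: float,
    depth: float = DEFAULT_DIP_DEPTH,
) -> Spectrum:
    """Reflectance of an uncoupled plasmonic antenna: a single
    Lorentzian dip at the dn-shifted resonance."""
    grid = np.asarray(grid, dtype=float)
    wl = mode.omega + plasmon_shift_from_index(load, sensitivity)
    r = 1.0 - _dip(grid, wl, mode.gamma, depth)
    return Spectrum(grid, r, REFLECTANCE, {"model": "bare_plasmon", "dn": load.dn})


def coupled_reflectance_spectrum(
    sys: CoupledSystem,
    load: AnalyteLoad,
    grid,
    sensitivity: float,
    depth: float = DEFAULT_DIP_DEPTH,
) -> Spectrum:
    """Surrogate reflectance of the coupled system under an index load.

    The LSPP frequency is redshifted by -s*dn, the hybrid modes of the
    shifted system are computed, and the spectrum is a product of
    Lorentzian dips located at Re(w_pm) with widths -2 Im(w_pm) and
    depths weighted by each mode's plasmon fraction. The multiplicative
    composition keeps the reflectance inside (0, 1] for any overlap.
    """
    grid = np.asarray(grid, dtype=float)
    shifted = sys.with_lspp_omega(
        sys.lspp.omega + plasmon_shift_from_index(load, sensitivity)
    )
    vals, fracs = _hybrid_modes_and_weights(shifted)
    r = np.ones_like(grid)
    meta = {"model": "coupled", "dn": load.dn, "modes": [complex(v) for v in vals]}
    for v, f in zip(vals, fracs):
        width = max(-2.0 * v.imag, 1e-9)
        r = r * (1.0 - _dip(grid, v.real, width, depth * f))
        if not (grid[0] <= v.real <= grid[-1]):
            meta["warning"] = "grid does not cover both dressed modes"
    return Spectrum(grid, r, REFLECTANCE, meta)


def sphp_signal(
    sys: CoupledSystem,
    load: AnalyteLoad,
    grid,
    sensitivity: float,
    depth: float = DEFAULT_DIP_DEPTH,
) -> np.ndarray:
    """Baseline-removed SPhP vibration signal, in mOD.

    Defined as the absorbance of the coupled spectrum relative to the
    bare-plasmon spectrum at the same load: the broad plasmon dip is the
    physical baseline, and what hybridization adds inside the
    Reststrahlen band is the SPhP vibrational signature. Identically
    zero when g = 0.
    """
    rc = coupled_reflectance_spectrum(sys, load, grid, sensitivity, depth)
    rb = bare_plasmon_reflectance(sys.lspp, load, grid, sensitivity, depth)
    return -1000.0 * np.log10(rc.values / rb.values)


# --------------------------------------------------------------------------
# dI--dn transition curve


@dataclass
class TransitionCurve:
    """The dI(dn) transition curve with its saturating-exponential fit
    dI = A - B*exp(-dn/c) and everything needed to invert it.

    ``delta_I`` is the band integral of the baseline-removed SPhP
    signal change (the statistic the exponential is fitted to);
    ``full_delta_I`` is the band integral of the raw coupled
    differential absorbance and ``band_profiles`` the raw in-band
    differential spectra themselves -- the calibrated response family
    an instrument actually measures before any baseline model is
    applied. The joint baseline correction matches a measurement
    against this family (:meth:`match_dn`); the scalar band integral
    alone is not invertible because the in-band SPhP gain and the
    broad dip moving out of the band compete.
    """

    dn: np.ndarray
    delta_I: np.ndarray
    full_delta_I: np.ndarray
    band_profiles: np.ndarray
    band_mask: np.ndarray
    A: float
    B: float
    c: float
    r_squared: float
    sys: CoupledSystem
    band: ReststrahlenBand
    grid: np.ndarray
    sensitivity: float
    monotone: bool

    def model(self, dn) -> np.ndarray:
        return self.A - self.B * np.exp(-np.asarray(dn, dtype=float) / self.c)

    def invert(self, delta_I: float) -> tuple[float, bool]:
        """Map a measured SPhP-signal dI back to dn via the exponential
        fit; returns (dn, clamped?).

        Values outside the invertible range (A - B, A) are clamped to
        the fitted dn span and flagged.
        """
        lo, hi = float(self.dn[0]), float(self.dn[-1])
        arg = (self.A - delta_I) / self.B
        if arg <= 0:
            return hi, True
        dn = -self.c * float(np.log(arg))
        if dn < lo:
            return lo, True
        if dn > hi:
            return hi, True
        return dn, False

    def match_dn(self, d_band: np.ndarray) -> tuple[float, bool]:
        """Estimate dn for a measured in-band differential spectrum by
        least-squares matching against the calibrated response family;
        returns (dn, clamped?) where ``clamped`` flags a best match at
        the edge of the calibrated span."""
        d_band = np.asarray(d_band, dtype=float)
        if d_band.shape != self.band_profiles.shape[1:]:
            raise ValueError("in-band spectrum length does not match calibration")
        resid = np.sum((self.band_profiles - d_band) ** 2, axis=1)
        i = int(np.argmin(resid))
        if i == 0 or i == resid.size - 1:
            return float(self.dn[i]), bool(i == resid.size - 1)
        # parabolic refinement between grid neighbours
        r0, r1, r2 = resid[i - 1], resid[i], resid[i + 1]
        denom = r0 - 2 * r1 + r2
        shift = 0.5 * (r0 - r2) / denom if denom > 0 else 0.0
        h = self.dn[i + 1] - self.dn[i]
        return float(self.dn[i] + np.clip(shift, -1, 1) * h), False


def _band_integral(grid, values, band: ReststrahlenBand) -> float:
    mask = (grid >= band.omega_to) & (grid <= band.omega_lo)
    return float(np.trapezoid(values[mask], grid[mask]))


def delta_I_transition_curve(
    sys: CoupledSystem,
    dn_grid,
    band: ReststrahlenBand,
    grid,
    sensitivity: float,
    depth: float = DEFAULT_DIP_DEPTH,
) -> TransitionCurve:
    """Compute dI(dn) and fit the saturating exponential A - B*exp(-dn/c).

    dI(dn) is the signed Reststrahlen band integral of the differential
    SPhP signal D(w) = A(w; dn) - A(w; 0) between load dn and the
    unloaded reference. With the surrogate's conventions the integral
    is positive and grows monotonically as the plasmon redshifts away
    from the phonon line; dI(0) = 0 by construction.
    """
    dn_grid = np.asarray(dn_grid, dtype=float)
    if dn_grid.size < 20:
        raise ValueError("dn grid needs >= 20 points for a stable fit")
    grid = np.asarray(grid, dtype=float)
    ref = sphp_signal(sys, AnalyteLoad(float(dn_grid[0])), grid, sensitivity, depth)
    r_ref = coupled_reflectance_spectrum(
        sys, AnalyteLoad(float(dn_grid[0])), grid, sensitivity, depth
    ).values
    mask = (grid >= band.omega_to) & (grid <= band.omega_lo)
    di = np.empty(dn_grid.size)
    di_full = np.empty(dn_grid.size)
    profiles = np.empty((dn_grid.size, int(mask.sum())))
    for i, dn in enumerate(dn_grid):
        sig = sphp_signal(sys, AnalyteLoad(float(dn)), grid, sensitivity, depth)
        di[i] = _band_integral(grid, sig - ref, band)
        r_dn = coupled_reflectance_spectrum(
            sys, AnalyteLoad(float(dn)), grid, sensitivity, depth
        ).values
        full = -1000.0 * np.log10(r_dn / r_ref)
        di_full[i] = _band_integral(grid, full, band)
        profiles[i] = full[mask]

    monotone = bool(np.all(np.diff(di) >= -1e-9 * max(1.0, np.max(np.abs(di)))))

    scale = max(np.max(np.abs(di)), 1.0)
    span = max(dn_grid[-1] - dn_grid[0], 1e-6)

    def f(x, a, b, c):
        return a - b * np.exp(-x / c)

    p0 = (di[-1], di[-1] - di[0], span / 3.0)
    popt, _ = curve_fit(
        f, dn_grid, di, p0=p0, maxfev=20000,
        bounds=([-10 * scale, -10 * scale, 1e-4 * span], [10 * scale, 10 * scale, 100 * span]),
    )
    resid = di - f(dn_grid, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((di - di.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return TransitionCurve(
        dn=dn_grid,
        delta_I=di,
        full_delta_I=di_full,
        band_profiles=profiles,
        band_mask=mask,
        A=float(popt[0]),
        B=float(popt[1]),
        c=float(popt[2]),
        r_squared=r2,
        sys=sys,
        band=band,
        grid=grid,
        sensitivity=sensitivity,
        monotone=monotone,
    )


# --------------------------------------------------------------------------
# sensitivity map


def sensitivity_map(
    sys: CoupledSystem,
    g_grid,
    dpi_grid,
    band: ReststrahlenBand,
    grid,
    depth: float = DEFAULT_DIP_DEPTH,
) -> np.ndarray:
    """2-D relative-sensitivity map over coupling strength and
    normalized frequency shift.

    For each coupling strength g the plasmon is detuned by the
    normalized shift dpi = (w - w0)/w0 of its bare frequency and the
    band-integrated differential SPhP signal dI(dpi) is computed.
    Because the absolute feature strength itself grows with g, dI is
    normalized by the band-integrated magnitude of the unshifted SPhP
    signal at that g before taking the finite-difference derivative
    along dpi — the map therefore measures the fractional modulation of
    the SPhP band response per unit normalized shift. The g = 0 column
    is identically zero (no hybridization, no band response), and the
    maximum sits in the weak-coupling regime: strongly coupled systems
    are robust against detuning and respond less, fractionally, to a
    given shift. Returned shape: (len(g_grid), len(dpi_grid)).
    """
    g_grid = np.asarray(g_grid, dtype=float)
    dpi_grid = np.asarray(dpi_grid, dtype=float)
    if g_grid.size < 10 or dpi_grid.size < 10:
        raise ValueError("both grids need >= 10 points")
    grid = np.asarray(grid, dtype=float)
    w0 = sys.lspp.omega
    out = np.zeros((g_grid.size, dpi_grid.size))
    for i, g in enumerate(g_grid):
        if g == 0.0:
            continue
        sg = sys.with_g(float(g))
        ref = sphp_signal(sg, AnalyteLoad(0.0), grid, sensitivity=1.0, depth=depth)
        norm = _band_integral(grid, np.abs(ref), band)
        di = np.empty(dpi_grid.size)
        for j, dpi in enumerate(dpi_grid):
            shifted = sg.with_lspp_omega(w0 * (1.0 + dpi))
            sig = sphp_signal(shifted, AnalyteLoad(0.0), grid, sensitivity=1.0, depth=depth)
            di[j] = _band_integral(grid, sig - ref, band)
        out[i] = np.gradient(di / norm, dpi_grid)
    return out


#: Default grids for the sensitivity map: coupling strengths spanning
#: weak to strong coupling, and modest normalized redshifts.
DEFAULT_G_GRID = np.linspace(0.0, 150.0, 16)
DEFAULT_DPI_GRID = np.linspace(-0.05, 0.0, 21)


# --------------------------------------------------------------------------
# defaults

#: Device-oxide dielectric function: one dominant asymmetric-stretch
#: oscillator giving a Reststrahlen band of roughly 1072--1256 cm^-1.
#: These are configuration defaults, not measured claims.
DEFAULT_SIO2 = DielectricModel(
    eps_inf=2.1,
    oscillators=(
        LorentzOscillator(
            strength=2.1 * (1256.0**2 - 1072.0**2),  # pins the gamma->0 LO edge
            center=1072.0,
            damping=15.0,
        ),
    ),
)

#: Default coupled system: narrow SPhP line mid-band, broad plasmonic
#: antenna parked slightly below it (the sensitivity map puts the
#: optimal operating point at a small negative detuning), coupling
#: splitting g = 45 cm^-1 (normalized coupling g/w_SPhP ~ 0.039).
DEFAULT_SYSTEM = CoupledSystem(
    lspp=PolaritonMode(omega=1145.0, gamma=190.0),
    sphp=PolaritonMode(omega=1160.0, gamma=8.0),
    g=45.0,
)

#: The reference conventional antenna: a plain broad nanorod resonance
#: with no phonon coupling, used by the nanorod platform branch of the
#: synthetic generator. Broad and shallow, as common SEIRA rods are:
#: its refractometric figure of merit is correspondingly low.
NANOROD_MODE = PolaritonMode(omega=1300.0, gamma=900.0)
NANOROD_DIP_DEPTH = 0.25

#: Refractometric sensitivity of the plasmonic resonance, cm^-1 per RIU.
DEFAULT_SHIFT_SENSITIVITY = 300.0


def default_grid(n: int = 1714, lo: float = 900.0, hi: float = 1730.0) -> np.ndarray:
    """The canonical 1714-point wavenumber grid, 900--1730 cm^-1."""
    return np.linspace(lo, hi, n)
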