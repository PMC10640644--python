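"""Spectral data-processing stages.

Differential absorbance, asymmetric-least-squares (ALS) baseline
correction, the refractive-index-informed joint baseline correction,
Reststrahlen band integration (the dI statistic), FWHM, the
sensitivity/FWHM figure of merit, and the normalized frequency shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .polariton import (
    AnalyteLoad,
    ReststrahlenBand,
    TransitionCurve,
    coupled_reflectance_spectrum,
    plasmon_shift_from_index,
)
from .spectra import ABSORBANCE_MOD, REFLECTANCE, DifferentialSpectrum, Spectrum, same_grid

__all__ = [
    "BaselineResult",
    "BandStatistic",
    "differential_absorbance",
    "als_baseline",
    "joint_baseline_correct",
    "integrate_band",
    "fwhm",
    "figure_of_merit",
    "normalized_frequency_shift",
]


@dataclass
class BaselineResult:
    """Outcome of a baseline fit."""

    baseline: np.ndarray
    lam: float
    p: float
    iterations: int
    converged: bool
    delta_f: float | None = None  # estimated frequency shift, joint mode only
    clamped: bool = False  # dI fell outside the invertible transition range


@dataclass(frozen=True)
class BandStatistic:
    """Band-integrated differential absorbance dI (mOD*cm^-1)."""

    delta_I: float
    band: ReststrahlenBand


def differential_absorbance(r: Spectrum, r0: Spectrum) -> DifferentialSpectrum:
    """Differential absorbance -1000*log10(R/R0) in mOD.

    ``r`` and ``r0`` must be reflectance spectra on the identical grid.
    """
    if r.kind != REFLECTANCE or r0.kind != REFLECTANCE:
        raise ValueError("both spectra must be reflectance")
    if not same_grid(r, r0):
        raise ValueError("R and R0 must share an identical wavenumber grid")
    return DifferentialSpectrum(
        r.wavenumbers.copy(), -1000.0 * np.log10(r.values / r0.values)
    )


def _second_difference(n: int) -> sparse.csc_matrix:
    d = sparse.eye(n, format="csc")
    return d[2:] - 2 * d[1:-1] + d[:-2]


def als_baseline(
    y,
    lam: float = 1e5,
    p: float = 0.01,
    max_iter: int = 10,
) -> BaselineResult:
    """Asymmetric least squares baseline (Whittaker smoother with
    iteratively reweighted asymmetry).

    Minimizes sum_i w_i (y_i - z_i)^2 + lam * sum_i (d2 z_i)^2 with
    w_i = p where y_i > z_i (points above the baseline, i.e. peaks,
    barely pull) and w_i = 1-p elsewhere. Iterates until the weight
    vector reaches a fixed point or ``max_iter`` is hit.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    d = _second_difference(n)
    penalty = lam * (d.T @ d)
    w = np.ones(n)
    z = y.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W = sparse.diags(w, format="csc")
        z = spsolve(W + penalty, w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            converged = True
            break
        w = w_new
    return BaselineResult(baseline=z, lam=lam, p=p, iterations=it, converged=converged)


def joint_baseline_correct(
    s: Spectrum,
    reference: Spectrum,
    transition: TransitionCurve,
    band: ReststrahlenBand | None = None,
    lam: float = 1e5,
    p: float = 0.01,
    max_iter: int = 10,
    depth: float | None = None,
) -> tuple[DifferentialSpectrum, BaselineResult]:
    """Refractive-index-informed joint baseline correction.

    Two-step procedure:

    1. Estimate the analyte index change dn by matching the in-band
       differential spectrum against the calibrated SPhP response
       family of the transition curve, and map it to the plasmonic
       frequency shift df = -s*dn. The physical platform response at
       dn (coupled reflectance relative to the unloaded reference) is
       then subtracted — the model-informed part of the baseline.
    2. Run plain ALS on the residual to absorb slow instrumental drift.

    Returns the corrected molecular differential spectrum and a
    :class:`BaselineResult` carrying the estimated shift ``delta_f``.
    """
    from .polariton import DEFAULT_DIP_DEPTH

    if depth is None:
        depth = DEFAULT_DIP_DEPTH
    if band is None:
        band = transition.band
    d = differential_absorbance(s, reference)
    dn_hat, clamped = transition.match_dn(d.absorbance[transition.band_mask])
    delta_f = plasmon_shift_from_index(AnalyteLoad(dn_hat), transition.sensitivity)

    r_model = coupled_reflectance_spectrum(
        transition.sys, AnalyteLoad(dn_hat), s.wavenumbers,
        transition.sensitivity, depth,
    )
    r_model0 = coupled_reflectance_spectrum(
        transition.sys, AnalyteLoad(0.0), s.wavenumbers,
        transition.sensitivity, depth,
    )
    platform = -1000.0 * np.log10(r_model.values / r_model0.values)
    residual = d.absorbance - platform

    base = als_baseline(residual, lam=lam, p=p, max_iter=max_iter)
    corrected = DifferentialSpectrum(s.wavenumbers.copy(), residual - base.baseline)
    base.delta_f = delta_f
    base.clamped = clamped
    return corrected, base


def integrate_band(d: DifferentialSpectrum, band: ReststrahlenBand) -> BandStatistic:
    """Trapezoidal band integral dI = int_{w_TO}^{w_LO} D(w) dw on the
    native grid (signed; no resampling)."""
    w = d.wavenumbers
    if band.omega_to < w[0] or band.omega_lo > w[-1]:
        raise ValueError("band lies outside the spectrum grid")
    mask = (w >= band.omega_to) & (w <= band.omega_lo)
    return BandStatistic(
        float(np.trapezoid(d.absorbance[mask], w[mask])), band
    )


def fwhm(s: Spectrum, center: float) -> float:
    """Full width at half maximum of the resonance nearest ``center``.

    Works for peaks and dips: the feature amplitude is measured against
    the mean of the two grid endpoints, and the two half-level crossings
    are located by linear interpolation.
    """
    w, v = s.wavenumbers, s.values
    if not w[0] <= center <= w[-1]:
        raise ValueError("center outside grid")
    ref = 0.5 * (v[0] + v[-1])
    i0 = int(np.argmin(np.abs(w - center)))
    # walk to the local extremum of the feature containing `center`
    sign = 1.0 if v[i0] >= ref else -1.0
    u = sign * (v - ref)
    while 0 < i0 < u.size - 1:
        if u[i0 - 1] > u[i0]:
            i0 -= 1
        elif u[i0 + 1] > u[i0]:
            i0 += 1
        else:
            break
    half = u[i0] / 2.0
    if half <= 0:
        raise ValueError("no resonance found at the requested center")

    def cross(idx_range):
        prev = i0
        for i in idx_range:
            if u[i] <= half:
                # linear interpolation between i and prev
                t = (half - u[i]) / (u[prev] - u[i])
                return w[i] + t * (w[prev] - w[i])
            prev = i
        raise ValueError("half level never crossed on one side of the resonance")

    left = cross(range(i0 - 1, -1, -1))
    right = cross(range(i0 + 1, u.size))
    return float(right - left)


def figure_of_merit(sensitivity: float, fwhm_value: float) -> float:
    """Refractometric figure of merit: sensitivity / FWHM (RIU^-1)."""
    if fwhm_value <= 0:
        raise ValueError("FWHM must be > 0")
    return sensitivity / fwhm_value


def normalized_frequency_shift(pi: float, pi0: float, omega0: float) -> float:
    """Dimensionless normalized frequency shift (pi - pi0)/omega0."""
    if omega0 <= 0:
        raise ValueError("omega0 must be > 0")
    return (pi - pi0) / omega0
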