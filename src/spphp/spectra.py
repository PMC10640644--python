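"""Spectral containers and elementary spectrum arithmetic.

All spectra live on a strictly increasing wavenumber grid in cm^-1.
Two value conventions are used throughout the package:

* ``reflectance`` -- dimensionless reflectance fraction in (0, 1];
* ``absorbance_mOD`` -- absorbance in milli optical density
  (OD x 1000), the unit used for differential molecular signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

REFLECTANCE = "reflectance"
ABSORBANCE_MOD = "absorbance_mOD"

_KINDS = (REFLECTANCE, ABSORBANCE_MOD)


def _as_grid(wavenumbers) -> np.ndarray:
    w = np.asarray(wavenumbers, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("wavenumber grid must be 1-D with at least 2 points")
    if not np.all(np.isfinite(w)):
        raise ValueError("wavenumber grid contains non-finite values")
    if not np.all(np.diff(w) > 0):
        raise ValueError("wavenumber grid must be strictly increasing")
    return w


@dataclass
class Spectrum:
    """A measured or simulated spectrum on a wavenumber grid.

    Parameters
    ----------
    wavenumbers:
        Strictly increasing grid in cm^-1.
    values:
        Same length as the grid. Reflectance values must lie in (0, 1].
    kind:
        ``"reflectance"`` or ``"absorbance_mOD"``.
    """

    wavenumbers: np.ndarray
    values: np.ndarray
    kind: str = REFLECTANCE
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavenumbers = _as_grid(self.wavenumbers)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.wavenumbers.shape:
            raise ValueError("values and wavenumbers must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values contain NaN/Inf")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == REFLECTANCE and (
            np.any(self.values <= 0) or np.any(self.values > 1)
        ):
            raise ValueError("reflectance values must lie in (0, 1]")

    def __len__(self) -> int:
        return self.wavenumbers.size

    def copy(self) -> "Spectrum":
        return replace(
            self,
            wavenumbers=self.wavenumbers.copy(),
            values=self.values.copy(),
            meta=dict(self.meta),
        )


@dataclass
class DifferentialSpectrum:
    """A differential absorbance spectrum, in mOD, on a wavenumber grid."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self):
        self.wavenumbers = _as_grid(self.wavenumbers)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != self.wavenumbers.shape:
            raise ValueError("absorbance and wavenumbers must have equal length")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("differential spectrum contains NaN/Inf")

    def __len__(self) -> int:
        return self.wavenumbers.size


def same_grid(a, b, rtol: float = 0.0, atol: float = 0.0) -> bool:
    """True when two objects share an identical wavenumber grid.

    Exact equality is the default: silent regridding is never allowed;
    use :func:`resample` explicitly when grids differ.
    """
    wa, wb = a.wavenumbers, b.wavenumbers
    if wa.shape != wb.shape:
        return False
    if rtol == 0.0 and atol == 0.0:
        return bool(np.array_equal(wa, wb))
    return bool(np.allclose(wa, wb, rtol=rtol, atol=atol))


def resample(s: Spectrum | DifferentialSpectrum, grid) -> Spectrum | DifferentialSpectrum:
    """Linear-interpolation resampling onto a new strictly increasing grid.

    The new grid must lie within the span of the old one (no extrapolation).
    """
    grid = _as_grid(grid)
    old = s.wavenumbers
    if grid[0] < old[0] or grid[-1] > old[-1]:
        raise ValueError("resample target grid extends beyond the data span")
    if isinstance(s, Spectrum):
        return Spectrum(grid, np.interp(grid, old, s.values), s.kind, dict(s.meta))
    return DifferentialSpectrum(grid, np.interp(grid, old, s.absorbance))
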