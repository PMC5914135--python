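"""Spectral data model and band descriptors for UV/vis and CD spectra.

The aggregation state of chlorin dyes is read off a handful of band
descriptors: the Q_y absorption maximum (bathochromic shift on J-aggregation),
the band width in wavenumbers (exchange narrowing in ordered stacks), and the
anisotropy factor g = delta_epsilon / epsilon, which measures chiral excitonic
order. This module provides the :class:`Spectrum` container, Gaussian-band
synthesis on the energy axis, the descriptor computations, and CSV I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "GaussianBand",
    "SpeciesSpectralModel",
    "nm_to_wavenumber",
    "synthesize_spectrum",
    "anisotropy_factor",
    "band_fwhm",
    "peak_position",
    "band_shift",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "DEFAULT_GRID",
]

#: Default synthesis grid: 350-850 nm at 0.5 nm, covering the Soret band
#: (428 nm) through the red CD couplet lobe (760 nm).
DEFAULT_GRID = np.arange(350.0, 850.0 + 1e-9, 0.5)

_LN2 = np.log(2.0)


def nm_to_wavenumber(wavelength):
    """Convert wavelength in nm to wavenumber in cm^-1 (and back).

    The map ``x -> 1e7 / x`` is its own inverse, so the same function
    converts cm^-1 to nm.
    """
    wl = np.asarray(wavelength, dtype=float)
    if np.any(wl <= 0):
        raise ValueError("wavelength must be positive")
    out = 1.0e7 / wl
    return float(out) if np.isscalar(wavelength) else out


@dataclass(frozen=True)
class Spectrum:
    """Per-monomer molar spectrum on a strictly increasing nm grid.

    Parameters
    ----------
    wavelengths : array, nm, strictly increasing
    epsilon : array, molar absorptivity, M^-1 cm^-1, non-negative
    delta_epsilon : array or None, molar CD, M^-1 cm^-1 (any sign)
    """

    wavelengths: np.ndarray
    epsilon: np.ndarray
    delta_epsilon: np.ndarray | None = None

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        eps = np.asarray(self.epsilon, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "epsilon", eps)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-d array")
        if eps.shape != wl.shape:
            raise ValueError("epsilon and wavelengths must have equal length")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(eps)):
            raise ValueError("spectrum values must be finite")
        if np.any(wl <= 0):
            raise ValueError("wavelengths must be positive")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(eps < 0):
            raise ValueError("epsilon must be non-negative")
        if self.delta_epsilon is not None:
            de = np.asarray(self.delta_epsilon, dtype=float)
            object.__setattr__(self, "delta_epsilon", de)
            if de.shape != wl.shape:
                raise ValueError("delta_epsilon and wavelengths must have equal length")
            if not np.all(np.isfinite(de)):
                raise ValueError("delta_epsilon values must be finite")

    @property
    def has_cd(self) -> bool:
        return self.delta_epsilon is not None


@dataclass(frozen=True)
class GaussianBand:
    """One electronic band, Gaussian on the wavenumber (energy) axis.

    ``amplitude`` is attained exactly at ``center_nm`` and is signed so the
    same primitive models absorption bands (positive) and CD couplet lobes
    (either sign). ``fwhm_cm`` is the full width at half maximum in cm^-1.
    """

    center_nm: float
    amplitude: float
    fwhm_cm: float

    def __post_init__(self):
        if self.center_nm <= 0:
            raise ValueError("band center must be positive")
        if self.fwhm_cm <= 0:
            raise ValueError("band FWHM must be positive")

    def evaluate(self, wavelengths_nm) -> np.ndarray:
        nu = nm_to_wavenumber(np.asarray(wavelengths_nm, dtype=float))
        nu0 = nm_to_wavenumber(self.center_nm)
        return self.amplitude * np.exp(-4.0 * _LN2 * ((nu - nu0) / self.fwhm_cm) ** 2)


@dataclass(frozen=True)
class SpeciesSpectralModel:
    """Gaussian-band description of one species (monomer, J1 or J2).

    For the aggregate species the CD channel is a bisignate exciton couplet:
    exactly one positive and one negative lobe.
    """

    label: str
    absorption_bands: tuple = field(default_factory=tuple)
    cd_bands: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.label not in {"monomer", "J1", "J2"}:
            raise ValueError(f"unknown species label {self.label!r}")
        object.__setattr__(self, "absorption_bands", tuple(self.absorption_bands))
        object.__setattr__(self, "cd_bands", tuple(self.cd_bands))
        if len(self.absorption_bands) < 1:
            raise ValueError("at least one absorption band is required")
        if any(b.amplitude <= 0 for b in self.absorption_bands):
            raise ValueError("absorption band amplitudes must be positive")
        if self.label in {"J1", "J2"}:
            signs = sorted(np.sign(b.amplitude) for b in self.cd_bands)
            if signs != [-1.0, 1.0]:
                raise ValueError(
                    f"{self.label} CD couplet needs exactly one positive and one "
                    "negative lobe"
                )


def synthesize_spectrum(model: SpeciesSpectralModel, grid=DEFAULT_GRID) -> Spectrum:
    """Evaluate a species model on an nm grid; bands sum per channel."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty wavelength grid")
    eps = np.zeros_like(grid)
    for band in model.absorption_bands:
        eps += band.evaluate(grid)
    de = None
    if model.cd_bands:
        de = np.zeros_like(grid)
        for band in model.cd_bands:
            de += band.evaluate(grid)
    return Spectrum(grid, eps, de)


def anisotropy_factor(spectrum: Spectrum, wavelength: float) -> float:
    """Anisotropy factor g = delta_epsilon / epsilon at one wavelength.

    Both channels are linearly interpolated at the query wavelength; the
    ratio is invariant under a common rescaling of the two channels.
    """
    if not spectrum.has_cd:
        raise ValueError("spectrum has no CD channel; g is undefined")
    wl = spectrum.wavelengths
    if not (wl[0] <= wavelength <= wl[-1]):
        raise ValueError(f"wavelength {wavelength} nm outside grid range")
    eps = float(np.interp(wavelength, wl, spectrum.epsilon))
    de = float(np.interp(wavelength, wl, spectrum.delta_epsilon))
    if eps == 0.0:
        raise ZeroDivisionError(f"epsilon vanishes at {wavelength} nm; g undefined")
    return de / eps


def _window_slice(spectrum: Spectrum, window) -> slice:
    lo, hi = sorted(float(w) for w in window)
    idx = np.nonzero((spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi))[0]
    if idx.size < 3:
        raise ValueError("window contains fewer than 3 grid points")
    return slice(idx[0], idx[-1] + 1)


def _parabolic_vertex(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex (position, value) of the parabola through points i-1, i, i+1."""
    x3, y3 = x[i - 1 : i + 2], y[i - 1 : i + 2]
    coeffs = np.polyfit(x3 - x3[1], y3, 2)
    a, b, c = coeffs
    if a == 0:  # collinear: fall back to the grid point
        return float(x3[1]), float(y3[1])
    xv = -b / (2.0 * a)
    return float(x3[1] + xv), float(c - b * b / (4.0 * a))


def _interior_max(y: np.ndarray) -> int:
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        raise ValueError("signal is monotone in window; no interior maximum")
    return i


def peak_position(spectrum: Spectrum, window) -> float:
    """Sub-gridpoint absorption maximum (nm) via 3-point parabolic fit."""
    sl = _window_slice(spectrum, window)
    wl, eps = spectrum.wavelengths[sl], spectrum.epsilon[sl]
    i = _interior_max(eps)
    pos, _ = _parabolic_vertex(wl, eps, i)
    return pos


def band_shift(spec_a: Spectrum, spec_b: Spectrum, window) -> float:
    """Peak displacement b - a in nm; positive means bathochromic (red) shift."""
    return peak_position(spec_b, window) - peak_position(spec_a, window)


def band_fwhm(spectrum: Spectrum, window) -> float:
    """Full width at half maximum of the single band in ``window``, in cm^-1.

    The peak height is taken from a 3-point parabolic fit on the wavenumber
    axis; the two half-maximum crossings are located by linear interpolation
    on the wavenumber axis. Raises if the band is truncated by the window.
    """
    sl = _window_slice(spectrum, window)
    # work on an increasing wavenumber axis
    nu = nm_to_wavenumber(spectrum.wavelengths[sl])[::-1]
    eps = spectrum.epsilon[sl][::-1]
    i = _interior_max(eps)
    _, peak = _parabolic_vertex(nu, eps, i)
    half = peak / 2.0

    def crossing(lo_side: bool) -> float:
        rng = range(i, 0, -1) if lo_side else range(i, eps.size - 1)
        for j in rng:
            k = j - 1 if lo_side else j + 1
            if (eps[j] - half) * (eps[k] - half) <= 0 and eps[j] != eps[k]:
                t = (half - eps[j]) / (eps[k] - eps[j])
                return float(nu[j] + t * (nu[k] - nu[j]))
        side = "low-wavenumber (red)" if lo_side else "high-wavenumber (blue)"
        raise ValueError(f"band truncated by window on the {side} side")

    return crossing(False) - crossing(True)


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    """Write a spectrum as CSV with columns wavelength_nm, epsilon[, delta_epsilon]."""
    cols = {"wavelength_nm": spectrum.wavelengths, "epsilon": spectrum.epsilon}
    if spectrum.has_cd:
        cols["delta_epsilon"] = spectrum.delta_epsilon
    pd.DataFrame(cols).to_csv(path, index=False)


def read_spectrum_csv(path) -> Spectrum:
    """Read a spectrum CSV (header required; delta_epsilon column optional)."""
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "epsilon"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(wl) <= 0)[0]
    if bad.size:
        # +2: data row after the header, 1-based
        raise ValueError(
            f"{path}: wavelength grid not strictly increasing at data row {bad[0] + 2}"
        )
    de = df["delta_epsilon"].to_numpy(dtype=float) if "delta_epsilon" in df.columns else None
    return Spectrum(wl, df["epsilon"].to_numpy(dtype=float), de)
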