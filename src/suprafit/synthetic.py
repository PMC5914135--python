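"""Synthetic spectroscopic data calibrated to the published observables.

No raw spectra are deposited for this system, so every input the analysis
consumes — species spectra, equilibrium concentration series, kinetic traces —
is generated here with the statistical structure the analysis assumes. The
presets encode the printed band descriptors (monomer Qy 656 nm / FWHM
450 cm^-1 plus Soret 428 nm; J1 Qy 738 nm / 850 cm^-1 with a weak bisignate
couplet at +725/-749 nm; J2 Qy 749 nm / 510 cm^-1 with a strong couplet at
+745/-760 nm), the fitted equilibrium constants (K_J1 = 1.3e4, K_N = 2.4e-2,
K_J2 = 1.0e5 M^-1 at 293 K) and the solvent-dependent transformation rates.
CD couplet amplitudes are calibrated numerically at construction so the
anisotropy factor at 745 nm hits the printed g values (-2.7e-3 for J1,
+9.4e-3 for J2). Absolute epsilon scales are arbitrary units with the
monomer Qy peak normalized to 1; every downstream target (g, FWHM, peak
positions, equilibrium constants, rates) is invariant to that scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .equilibrium import ObservableCoefficients, ThermoParams, observable_series
from .kinetics import KineticTrace, simulate_trace
from .spectra import (
    DEFAULT_GRID,
    GaussianBand,
    SpeciesSpectralModel,
    Spectrum,
    anisotropy_factor,
    synthesize_spectrum,
)

__all__ = [
    "NoiseSpec",
    "NOISELESS",
    "PaperPresets",
    "paper_presets",
    "preset_observable_coefficients",
    "generate_concentration_series",
    "generate_kinetic_trace",
    "generate_mixture_spectrum",
    "DEFAULT_CONCENTRATION_GRID",
    "DEFAULT_TRACE_TIMES",
]

#: Concentration grid of the equilibrium study: 5e-7 to 3e-5 M, log-spaced.
DEFAULT_CONCENTRATION_GRID = np.geomspace(5e-7, 3e-5, 15)

#: Default kinetic sampling: 0-3 h, matching the reported time window.
DEFAULT_TRACE_TIMES = np.arange(0.0, 3.0 + 1e-9, 0.02)

#: Wavelength (nm) at which the anisotropy factor is tracked.
G_WAVELENGTH_NM = 745.0


@dataclass(frozen=True)
class NoiseSpec:
    """Seeded measurement noise: per-channel multiplicative and additive sd."""

    eps_mult_sd: float = 0.01
    cd_mult_sd: float = 0.02
    eps_add_sd: float = 0.0
    cd_add_sd: float = 0.0
    seed: int = 1729

    def __post_init__(self):
        if min(self.eps_mult_sd, self.cd_mult_sd,
               self.eps_add_sd, self.cd_add_sd) < 0:
            raise ValueError("noise standard deviations must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


NOISELESS = NoiseSpec(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class PaperPresets:
    """Calibrated species models, equilibrium constants and kinetic presets."""

    monomer: SpeciesSpectralModel
    J1: SpeciesSpectralModel
    J2: SpeciesSpectralModel
    thermo: ThermoParams
    rates_per_h: dict  # MeOH:water label -> initial d(g)/dt, h^-1
    g_start: float  # J1 anisotropy factor at 745 nm
    g_end: float  # J2 anisotropy factor at 745 nm

    def spectrum(self, label: str, grid=DEFAULT_GRID) -> Spectrum:
        return synthesize_spectrum(getattr(self, label), grid)


def _calibrated_couplet(absorption_bands, pos_nm, neg_nm, fwhm_cm, g_target,
                        probe_nm=G_WAVELENGTH_NM, grid=DEFAULT_GRID):
    """Scale an equal-|amplitude| couplet so g(probe) equals g_target.

    g is linear in the couplet amplitude, so the scale follows from one
    evaluation of the unit couplet on the synthesis grid (same linear
    interpolation the anisotropy computation uses).
    """
    eps = synthesize_spectrum(
        SpeciesSpectralModel("monomer", absorption_bands), grid).epsilon
    unit = (GaussianBand(pos_nm, 1.0, fwhm_cm).evaluate(grid)
            + GaussianBand(neg_nm, -1.0, fwhm_cm).evaluate(grid))
    eps_probe = float(np.interp(probe_nm, grid, eps))
    unit_probe = float(np.interp(probe_nm, grid, unit))
    if eps_probe == 0.0 or unit_probe == 0.0:
        raise RuntimeError(
            f"cannot calibrate couplet at {probe_nm} nm: degenerate probe values")
    scale = g_target * eps_probe / unit_probe
    if scale <= 0:
        raise RuntimeError(
            f"couplet lobes at {pos_nm}/{neg_nm} nm cannot reach g({probe_nm}) = "
            f"{g_target:g} with a positive amplitude")
    return (GaussianBand(pos_nm, scale, fwhm_cm),
            GaussianBand(neg_nm, -scale, fwhm_cm))


@lru_cache(maxsize=1)
def paper_presets() -> PaperPresets:
    """The calibrated study presets (cached; construction also verifies them)."""
    # amplitudes in arbitrary units, monomer Qy peak = 1; Soret parameters and
    # the relative aggregate intensities are plausible choices (see docs)
    mono_bands = (GaussianBand(428.0, 1.3, 1400.0), GaussianBand(656.0, 1.0, 450.0))
    j1_abs = (GaussianBand(434.0, 1.0, 1600.0), GaussianBand(738.0, 0.55, 850.0))
    j2_abs = (GaussianBand(434.0, 1.0, 1400.0), GaussianBand(749.0, 1.6, 510.0))

    g_start, g_end = -2.7e-3, 9.4e-3
    j1_cd = _calibrated_couplet(j1_abs, 725.0, 749.0, 850.0, g_start)
    j2_cd = _calibrated_couplet(j2_abs, 745.0, 760.0, 510.0, g_end)

    presets = PaperPresets(
        monomer=SpeciesSpectralModel("monomer", mono_bands),
        J1=SpeciesSpectralModel("J1", j1_abs, j1_cd),
        J2=SpeciesSpectralModel("J2", j2_abs, j2_cd),
        thermo=ThermoParams(K_J1=1.3e4, K_N=2.4e-2, K_J2=1.0e5, T=293.0),
        rates_per_h={"30:70": 8.6e-3, "20:80": 2.5e-3,
                     "10:90": 0.4e-3, "1:99": 0.0},
        g_start=g_start,
        g_end=g_end,
    )
    for label, target in (("J1", g_start), ("J2", g_end)):
        got = anisotropy_factor(presets.spectrum(label), G_WAVELENGTH_NM)
        if abs(got - target) > 1e-5:
            raise RuntimeError(
                f"{label} couplet calibration failed: g(745) = {got:g}, "
                f"target {target:g}")
    return presets


def preset_observable_coefficients(lambda_A_nm: float = 750.0,
                                   lambda_C_nm: float = 746.0,
                                   grid=DEFAULT_GRID) -> ObservableCoefficients:
    """Per-species epsilon/delta_epsilon read off the preset spectra."""
    p = paper_presets()
    vals = {}
    for label in ("monomer", "J1", "J2"):
        s = p.spectrum(label, grid)
        vals[label] = (
            float(np.interp(lambda_A_nm, s.wavelengths, s.epsilon)),
            float(np.interp(lambda_C_nm, s.wavelengths, s.delta_epsilon))
            if s.has_cd else 0.0,
        )
    return ObservableCoefficients(
        eps_mono=vals["monomer"][0], eps_J1=vals["J1"][0], eps_J2=vals["J2"][0],
        deps_mono=vals["monomer"][1], deps_J1=vals["J1"][1], deps_J2=vals["J2"][1],
        lambda_A_nm=lambda_A_nm, lambda_C_nm=lambda_C_nm,
    )


def generate_concentration_series(params: ThermoParams | None = None,
                                  coeffs: ObservableCoefficients | None = None,
                                  grid=None,
                                  noise: NoiseSpec = NOISELESS) -> pd.DataFrame:
    """Equilibrium observables over a concentration grid with seeded noise.

    With ``noise = NOISELESS`` the output equals
    :func:`suprafit.equilibrium.observable_series` exactly.
    """
    params = params or paper_presets().thermo
    coeffs = coeffs or preset_observable_coefficients()
    grid = DEFAULT_CONCENTRATION_GRID if grid is None else np.asarray(grid, float)
    series = observable_series(params, coeffs, grid)
    rng = noise.rng()
    eps = series["epsilon_obs"].to_numpy()
    de = series["delta_epsilon_obs"].to_numpy()
    if noise.eps_mult_sd or noise.eps_add_sd:
        eps = (eps * (1.0 + rng.normal(0.0, noise.eps_mult_sd, eps.size))
               + rng.normal(0.0, noise.eps_add_sd, eps.size))
    if noise.cd_mult_sd or noise.cd_add_sd:
        de = (de * (1.0 + rng.normal(0.0, noise.cd_mult_sd, de.size))
              + rng.normal(0.0, noise.cd_add_sd, de.size))
    return pd.DataFrame({"c_total_M": series["c_total_M"], "epsilon_obs": eps,
                         "delta_epsilon_obs": de})


def generate_kinetic_trace(condition: str, sampling=None,
                           noise: NoiseSpec = NOISELESS,
                           c_T: float = 1e-5, T: float = 293.0) -> KineticTrace:
    """Transformation trace g(t) for one preset MeOH:water condition."""
    p = paper_presets()
    if condition not in p.rates_per_h:
        raise ValueError(
            f"unknown condition {condition!r}; valid: {sorted(p.rates_per_h)}")
    times = DEFAULT_TRACE_TIMES if sampling is None else np.asarray(sampling, float)
    trace = simulate_trace(p.g_start, p.g_end, p.rates_per_h[condition], times,
                           condition={"condition": condition, "cT_M": c_T, "T_K": T})
    g = trace.g_values
    if noise.cd_add_sd or noise.cd_mult_sd:
        rng = noise.rng()
        g = (g * (1.0 + rng.normal(0.0, noise.cd_mult_sd, g.size))
             + rng.normal(0.0, noise.cd_add_sd, g.size))
    return KineticTrace(trace.times, g, trace.condition)


def generate_mixture_spectrum(fractions, grid=DEFAULT_GRID,
                              noise: NoiseSpec = NOISELESS) -> Spectrum:
    """Population-weighted snapshot spectrum of (monomer, dimer, polymer)."""
    phi = np.asarray(fractions, dtype=float)
    if phi.shape != (3,) or np.any(phi < 0) or np.any(phi > 1):
        raise ValueError("fractions must be three values in [0, 1]")
    if abs(phi.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {phi.sum()}")
    p = paper_presets()
    grid = np.asarray(grid, dtype=float)
    eps = np.zeros_like(grid)
    de = np.zeros_like(grid)
    for frac, label in zip(phi, ("monomer", "J1", "J2")):
        s = p.spectrum(label, grid)
        eps += frac * s.epsilon
        if s.has_cd:
            de += frac * s.delta_epsilon
    if noise.eps_mult_sd or noise.eps_add_sd or noise.cd_mult_sd or noise.cd_add_sd:
        rng = noise.rng()
        eps = np.clip(eps * (1.0 + rng.normal(0.0, noise.eps_mult_sd, eps.size))
                      + rng.normal(0.0, noise.eps_add_sd, eps.size), 0.0, None)
        de = (de * (1.0 + rng.normal(0.0, noise.cd_mult_sd, de.size))
              + rng.normal(0.0, noise.cd_add_sd, de.size))
    return Spectrum(grid, eps, de)
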