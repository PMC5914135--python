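"""Competing-pathway equilibrium: off-pathway dimer vs cooperative stacks.

The mass balance combines two pathways that compete for free monomer at
total concentration ``c_T`` (all concentrations in monomer units, M):

* off-pathway dimerization, monomer + monomer <-> dimer, constant ``K_J1``;
* cooperative (K2-K) nucleation-elongation: a dimeric nucleus forms with
  binding constant ``K_N`` and every subsequent monomer addition carries the
  elongation constant ``K_J2``. Cooperativity sigma = K_N / K_J2 << 1 gives a
  sharp polymerization onset near the elongation concentration 1 / K_J2.

Summing the geometric stack series for x = K_J2 * m < 1 gives the closed form

    c_T = m + 2 K_J1 m^2 + K_N m^2 (2 - x) / (1 - x)^2,

whose right-hand side is strictly increasing in m, so the free-monomer root is
unique and safely bracketed. ``truncated_sum_oracle`` keeps the raw series as
an independent check of the closed form.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "ThermoParams",
    "SpeciesDistribution",
    "ObservableCoefficients",
    "free_monomer",
    "species_distribution",
    "mass_fractions",
    "truncated_sum_oracle",
    "observable_series",
    "elongation_concentration",
    "read_series_csv",
    "write_series_csv",
]


@dataclass(frozen=True)
class ThermoParams:
    """Equilibrium constants (M^-1) and temperature (K) of one solvent condition.

    K_J1 : off-pathway dimerization constant
    K_N  : nucleation binding constant (nucleus size 2)
    K_J2 : elongation binding constant
    """

    K_J1: float
    K_N: float
    K_J2: float
    T: float = 293.0

    def __post_init__(self):
        for name in ("K_J1", "K_N", "K_J2", "T"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")

    @property
    def sigma(self) -> float:
        """Cooperativity parameter sigma = K_N / K_J2 (dimensionless)."""
        return self.K_N / self.K_J2


@dataclass(frozen=True)
class SpeciesDistribution:
    """Species populations at one total concentration (monomer units)."""

    c_T: float
    m: float
    phi_mono: float
    phi_dimer: float
    phi_polymer: float
    dp_n: float

    def __post_init__(self):
        if not (0 < self.m <= self.c_T * (1 + 1e-12)):
            raise ValueError("free monomer must satisfy 0 < m <= c_T")
        total = self.phi_mono + self.phi_dimer + self.phi_polymer
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class ObservableCoefficients:
    """Per-species per-monomer epsilon (at lambda_A) and delta_epsilon (at lambda_C)."""

    eps_mono: float
    eps_J1: float
    eps_J2: float
    deps_mono: float
    deps_J1: float
    deps_J2: float
    lambda_A_nm: float = 750.0
    lambda_C_nm: float = 746.0

    def __post_init__(self):
        if min(self.eps_mono, self.eps_J1, self.eps_J2) < 0:
            raise ValueError("epsilon coefficients must be non-negative")
        if self.lambda_A_nm <= 0 or self.lambda_C_nm <= 0:
            raise ValueError("wavelengths must be positive")

    @property
    def eps(self) -> np.ndarray:
        return np.array([self.eps_mono, self.eps_J1, self.eps_J2])

    @property
    def deps(self) -> np.ndarray:
        return np.array([self.deps_mono, self.deps_J1, self.deps_J2])


def _mass_balance_total(params: ThermoParams, m):
    """Total concentration c_T implied by free monomer m (closed form)."""
    m = np.asarray(m, dtype=float)
    x = params.K_J2 * m
    return m + 2.0 * params.K_J1 * m**2 + params.K_N * m**2 * (2.0 - x) / (1.0 - x) ** 2


def free_monomer(params: ThermoParams, c_T, rtol: float = 1e-12, max_iter: int = 200):
    """Free monomer concentration(s) at total concentration(s) ``c_T``.

    Solves the mass balance by bisection on the bracket
    (0, min(c_T, (1 - 1e-12)/K_J2)); the bracket is guaranteed because the
    mass-balance right-hand side is strictly increasing in m and diverges at
    m -> 1/K_J2. Accepts a scalar or an array of concentrations.
    """
    scalar = np.isscalar(c_T)
    c = np.atleast_1d(np.asarray(c_T, dtype=float))
    if np.any(c <= 0) or not np.all(np.isfinite(c)):
        raise ValueError("total concentrations must be positive and finite")
    lo = np.zeros_like(c)
    hi = np.minimum(c, (1.0 - 1e-12) / params.K_J2)
    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        resid = _mass_balance_total(params, mid) - c
        # a root on a very steep branch (x -> 1) can be bracketed to machine
        # precision while its residual stays above rtol*c in float64; accept
        # bracket collapse as convergence in that case
        done = (np.abs(resid) <= rtol * c) | (hi - lo <= 4.0 * np.spacing(mid))
        if np.all(done):
            break
        too_high = resid > 0
        hi = np.where(too_high, mid, hi)
        lo = np.where(too_high, lo, mid)
        mid = 0.5 * (lo + hi)
    else:
        resid = _mass_balance_total(params, mid) - c
        done = (np.abs(resid) <= 1e-10 * c) | (hi - lo <= 4.0 * np.spacing(mid))
        if not np.all(done):
            worst = int(np.argmax(np.abs(resid) / c))
            raise RuntimeError(
                "free_monomer did not converge: "
                f"c_T={c[worst]:.6g}, bracket=({lo[worst]:.6g}, {hi[worst]:.6g}), "
                f"relative residual={abs(resid[worst]) / c[worst]:.3g}"
            )
    return float(mid[0]) if scalar else mid


def mass_fractions(params: ThermoParams, c_T):
    """Vectorized (phi_mono, phi_dimer, phi_polymer) at total concentration(s)."""
    c = np.atleast_1d(np.asarray(c_T, dtype=float))
    m = np.atleast_1d(free_monomer(params, c))
    phi_mono = m / c
    phi_dimer = 2.0 * params.K_J1 * m**2 / c
    phi_poly = 1.0 - phi_mono - phi_dimer
    return phi_mono, phi_dimer, np.clip(phi_poly, 0.0, None), m


def species_distribution(params: ThermoParams, c_T: float) -> SpeciesDistribution:
    """Full species breakdown at one total concentration."""
    phi_mono, phi_dimer, phi_poly, m = mass_fractions(params, float(c_T))
    x = params.K_J2 * m[0]
    dp_n = (2.0 - x) / (1.0 - x)
    return SpeciesDistribution(
        c_T=float(c_T),
        m=float(m[0]),
        phi_mono=float(phi_mono[0]),
        phi_dimer=float(phi_dimer[0]),
        phi_polymer=float(phi_poly[0]),
        dp_n=float(dp_n),
    )


class TruncatedSum(NamedTuple):
    total: float
    last_term: float


def truncated_sum_oracle(params: ThermoParams, m: float, i_max: int) -> TruncatedSum:
    """Mass balance by explicit summation over stack lengths 2..i_max.

    Returns the truncated total concentration and the final summand so callers
    can bound the neglected tail. Independent check of the closed-form series.
    """
    if i_max < 2:
        raise ValueError("i_max must be at least 2")
    x = params.K_J2 * m
    if x >= 1.0:
        raise ValueError(f"series diverges: K_J2 * m = {x} >= 1")
    total = m + 2.0 * params.K_J1 * m**2
    term = 0.0
    base = params.K_N * m * m  # i-th summand is i * base * x^(i-2)
    for i in range(2, i_max + 1):
        term = i * base * x ** (i - 2)
        total += term
    return TruncatedSum(total=float(total), last_term=float(term))


def observable_series(params: ThermoParams, coeffs: ObservableCoefficients,
                      concentrations) -> pd.DataFrame:
    """Equilibrium observables over a concentration grid.

    Per-monomer convention: the observed epsilon (delta_epsilon) is the
    mass-fraction-weighted mean of the species coefficients, so each
    observable is a convex combination of its three coefficients.
    """
    c = np.atleast_1d(np.asarray(concentrations, dtype=float))
    phi_mono, phi_dimer, phi_poly, _ = mass_fractions(params, c)
    phi = np.column_stack([phi_mono, phi_dimer, phi_poly])
    return pd.DataFrame({
        "c_total_M": c,
        "epsilon_obs": phi @ coeffs.eps,
        "delta_epsilon_obs": phi @ coeffs.deps,
    })


def elongation_concentration(params: ThermoParams) -> float:
    """Concentration scale 1/K_J2 above which extended stacks accumulate."""
    return 1.0 / params.K_J2


def write_series_csv(series: pd.DataFrame, path, lambda_A_nm: float = 750.0,
                     lambda_C_nm: float = 746.0) -> None:
    """Write a concentration series with `# key=value` metadata header lines."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# lambda_A_nm={lambda_A_nm:g}\n")
        fh.write(f"# lambda_C_nm={lambda_C_nm:g}\n")
        series.to_csv(fh, index=False)


def read_series_csv(path) -> tuple[pd.DataFrame, dict]:
    """Read a concentration series CSV; returns (table, metadata)."""
    meta: dict[str, float] = {}
    lines = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = float(value)
            else:
                lines.append(line)
    df = pd.read_csv(io.StringIO("".join(lines)))
    required = {"c_total_M", "epsilon_obs", "delta_epsilon_obs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df, meta
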