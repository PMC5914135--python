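"""Equilibrium-constant estimation and Gibbs-energy landscape construction.

The concentration-dependent observables (epsilon at lambda_A, delta_epsilon at
lambda_C) are fitted to the competing-pathway equilibrium of
:mod:`suprafit.equilibrium`. The problem is separable: for fixed equilibrium
constants the observables are linear in the six per-species coefficients, so
the fit searches the three constants in log10 space and solves the
coefficients by linear least squares at every evaluation (variable
projection). Constants convert to standard Gibbs energies via
dG = -R T ln K, and the three processes assemble into an energy landscape
whose maximum identifies the rate-limiting step (nucleation, for a
cooperative system).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls
from sklearn.base import BaseEstimator, RegressorMixin

from .equilibrium import ObservableCoefficients, ThermoParams, mass_fractions

__all__ = [
    "R_GAS",
    "gibbs_energy",
    "EnergyLandscape",
    "energy_landscape",
    "EquilibriumFit",
    "FitResult",
    "fit_concentration_series",
]

#: Ideal gas constant, J mol^-1 K^-1.
R_GAS = 8.31446

_PROCESSES = ("off-pathway dimerization", "nucleation", "elongation")


def gibbs_energy(K: float, T: float) -> float:
    """Standard Gibbs energy dG = -R T ln K, in kJ mol^-1.

    K is a binding equilibrium constant in M^-1; K > 1 (favourable binding)
    gives dG < 0, and an unfavourable step such as nucleation with K << 1
    gives dG > 0.
    """
    if K <= 0:
        raise ValueError("equilibrium constant must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    return -R_GAS * T * np.log(K) / 1000.0


@dataclass(frozen=True)
class EnergyLandscape:
    """Gibbs energies of the three assembly processes at one temperature."""

    entries: tuple  # of (process, K, dG_kJ_per_mol)
    T: float
    rate_limiting: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p, k, dg) for p, k, dg in self.entries],
            columns=["process", "K_per_M", "dG_kJ_per_mol"],
        )


def energy_landscape(params: ThermoParams) -> EnergyLandscape:
    """Assemble the energy landscape from fitted constants.

    The process with the largest (least favourable) dG is flagged as
    rate-limiting; for a cooperative system (sigma << 1) that is nucleation.
    """
    ks = (params.K_J1, params.K_N, params.K_J2)
    entries = tuple(
        (proc, k, gibbs_energy(k, params.T)) for proc, k in zip(_PROCESSES, ks)
    )
    rate_limiting = max(entries, key=lambda e: e[2])[0]
    return EnergyLandscape(entries=entries, T=params.T, rate_limiting=rate_limiting)


@dataclass
class FitResult:
    """Outcome of a concentration-series fit."""

    params: ThermoParams
    coeffs: ObservableCoefficients
    rss_epsilon: float
    rss_delta_epsilon: float
    converged: bool
    iterations: int
    nonneg_refit: bool = False
    uncertainty: dict | None = None  # per-constant bootstrap std of log10 K

    def to_text(self) -> str:
        lines = [
            "Competing-pathway equilibrium fit",
            f"  K_J1 (dimerization) = {self.params.K_J1:.4g} M^-1",
            f"  K_N  (nucleation)   = {self.params.K_N:.4g} M^-1",
            f"  K_J2 (elongation)   = {self.params.K_J2:.4g} M^-1",
            f"  sigma = K_N/K_J2    = {self.params.sigma:.4g}",
            f"  T = {self.params.T:g} K",
            f"  RSS epsilon channel        = {self.rss_epsilon:.4g}",
            f"  RSS delta-epsilon channel  = {self.rss_delta_epsilon:.4g}",
            f"  converged = {self.converged} ({self.iterations} evaluations)",
        ]
        if self.uncertainty:
            lines.append("  bootstrap std of log10 K: " + ", ".join(
                f"{k}={v:.3g}" for k, v in self.uncertainty.items()))
        return "\n".join(lines)


class EquilibriumFit(BaseEstimator, RegressorMixin):
    """Fit the competing dimerization + nucleation-elongation model.

    scikit-learn style estimator: ``X`` is the total-concentration grid
    (shape (n,) or (n, 1), in M) and ``y`` holds the two observable channels
    as columns ``[epsilon_obs, delta_epsilon_obs]``.

    The three equilibrium constants are searched in log10 space with a
    bounded trust-region least-squares optimizer; at each evaluation the six
    per-species spectroscopic coefficients are projected out by linear least
    squares (non-negativity enforced on the epsilon channel via NNLS when the
    unconstrained solution goes negative). Residuals of each channel are
    normalized by that channel's observed range so the two channels carry
    comparable weight. Several jittered starts guard against the multimodal
    biphasic objective; the best final cost wins, ties broken by smallest K_N.

    Parameters
    ----------
    init : ThermoParams or None
        Initial guess for the constants. If None, a heuristic from the data
        is used (elongation onset locates K_J2).
    T : float
        Absolute temperature in K, stored in the fitted parameters.
    n_starts : int
        Number of optimizer starts (first at ``init``, the rest jittered).
    jitter_decades : float
        Std of the log10 jitter applied to the extra starts.
    pin_monomer : tuple or None
        Optional (eps_mono, deps_mono) pinned from dilute-regime spectra
        instead of co-fitted.
    n_bootstrap : int
        Residual-bootstrap resamples for parameter uncertainty (0 = off).
    seed : int
        Seed for start jitter and bootstrap.

    Attributes
    ----------
    params_ : ThermoParams           fitted constants
    coeffs_ : ObservableCoefficients fitted per-species coefficients
    cost_ : float                    final normalized residual cost
    rss_ : dict                      raw residual sum of squares per channel
    converged_ : bool
    n_iter_ : int                    objective evaluations of the best start
    """

    def __init__(self, init=None, T=293.0, n_starts=5, jitter_decades=0.5,
                 pin_monomer=None, n_bootstrap=0, seed=0,
                 lambda_A_nm=750.0, lambda_C_nm=746.0):
        self.init = init
        self.T = T
        self.n_starts = n_starts
        self.jitter_decades = jitter_decades
        self.pin_monomer = pin_monomer
        self.n_bootstrap = n_bootstrap
        self.seed = seed
        self.lambda_A_nm = lambda_A_nm
        self.lambda_C_nm = lambda_C_nm

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _validate(X, y):
        c = np.asarray(X, dtype=float)
        if c.ndim == 2 and c.shape[1] == 1:
            c = c[:, 0]
        if c.ndim != 1:
            raise ValueError("X must be a 1-d concentration grid or (n, 1) array")
        Y = np.asarray(y, dtype=float)
        if Y.ndim != 2 or Y.shape != (c.size, 2):
            raise ValueError("y must be (n, 2): epsilon and delta_epsilon channels")
        if np.any(c <= 0) or not np.all(np.isfinite(c)) or not np.all(np.isfinite(Y)):
            raise ValueError("concentrations must be positive; all values finite")
        if np.unique(c).size < 8:
            raise ValueError("need at least 8 distinct concentrations")
        span = np.log10(c.max() / c.min())
        if span < 1.5:
            raise ValueError(
                f"concentration grid spans {span:.2f} decades; need >= 1.5")
        order = np.argsort(c)
        return c[order], Y[order]

    def _solve_coeffs(self, phi, Y):
        """Variable projection: channel coefficients by linear least squares."""
        ranges = np.maximum(Y.max(axis=0) - Y.min(axis=0), 1e-300)
        coeffs = np.empty((3, 2))
        nonneg = False
        for ch in range(2):
            if self.pin_monomer is not None:
                rhs = Y[:, ch] - phi[:, 0] * self.pin_monomer[ch]
                A = phi[:, 1:]
                sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
                if ch == 0 and np.any(sol < 0):
                    sol, _ = nnls(A, rhs)
                    nonneg = True
                coeffs[:, ch] = np.concatenate([[self.pin_monomer[ch]], sol])
            else:
                sol, *_ = np.linalg.lstsq(phi, Y[:, ch], rcond=None)
                if ch == 0 and np.any(sol < 0):
                    sol, _ = nnls(phi, Y[:, ch])
                    nonneg = True
                coeffs[:, ch] = sol
        resid = (phi @ coeffs - Y) / ranges
        return coeffs, resid, nonneg

    def _residual_factory(self, c, Y, counter):
        def residual(theta):
            counter[0] += 1
            params = ThermoParams(10.0 ** theta[0], 10.0 ** theta[1],
                                  10.0 ** theta[2], self.T)
            pm, pd_, pp, _ = mass_fractions(params, c)
            phi = np.column_stack([pm, pd_, pp])
            _, resid, _ = self._solve_coeffs(phi, Y)
            return resid.ravel(order="F")
        return residual

    def _default_init(self, c, Y) -> np.ndarray:
        # elongation onset: concentration where the epsilon channel crosses
        # the midpoint of its range locates 1/K_J2 within a small factor
        eps = Y[:, 0]
        mid = 0.5 * (eps.min() + eps.max())
        rising = eps[-1] >= eps[0]
        crossed = np.nonzero((eps >= mid) if rising else (eps <= mid))[0]
        c_half = c[crossed[0]] if crossed.size else np.sqrt(c[0] * c[-1])
        k_j2 = 1.0 / c_half
        return np.log10([k_j2 / 10.0, 1e-6 * k_j2, k_j2])

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        c, Y = self._validate(X, y)
        ranges = Y.max(axis=0) - Y.min(axis=0)
        if np.any(ranges <= 0):
            flat = ["epsilon", "delta_epsilon"][int(np.argmin(ranges))]
            raise ValueError(
                f"non-identifiable series: {flat} channel is constant over the grid")

        if self.init is not None:
            theta0 = np.log10([self.init.K_J1, self.init.K_N, self.init.K_J2])
        else:
            theta0 = self._default_init(c, Y)

        rng = np.random.default_rng(self.seed)
        starts = [theta0] + [
            theta0 + rng.normal(0.0, self.jitter_decades, size=3)
            for _ in range(max(0, self.n_starts - 1))
        ]
        bounds = (np.full(3, -12.0), np.full(3, 12.0))

        best = None
        for theta_start in starts:
            counter = [0]
            residual = self._residual_factory(c, Y, counter)
            sol = least_squares(
                residual, np.clip(theta_start, bounds[0] + 1e-9, bounds[1] - 1e-9),
                bounds=bounds, method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-12, max_nfev=400,
            )
            key = (sol.cost, sol.x[1])  # ties broken by smallest K_N
            if best is None or key < best[0]:
                best = (key, sol, counter[0])
        sol, nfev = best[1], best[2]

        params = ThermoParams(*(10.0 ** sol.x), self.T)
        pm, pd_, pp, _ = mass_fractions(params, c)
        phi = np.column_stack([pm, pd_, pp])
        coeffs, resid, nonneg = self._solve_coeffs(phi, Y)
        raw = phi @ coeffs - Y

        self.params_ = params
        self.coeffs_ = ObservableCoefficients(
            eps_mono=coeffs[0, 0], eps_J1=coeffs[1, 0], eps_J2=coeffs[2, 0],
            deps_mono=coeffs[0, 1], deps_J1=coeffs[1, 1], deps_J2=coeffs[2, 1],
            lambda_A_nm=self.lambda_A_nm, lambda_C_nm=self.lambda_C_nm,
        )
        self.cost_ = float(sol.cost)
        self.rss_ = {
            "epsilon": float(np.sum(raw[:, 0] ** 2)),
            "delta_epsilon": float(np.sum(raw[:, 1] ** 2)),
        }
        self.converged_ = bool(sol.success)
        self.n_iter_ = int(nfev)
        self.nonneg_refit_ = nonneg
        self.uncertainty_ = (
            self._bootstrap(c, Y, raw, rng) if self.n_bootstrap > 0 else None
        )
        return self

    def _bootstrap(self, c, Y, raw, rng) -> dict:
        """Residual bootstrap: std of log10 K over refits to resampled data."""
        fitted = Y - raw
        thetas = []
        point = np.log10([self.params_.K_J1, self.params_.K_N, self.params_.K_J2])
        for _ in range(self.n_bootstrap):
            idx = rng.integers(0, c.size, size=c.size)
            Yb = fitted + raw[idx]
            residual = self._residual_factory(c, Yb, [0])
            sol = least_squares(residual, point, bounds=(np.full(3, -12.0),
                                np.full(3, 12.0)), method="trf", max_nfev=100)
            thetas.append(sol.x)
        std = np.std(np.array(thetas), axis=0)
        return {"log10_K_J1": float(std[0]), "log10_K_N": float(std[1]),
                "log10_K_J2": float(std[2])}

    def predict(self, X):
        """Predicted [epsilon_obs, delta_epsilon_obs] at concentrations ``X``."""
        if not hasattr(self, "params_"):
            raise AttributeError("EquilibriumFit is not fitted yet")
        c = np.asarray(X, dtype=float)
        if c.ndim == 2 and c.shape[1] == 1:
            c = c[:, 0]
        pm, pd_, pp, _ = mass_fractions(self.params_, c)
        phi = np.column_stack([pm, pd_, pp])
        return np.column_stack([phi @ self.coeffs_.eps, phi @ self.coeffs_.deps])

    def result_(self) -> FitResult:
        return FitResult(
            params=self.params_, coeffs=self.coeffs_,
            rss_epsilon=self.rss_["epsilon"],
            rss_delta_epsilon=self.rss_["delta_epsilon"],
            converged=self.converged_, iterations=self.n_iter_,
            nonneg_refit=self.nonneg_refit_, uncertainty=self.uncertainty_,
        )


def fit_concentration_series(series: pd.DataFrame, init: ThermoParams | None = None,
                             **options) -> FitResult:
    """Fit a concentration-series table (columns c_total_M, epsilon_obs,
    delta_epsilon_obs); thin wrapper over :class:`EquilibriumFit`."""
    est = EquilibriumFit(init=init, **options)
    X = series["c_total_M"].to_numpy(dtype=float)
    y = series[["epsilon_obs", "delta_epsilon_obs"]].to_numpy(dtype=float)
    est.fit(X, y)
    return est.result_()
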