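# Methods

## Equilibrium model

Two pathways compete for free monomer `m` at total concentration `c_T`
(monomer units, M, 293 K):

* **Off-pathway dimerization.** monomer + monomer ⇌ dimer with constant
  `K_J1` (M⁻¹). The off-pathway species is modeled as a dimer only; the
  clustering of dimers into nanoparticles is treated as spectroscopically
  silent, so higher off-pathway clusters carry no extra parameters.
* **Cooperative nucleation–elongation (K2–K).** A dimeric nucleus forms with
  binding constant `K_N`; every subsequent monomer addition carries the
  elongation constant `K_J2`. The stack of length `i ≥ 2` then has
  concentration `K_N·K_J2^(i−2)·m^i`.

Summing the geometric series for `x = K_J2·m < 1`:

```
c_T = m + 2·K_J1·m² + K_N·m²·(2 − x)/(1 − x)²
```

with number-average stack length `DP_n = (2 − x)/(1 − x) ≥ 2`. The closed form
is verified two independent ways in the tests: against explicit truncated
summation over stack lengths (`truncated_sum_oracle`, tail bounded by the
reported last term) and against the isodesmic algebraic reduction
`c_T = m/(1 − K·m)²` when `K_N = K_J2` and `K_J1 = 0`.

**Root solving.** The right-hand side is strictly increasing in `m` and
diverges as `m → 1/K_J2`, so the root is unique and bracketed in
`(0, min(c_T, (1−10⁻¹²)/K_J2))`. It is found by vectorized bisection (budget
200 iterations) to a relative residual of 10⁻¹². On the very steep branch
(`x → 1`, reached for extreme trial parameters during optimization) the
residual tolerance can be unattainable in double precision even though the
root is exact to representation; bracket collapse to ~4 ulp is then accepted
as convergence.

**Observables.** Per-monomer convention: observed ε at λ_A (default 750 nm)
and Δε at λ_C (default 746 nm) are mass-fraction-weighted means of three
per-species coefficients each, hence convex combinations of the coefficients.

## Spectral descriptors

Bands are Gaussian on the wavenumber (energy) axis — the physical lineshape
convention, and the widths of interest are quoted in cm⁻¹ — evaluated on an
nm grid (default 350–850 nm at 0.5 nm). Descriptors:

* **Peak position**: 3-point parabolic interpolation around the grid maximum
  (sub-gridpoint accuracy, ~0.001 nm on the default grid for a clean band).
* **FWHM**: peak height from the parabolic fit on the wavenumber axis;
  half-maximum crossings by linear interpolation on the wavenumber axis. On a
  0.5 nm grid the generating FWHM of a single Gaussian is recovered well
  within 1% (tested for 450/510/850 cm⁻¹ and against the
  `FWHM = 2√(2 ln 2)·σ` relation).
* **Anisotropy factor** `g = Δε/ε`: both channels linearly interpolated at
  the query wavelength; invariant under common rescaling of the channels.

All other interpolation is linear between grid points.

## Thermodynamic fit

The estimator (`EquilibriumFit`) minimizes the summed squared residuals of
both channels, each channel normalized by its observed range so both carry
comparable weight. Structure is separable: for fixed constants the model is
linear in the six coefficients, which are solved per evaluation by linear
least squares (variable projection); non-negativity of the ε coefficients is
enforced by NNLS only when the unconstrained solution goes negative, and the
refit is flagged. The three constants are searched as log₁₀ values (positivity
by construction) with scipy's bounded trust-region least-squares
(`least_squares`, method `trf`, bounds 10⁻¹²–10¹² M⁻¹, xtol/ftol 10⁻¹⁴).
Because the biphasic objective can be multimodal, 5 seeded starts are used:
the supplied or data-derived initial guess plus jittered copies (σ = 0.5
decades); best final cost wins, ties broken by smallest K_N. The default
initial guess reads the elongation onset off the data (the concentration
where the ε channel crosses the midpoint of its range approximates `1/K_J2`),
sets `K_J1 = K_J2/10` and `σ = 10⁻⁶`. Monomer coefficients can optionally be
pinned from dilute-regime measurements (`pin_monomer`); the default co-fits
them, since the dilute regime is monomeric anyway.

Gibbs energies use `ΔG° = −R·T·ln K` with `R = 8.31446 J mol⁻¹ K⁻¹`, reported
in kJ mol⁻¹. The landscape flags the process with the largest ΔG° as
rate-limiting; for a cooperative system (σ ≪ 1) that is nucleation.

**Identifiability.** With the study constants, σ ≈ 2.4×10⁻⁷, and the
nucleation constant is only weakly constrained by equilibrium data: under
measurement noise the fitted `K_N` can wander over orders of magnitude while
`K_J1` and `K_J2` remain well determined (the tests assert a ≤25% median
relative error for those two under the generator's default noise; `K_N` is
deliberately excluded). The optional residual bootstrap (seeded, default 200
resamples when enabled) reports the spread of log₁₀ K — an addition of this
package; the original analysis reports no uncertainties.

## Kinetics

The transformation of the trapped into the equilibrated aggregate is followed
through g(t) at 745 nm; times in hours, rates in h⁻¹.

* **Forward model** (`simulate_trace`): single-exponential approach
  `g(t) = g_start + Δg·(1 − e^(−kt))` with `k = rate/|Δg|`, so the analytic
  derivative at t = 0 equals the requested initial rate exactly. Real traces
  may show lag phases from off-pathway depletion; a lag is not modeled
  (the empirical initial rate is the only kinetic quantity analyzed).
* **Initial rate** (`initial_rate`): the window is the leading run of samples
  whose g has moved by at most 25% of the total observed change (minimum 3
  samples). A straight-line slope on that window would be biased low by
  ≈ kT_w/2 ≈ 13% for an exponential trace covering 25% of its change, so the
  estimator fits a quadratic on the window and reports its derivative at the
  first sample; the residual bias is ≈ (kT_w)²/10 ≤ 0.9% at the 25% window,
  comfortably inside the 3% recovery tolerance the tests assert. An exact
  line is returned exactly for any window; a constant trace gives rate 0.
  The estimate scales as 1/s when time is scaled by s. A warning flag is set
  when the fitted initial slope opposes the overall direction of change.

## Synthetic data

The generator emulates the study's three spectroscopic species and its
measurement designs:

* **Species presets** (amplitudes in arbitrary units, monomer Qy peak = 1;
  every analysis target — g, FWHM, positions, constants, rates — is invariant
  to the absolute ε scale): monomer Soret 428 nm + Qy 656 nm (FWHM 450 cm⁻¹);
  J1 Qy 738 nm (850 cm⁻¹), weak couplet +725/−749 nm; J2 Qy 749 nm
  (510 cm⁻¹), strong couplet +745/−760 nm. Aggregate Qy amplitudes (0.55 and
  1.6) follow approximate oscillator-strength conservation across the width
  change plus the pronounced intensification of the ordered fiber band; Soret
  parameters are plausible round values. Couplets are two opposite-signed
  Gaussians of equal |amplitude| at the printed extrema wavelengths, reusing
  the species' absorption FWHM (the lobe widths are not printed); amplitudes
  are calibrated numerically at construction so g(745 nm) equals −2.7×10⁻³
  (J1) and +9.4×10⁻³ (J2) to 10⁻⁵. Because the lobes overlap strongly, the
  observed couplet extrema sit slightly outside the lobe centers — the zero
  crossing and sign structure are what the analysis relies on.
* **Equilibrium constants**: K_J1 = 1.3×10⁴, K_N = 2.4×10⁻², K_J2 = 1.0×10⁵
  M⁻¹ at 293 K. Concentration grid: 15 log-spaced points, 5×10⁻⁷–3×10⁻⁵ M.
* **Kinetic presets** (MeOH:water → initial d(g)/dt): 30:70 → 8.6×10⁻³,
  20:80 → 2.5×10⁻³, 10:90 → 0.4×10⁻³, 1:99 → 0 h⁻¹ (deep trap), all between
  g = −2.7×10⁻³ and +9.4×10⁻³; default sampling 0–3 h at 0.02 h.
* **Noise**: seeded (default seed 1729), multiplicative 1% on ε and 2% on Δε
  by default plus optional additive terms; true experimental noise levels are
  not reported, so these are conventional values and labeled as such. Noise 0
  reproduces the deterministic pipeline exactly; all generators are
  bit-reproducible under a fixed seed.

What passing the round-trip tests shows — and does not show: the estimators
recover the generating parameters when the data actually follow the model
(correct lineshape, single-exponential kinetics, independent Gaussian noise).
Real spectra add baseline drift, vibronic structure, solvent-dependent
coefficients and possible lag phases, none of which are emulated, so the
tests validate the inference machinery, not the model's adequacy for any
particular experiment.

## Problem sizes and numerical choices

Defaults keep every analysis fast: 15-point series fits take well under a
second; the noise-robustness study (50 replicates × 12 concentrations) runs
in about a minute. Degenerate inputs fail loudly: constant observable
channels raise a non-identifiability error, truncated bands name the missing
half-maximum side, traces shorter than 4 samples are rejected, and the series
oracle refuses `K_J2·m ≥ 1`.

## Known limitations

* Single temperature; no van 't Hoff analysis and no solvent-composition
  model — each solvent ratio is a separate parameter set.
* No mechanistic ODE model of the pathway exchange; kinetics are empirical
  initial rates only.
* K_N (equivalently σ) is weakly identified from equilibrium data alone;
  treat its point estimate with the bootstrap spread, not at face value.
* The spectral model excludes vibronic progressions, Soret-region exciton
  analysis and instrument artifacts.
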