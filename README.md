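# suprafit

Thermodynamic and kinetic analysis of **competing supramolecular polymerization
pathways**, built for the self-assembly of a semi-synthetic zinc chlorin dye
(a model of the bacteriochlorophyll pigments of chlorosomal light-harvesting
antennae) in methanol/water mixtures. The dye can either form kinetically
trapped nanoparticles of antiparallel dimers (an off-pathway J-aggregate,
"J1") or grow into thermodynamically stable helical J-aggregate nanofibers
("J2"). `suprafit` quantifies that pathway competition from concentration-
and time-dependent UV/vis and circular dichroism (CD) observables.

## The model

At total concentration `c_T` (monomer units, M) the free monomer `m` is shared
between an off-pathway dimer and cooperatively nucleated stacks. With an
off-pathway dimerization constant `K_J1`, a nucleation binding constant `K_N`
(nucleus size 2) and an elongation constant `K_J2` applied to every further
addition (the cooperative K2–K model), summing the stack series for
`x = K_J2·m < 1` gives the mass balance

```
c_T = m + 2·K_J1·m² + K_N·m²·(2 − x)/(1 − x)²,      x = K_J2·m
```

whose right-hand side is strictly increasing in `m`, so the root is unique.
Cooperativity `σ = K_N/K_J2 ≪ 1` produces a sharp polymerization onset near
the elongation concentration `1/K_J2`. Observables follow the per-monomer
convention: the measured molar absorptivity ε (and molar CD Δε) is the
mass-fraction-weighted mean of per-species coefficients. The fit
(`EquilibriumFit`, a scikit-learn-style estimator) searches the three
constants in log₁₀ space and projects the six linear coefficients out by
linear least squares at each step (variable projection). Constants convert to
standard Gibbs energies via `ΔG° = −RT ln K`, giving the energy landscape of
the two pathways. The trapped-to-equilibrated transformation J1 → J2 is
followed through the anisotropy factor `g = Δε/ε` at 745 nm, and its initial
rate d(g)/dt is estimated on the window covering the first 25% of the
observed change.

No raw spectra are deposited for this system, so the `synthetic` module
generates every input — species spectra, concentration series, kinetic
traces — calibrated to the published band positions, widths, g values,
equilibrium constants and rates, with seeded noise.

## Worked example

```python
import suprafit as sf

series = sf.generate_concentration_series()          # noiseless, 15 points
result = sf.fit_concentration_series(series)
print(result.to_text())
```

prints

```
Competing-pathway equilibrium fit
  K_J1 (dimerization) = 1.3e+04 M^-1
  K_N  (nucleation)   = 0.024 M^-1
  K_J2 (elongation)   = 1e+05 M^-1
  sigma = K_N/K_J2    = 2.4e-07
  T = 293 K
  RSS epsilon channel        = 2.854e-27
  RSS delta-epsilon channel  = 2.597e-32
  converged = True (95 evaluations)
```

i.e. the three equilibrium constants are recovered from the concentration
series: dimerization is favourable (ΔG° ≈ −23.1 kJ/mol), elongation more so
(−28.0 kJ/mol), and nucleation is the energetically unfavourable,
rate-limiting step (+9.1 kJ/mol at 293 K) — the signature of an off-pathway
trap next to a cooperative growth pathway:

```python
print(sf.energy_landscape(result.params).to_frame())
#                     process     K_per_M  dG_kJ_per_mol
# 0  off-pathway dimerization   13000.000     -23.076804
# 1                nucleation       0.024       9.086063
# 2                elongation  100000.000     -28.047061

trace = sf.generate_kinetic_trace("30:70")           # MeOH:water 30:70
print(sf.initial_rate(trace).rate)                   # 0.00856 h^-1
```

The same pipeline is available from the shell:

```
suprafit generate --out dataset --seed 1729
suprafit fit --series dataset/series.csv --out fit
suprafit kinetics --traces dataset/traces --out rates.csv
suprafit report --fit-dir fit --rates rates.csv
```

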