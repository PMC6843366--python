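# cyclofit

Binding analysis for drug/cyclodextrin inclusion complexes.

When a poorly soluble drug (the *guest*, e.g. the quinone antioxidant
idebenone) is formulated with a cyclodextrin (the *host*, e.g.
2-hydroxypropyl-β-cyclodextrin), the evidence for a 1:1 inclusion complex
and its strength comes from several independent experiments.  `cyclofit`
implements the complete desk-side analysis chain for such a study, plus
seeded synthetic-data generators so every stage can be exercised and
validated without any instrument data:

* **Phase solubility** (Higuchi–Connors).  An A_L diagram is the line
  S(c) = S₀ + c·K_c S₀/(1 + K_c S₀); the association constant follows from
  the fitted slope as **K_c = slope / (S₀ (1 − slope))** and the binding
  free energy as ΔG = −RT ln K_c.
* **Global UV–Vis titration fitting.**  Speciation of any set of complexes
  HₕG_g ([HₕG_g] = β_hg [H]ʰ[G]ᵍ, log₁₀ β parameterization) is solved by
  damped Newton iteration in log-concentration space; absorbance matrices
  are fitted by *variable projection* — the outer search runs over log β
  while each absorbing species' molar absorptivity spectrum is recovered by
  non-negative least squares at every step.  Candidate stoichiometries
  (1:1, 1:1+1:2, 1:1+2:1) are ranked by residual-trend analysis
  (per-wavelength runs tests) and AICc.
* **O–H band deconvolution + van 't Hoff thermodynamics.**  The O–H
  stretching envelope (3800–3000 cm⁻¹) is decomposed into six Voigt
  sub-bands seeded from Savitzky–Golay second-derivative minima, after
  modelling and subtracting the overlapping C–H doublet.  The two-state
  population ratio R = (I₁+I₂)/(I₃+I₄+I₅+I₆) fitted as
  ln R = −ΔH_HB/(R_gas T) + ΔS_HB/R_gas yields the mean hydrogen-bond
  rupture enthalpy; an isosbestic-point check validates the two-state
  picture.
* **DOSY and chemical shifts.**  Fast-exchange bound fractions
  f = (D_free − D_obs)/(D_free − D_complex), 1:1 inversion to K_c, and Δδ
  displacement tables.
* **Assay arithmetic.**  Viability %, LDH release %, Franz-cell cumulative
  permeation with the sampling-replacement correction
  Qₙ = Cₙ·V_receptor + Σ_{i<n} Cᵢ·V_sample, and HPLC calibration with
  LOD/LOQ at S/N = 3 and 10.

The package is aimed at formulation and physical-chemistry groups who want
these standard analyses scripted, testable and reproducible instead of
spread over vendor software.

## Worked example

```python
import cyclofit as cf

# phase solubility: synthesize an A_L isotherm and fit it back
data = cf.gen_phase_solubility(kc=6031, s0=2e-5, cv=0.02, seed=1)
res = cf.fit_phase_solubility(data, s0=2e-5)
print(res.summary())
```

```
Phase-solubility fit (Higuchi-Connors)
--------------------------------------
diagram class : A_L
slope         : 0.1084 +/- 0.0007
intercept (M) : 1.891e-05 +/- 3.552e-06
r-squared     : 0.99970
S0 used (M)   : 2.000e-05
Kc (M^-1)     : 6077 +/- 42
dG (kcal/mol) : -5.16
```

The diagram is linear (r² ≈ 0.9997) with slope < 1, hence A_L: a soluble
1:1-type complex.  The association constant recovered from the noisy
isotherm (6077 ± 42 M⁻¹) agrees with the generating value 6031 M⁻¹, and
−RT ln K_c ≈ −5.2 kcal/mol is a moderately strong host–guest association.

```python
# global titration fit with stoichiometry selection
tit = cf.gen_titration(noise_sd=0.002, seed=1)
report = cf.select_model(tit, ["1:1", "1:1+1:2", "1:1+2:1"], seed=1)
print(report.summary())
```

```
Stoichiometry model selection
-----------------------------
1. 1:1        rss=2.442e-03 AICc=-9726.0 residuals=random
2. 1:1+2:1    rss=2.083e-03 AICc=-9415.8 residuals=random
3. 1:1+1:2    rss=2.169e-03 AICc=-9383.3 residuals=random
```

All three candidates fit the absorbance matrix essentially equally well
(the richer models cannot beat the noise floor), so the information
criterion charges their extra formation constant and absorptivity spectrum
and the 1:1 model wins — the same conclusion the residual-distribution
analysis supports.  The selected fit's constant is
`report.best.kc` ≈ 6160 M⁻¹ (log β = 3.790 ± 0.005) against a generating
value of 6025 M⁻¹.

The command line mirrors the library
(`cyclofit simulate phasesol`, `cyclofit phasesol`, `cyclofit titrate`,
`cyclofit deconv`, `cyclofit vanthoff`, `cyclofit dosy`, …); every run can
write a JSON report plus a provenance record.

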