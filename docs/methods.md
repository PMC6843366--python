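# Methods

This note records the models behind each analysis, the conventions and
numerical choices the implementation commits to, what the synthetic-data
generators emulate, and the limits of what the test suite demonstrates.

## Phase solubility (Higuchi–Connors)

For a soluble 1:1 complex the dissolved guest follows the linear A_L
isotherm S(c) = S₀ + c·K_c S₀/(1 + K_c S₀), where S₀ is the guest's
intrinsic solubility and c the total host concentration.  The model is an
ordinary least-squares line; a diagram is classified **A_L** when
r² ≥ 0.99 (configurable) and 0 < slope < 1, and the constant is

    K_c = slope / (S₀ (1 − slope))        [M⁻¹]

The standard Higuchi–Connors parenthesization is used; the 1:1 formula is
invalid at slope ≥ 1, which the code rejects.  A user-supplied measured S₀
is preferred over the fitted intercept, since intercept estimates inherit
the full regression uncertainty of a quantity that is usually measured
directly.  The standard error of K_c comes from the slope SE by the delta
method, dK_c/dslope = 1/(S₀(1 − slope)²).  ΔG = −R_gas·T·ln K_c with
R_gas = 8.31446 J·mol⁻¹·K⁻¹ and 1 kcal = 4184 J (1 M standard state
implicit, the universal convention for cyclodextrin binding constants).

## Speciation and global titration fitting

A binding model is a set of complexes HₕG_g with cumulative constants
β_hg = [HₕG_g]/([H]ʰ[G]ᵍ), parameterized as log₁₀ β for positivity and
scale invariance.  The two mass balances are solved by Newton iteration in
(ln[H], ln[G]) with an analytic Jacobian, step capping and residual-
decreasing damping; convergence is declared at a relative mass-balance
residual ≤ 1e-12 (asserted property: agreement with the 1:1 closed-form
quadratic to 1e-9 relative over K ∈ [1, 10⁸]).  Zero totals are handled by
dimension reduction rather than by large negative logs.

The multiwavelength fit uses **variable projection**: the outer bounded
least-squares search runs only over the log β values (multistart, default
7 starts drawn from [1, 6], first start at the centre, seeded); at each
trial the per-wavelength molar absorptivities are recovered by non-negative
least squares, which keeps them physical and removes them from the
nonlinear search.  Standard errors of log β come from the Gauss–Newton
curvature of the projected problem with σ² estimated from the residuals
(degrees of freedom: all linear and nonlinear parameters counted).  A fit
is flagged *degenerate* (SE withheld) when the projected curvature is flat
or numerically singular — e.g. an all-zero absorbance matrix.

**Residual-trend analysis.**  Model adequacy is judged per wavelength by a
Wald–Wolfowitz runs test on the residual signs ordered by titration point
(exact zeros count as positive), one-sided against *too few* runs — the
signature of a smooth systematic misfit; alternating signs are over-
dispersed, not trendy, and are never flagged.  The normal approximation is
used without continuity correction: with only seven or eight titration
points the test is already conservative, and the correction would remove
all its power.  The overall verdict is "systematic" when the fraction of
wavelengths rejecting at α exceeds α.  Guest-only reference rows
(h_tot = 0) are excluded from the ordering in fitted results: they pin the
free-guest spectrum and dilute the trend signal.  One honest limitation,
found empirically: because the projected residual is orthogonal to the
species-concentration subspace, a *single* wrong complex (e.g. a lone 1:2
species fitted to 1:1 data) can reproduce the isotherm to near the noise
floor and is caught by its residual-sum and information-criterion penalty
rather than by the runs tests.

**Model selection** fits every candidate and ranks by (no systematic
trend) first, then AICc computed on Gaussian residuals with the full
parameter count, which charges the extra formation constant and extra
absorptivity spectrum of two-complex models.

## O–H band deconvolution

The O–H stretching envelope (3800–3000 cm⁻¹) of a cyclodextrin complex is
modelled as six Voigt sub-bands — from high to low wavenumber: intracavity
water (~3525), primary host OH (~3439), interstitial water (~3360), guest
OH (~3277), secondary host OH (~3191), strongly bound water (~3084 cm⁻¹) —
plus a linear baseline.  Each sub-band is the exact Gaussian⊗Lorentzian
convolution (Faddeeva function), area-parameterized, with independent
Gaussian σ and Lorentzian γ widths, both free.  Candidate centers are
seeded from the minima of the Savitzky–Golay second derivative
(polynomial order 3; a component produces a d² minimum at its center even
when it is only a shoulder in the raw trace) and bounded to ±40 cm⁻¹
during the fit, which keeps the physical band assignment stable while
leaving all parameters free within the window.

Numerics: the trace is normalized to unit maximum before fitting and the
areas rescaled afterwards, making the fit exactly equivariant under
intensity scaling; the trust-region solver uses the analytic Voigt
Jacobian; after the first convergence the solver is restarted from a
perturbed copy of the best solution (fixed internal seed) until R²
improves by less than 1e-6 or `max_rounds` is reached, which escapes the
shallow local minima that heavily overlapped envelopes produce.  R² is
computed over the full fit window.  The overlapping C–H stretching doublet
(~2922/2848 cm⁻¹) is handled by fitting two Voigts plus a baseline inside
2700–3000 cm⁻¹ and subtracting their modelled profiles (tails included)
from the whole trace, clipping at zero; a window whose maximum is below 3×
the noise MAD is treated as signal-free and left untouched.

## Two-state van 't Hoff analysis

Sub-bands 1–2 form the free (non/weakly H-bonded) class, sub-bands 3–6 the
H-bonded class; R(T) = (I₁+I₂)/(I₃+I₄+I₅+I₆).  The fit is OLS of ln R on
1/T.  Sign convention: breaking hydrogen bonds costs enthalpy and the free
population grows with temperature, so the slope against 1/T is negative
and ΔH_HB is reported as the positive magnitude |slope|·R_gas (the H-bond
rupture enthalpy); ΔS_HB = intercept·R_gas with its fitted sign.  SEs are
the regression SEs scaled by R_gas.

The isosbestic check area-normalizes every spectrum (the comparison is per
absorber), then finds the axis point of minimal across-temperature SD
*within the signal region* (mean intensity ≥ 5% of its maximum — outside
the bands the SD is trivially zero and the baseline would always win).
The point is accepted when that minimum is below 5% of the median SD; a
series of numerically identical spectra is reported as degenerate, not as
isosbestic.

## DOSY and chemical shifts

Under fast exchange the observed guest diffusion coefficient is the
population-weighted average D_obs = (1−f)·D_free + f·D_complex, so
f = (D_free − D_obs)/(D_free − D_complex); noise can push D_obs slightly
past either limit, in which case f is clipped into [0, 1] with a warning.
D_complex is approximated by the measured host/complex diffusion.  The 1:1
inversion K_c = b/((g_tot−b)(h_tot−b)) with b = f·g_tot is an extension
beyond the usual qualitative DOSY comparison and requires f·g_tot < h_tot.
Chemical-shift displacement tables are Δδ = δ_complex − δ_free per proton,
with a "downfield" summary flag when all Δδ > 0.

## Assay arithmetic

Viability = 100·AbsT/AbsC; LDH release = 100·released/total (values above
100% flagged).  Franz-cell sampling with replacement dilutes later
samples, so Qₙ = Cₙ·V_receptor + Σ_{i<n} Cᵢ·V_sample; the withdrawn-aliquot
volume is a parameter (default 0.5 mL against the 4.5 mL receptor).
Mucosal accumulation = 100·recovered/dose, optionally corrected by an
extraction recovery factor (e.g. 0.97).  HPLC calibration is an OLS line
over ≥ 5 levels with LOD = 3·noise_sd/slope and LOQ = 10·noise_sd/slope —
the pharmacopoeial S/N = 3 and 10 convention (LOQ/LOD ≡ 10/3).

## Synthetic data: what it emulates, and what it does not

Every generator is a deterministic function of (parameters, seed), and each
one's noiseless output, pushed through its analysis stage, returns the
generating parameters to numerical precision — the package's master
round-trip suite.

* Phase solubility: the A_L law at K_c = 6031 M⁻¹, S₀ = 2×10⁻⁵ M on a
  0–9 mM host grid, multiplicative Gaussian noise (default CV 2%,
  heteroscedastic like an HPLC readout).
* Titration: 1:1 binding at log β = log₁₀ 6025 ≈ 3.780, guest total
  4.43×10⁻⁵ M, the seven protocol host levels plus a guest-only reference
  row, Gaussian-mixture absorptivity shapes for the free (π→π* band near
  280 nm) and bound (red-shifted, hyperchromic) guest over 200–400 nm in
  2 nm steps, additive detector noise (default SD 0.002 AU).
* O–H series: ten temperatures over 250–340 K on a 2 cm⁻¹ grid; class
  weights w(T) = R/(1+R) with ΔH_HB = 10596 J/mol and ΔS_HB = 30 J/mol/K
  (chosen so R ≈ 0.5 mid-range); fixed within-class proportions, total
  area 1, multiplicative noise (default 1%).  Sub-band widths (σ ≈ 26–33,
  γ ≈ 6–8 cm⁻¹) are set so the six components are resolvable in the second
  derivative, the documented qualitative feature of the experimental
  envelope.  Because within-class proportions are fixed and the weights
  sum to one, the series has an exact isosbestic point by construction.
* Diffusion: speciate, average D under fast exchange (defaults
  D_free = 2.69×10⁻¹⁰, D_complex = 1.30×10⁻¹⁰ m²/s at 14 mM totals).

Real spectra additionally carry correlated baselines, atmospheric bands,
ATR penetration-depth effects and drifting within-class proportions; real
titrations carry wavelength-correlated noise and activity effects.  None
of these are simulated, so passing tests demonstrate the correctness and
statistical calibration of the estimators under their stated models — not
robustness to instrument systematics.

## Problem sizes and reproduction

`scripts/acceptance.py --seed N --out file.json` regenerates the headline
quantities: 100 phase-solubility isotherms (mean K_c and the maximum
fitted slope), 25 titrations fitted 1:1 (median K_c), and 50 ten-
temperature O–H series pushed through the full deconvolution pipeline
(mean ΔH_HB).  These replicate counts give Monte-Carlo SEs of ~0.2%, ~0.2%
and ~1% respectively while keeping the whole script at a few minutes on a
single CPU; all randomness derives from `--seed`.

## Known limitations

* Six-component deconvolution of a heavily overlapped envelope is close to
  ill-posed: with 1% noise individual percent areas can trade several
  points between neighbouring bands even at R² ≥ 0.999.  The van 't Hoff
  slope averages this noise over ten temperatures and 50 replicates; a
  single noisy spectrum's R should not be over-interpreted.
* The runs-test aggregate has little power against single-complex
  misspecifications (see above); use it together with the information
  criterion, as the selection routine does.
* Only 1:1 diagrams are quantified in phase solubility (A_P/A_N/B-type
  curves are classified "nonlinear" and left unfitted), and the nonlinear
  (ΔCp ≠ 0) van 't Hoff model is out of scope.
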