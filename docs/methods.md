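# Methods

## Scope and data model

The package analyses equilibrium (thermodynamic) solubility of a single
solid solute. All solubilities are mole fractions; all temperatures are
kelvin (no Celsius input anywhere); masses are grams with no unit
inference. The gas constant is fixed at R = 8.314 J·mol⁻¹·K⁻¹ and is not
configurable.

Gravimetric records convert to mole fractions as
`x = (mA/MA) / (mA/MA + m1/M1 + m2/M2)`. The binary-solvent composition
index `w₂ = m₂/(m₁+m₂)` is a solute-free **mass** ratio; parts of the
cosolvency literature label this same quantity a mole fraction, and the
package keeps the arithmetic while treating `w₂` as an abstract
composition fraction. Whether a published `w₂` grid is mass- or mole-based
therefore does not affect any computation here, only the label.

## Solubility models and fitting objective

All five models are standard. The fitting objective is a genuinely open
choice, since sources rarely state theirs: by default every fit minimises
residuals in **ln x**. Three reasons: (i) the Apelblat, van't Hoff and
Jouyban–Acree van't Hoff models are *linear* in their parameters on that
scale, so the least-squares problem has an exact SVD solution with no
iteration or starting-point sensitivity; (ii) solubility spans orders of
magnitude across solvents and compositions, and multiplicative measurement
error is homoscedastic in ln x; (iii) the λh model's residual is naturally
log-scaled. The nonlinear fitters accept `objective="linear"` to minimise
residuals in x instead (Levenberg–Marquardt, warm-started from the
log-scale solution). Fit quality (MRD %, RMSD) is always reported on the
linear x scale, whatever the objective.

MRD is implemented exactly as the signed form
`100/N · Σ (x_exp − x_cal)/x_exp`, in which deviations of opposite sign
cancel; because published comparison tables are plausibly the
absolute-value variant, `mrd_abs` is provided alongside and is what the
report tables carry.

### Apelblat

`ln x = A + B/T + C ln T` is linear in (A, B, C), so the "nonlinear
regression" of common usage is solved in closed form. Over a narrow window
(298–318 K) the regressors 1, 1/T and ln T are nearly collinear; the SVD
solve keeps noiseless-data parameter recovery at ~1e-11 relative where
normal equations would lose several more digits. Consequences of that
collinearity, not of the solver: parameter *values* are exquisitely
sensitive to data noise even when the fitted *curve* is stable, which is
why recovery tests on noisy data assert on predictions, not parameters.

### Buchowski–Ksiazaczak λh

The implicit relation `ln(1 + λ(1−x)/x) = λh(1/T − 1/Tm)` inverts exactly:

    x = λ / (expm1(u) + λ),  u = λh(1/T − 1/Tm),

which satisfies the defining identity to rounding error and gives x = 1 at
T = Tm. The fit optimises (ln λ, h) — log-scaling keeps λ positive and
well-conditioned across the ~6 orders of magnitude it spans between
aqueous and organic systems — with ln λ bounded in [−60, 6], residuals
evaluated in log space with a large-`u` branch (`u + log1p((λ−1)e^{−u})`)
to avoid overflow at λh ~ 10⁷–10⁸ (aqueous systems), and three warm starts
(λ₀ = 10⁻³ from the small-λ heuristic h₀ = −b/λ₀, plus 0.1 and 1).
Recovery on noiseless data from all eleven bundled parameter sets is at
machine precision. The small-λ consistency λh ≈ −b (van't Hoff slope)
holds only when exp(−b(1/T − 1/Tm)) ≫ 1; for shallow slopes
(|b| ≲ 3000 K) the correction terms contribute at the 10% level.

### Jouyban–Acree van't Hoff

Seven regressors — `w₁, w₁/T, w₂, w₂/T, w₁w₂/T, w₁w₂(w₁−w₂)/T,
w₁w₂(w₁−w₂)²/T` — fitted by exact linear least squares with a rank check.
The three interaction coefficients are stored as J0, J1, J2, matching the
summation index of the underlying Jouyban–Acree form. The
`α₁, α₂` / `α₃, α₄` pairs are the pure-solvent van't Hoff parameters of the
w₂ = 0 and w₂ = 1 endpoints; with all Jᵢ = 0 the model degenerates to the
two pure-solvent lines, which is tested.

### Anti-solvent design rule

Precipitation by anti-solvent quench needs maximal supersaturation, i.e.
minimal equilibrium solubility at the mixing composition, subject to a cap
on the solvent-to-anti-solvent ratio (the conventional cap is w₂ < 0.2;
it is a parameter). The selector evaluates the fitted mixture surface on a
composition grid (default step 0.1, overridable, or an explicit grid),
restricts to the feasible set and returns the argmin, breaking ties toward
smaller w₂ (less solvent to remove downstream).

## Thermodynamics

Ideal solubility uses the fusion expression with `(Tfus − T)` in the first
numerator — the only form for which ln x_idl vanishes at T = Tfus — and
`ΔCp = ΔHfus/Tfus`. Values are clipped at 1 against rounding; T > Tfus is
an error rather than an extrapolation.

The apparent quantities come from OLS of ln x on `(1/T − 1/Thm)`. Centring
at the mean harmonic temperature makes the intercept a ΔG° estimate at a
single reference temperature. `Thm` defaults to the computed harmonic mean
(307.99 K for the five-point 298.15–318.15 K grid) but is overridable —
reference tables for the ABN401 system round it to 308.15 K, and passing
that value reproduces them. ΔS° is derived as (ΔH° − ΔG°)/Thm, so the
Gibbs–Helmholtz identity holds to machine precision by construction;
tests assert it as an internal-consistency check, not as physics.

Activity coefficients are the plain ratio γ = x_idl/x_e. A subtlety worth
recording: the *sign* of dγ/dT is a competition between the
ideal-solubility temperature sensitivity (an effective van't Hoff slope of
about −1900 K for the ABN401 fusion constants over the study window) and
the solution's slope b. Solvents with |b| below that threshold (for
ABN401: ethyl acetate, acetonitrile, 1-butanol) show γ *increasing* with
temperature; the steep-slope solvents show the familiar decrease. The
property test asserts exactly this conditional statement.

Enthalpy–entropy compensation is OLS of ΔH° on ΔG° across compositions;
the slope's sign is the interpretive output (positive ⇒ co-variation of
enthalpy with free energy, solvation-driven compensation). For the bundled
Transcutol HP–water per-composition parameters the slope is ≈ +0.19.

## KAT-LSER

OLS (via statsmodels, which supplies coefficient standard errors, R², F
and RSS) of ln x on `[1, α, β, π*, Vs·δH²/(100RT)]`, requiring n ≥ 6 and a
full-rank design. On an exact fit the F statistic is reported as the +inf
sentinel rather than statsmodels' overflow. Percentage contributions use
`|cᵢ|·mean(|regressorᵢ|)` normalised to 100% over the four non-intercept
terms — the usual effect-share convention; published percentage splits
computed by other conventions will not reproduce exactly. The bundled
descriptor CSV carries literature-typical Kamlet–Taft/Hildebrand values
for ten common pharmaceutical solvents (Transcutol HP has no reliable
published descriptors and is excluded); it is an editable data file, not
code. Vs defaults to 26.5, the Fedors-method value reported for ABN401 —
reported in a solubility-parameter unit, so its magnitude should be read
as a dataset convention; supply your own Vs for other solutes (Fedors
group-contribution computation is out of scope).

## Synthetic data

The generator emulates a static-equilibrium study: a 5-point temperature
grid (298.15–318.15 K, 5 K steps) and an 11-point composition grid
(w₂ = 0…1) by default, triplicate replicates averaged arithmetically on
the linear x scale. Noise is multiplicative log-normal,
ε ~ N(0, ln(1+cv²)) on ln x, giving each draw the requested coefficient of
variation; additive noise would be unphysical at the 10⁻⁶ solubility end.
The default cv = 0.03 is a realistic relative uncertainty for
HPLC-assayed equilibrium solubilities, not a measured value. Draws above
x = 1 are rejected and resampled (bounded retries). Seeding is explicit
and mandatory in CLI use; identical specs are bit-reproducible.

What the generator does *not* emulate: assay calibration error, dilution
and filtration losses, temperature-equilibration drift, or any
between-replicate correlation. Passing recovery tests therefore
demonstrate the estimators are correct under the assumed error model, not
that real laboratory data satisfy that model.

## Problem sizes and numerical tolerances

Tests and examples use the study-scale problems the package is designed
for: 5-temperature series, 11×5 mixture grids, 10-solvent descriptor
panels; stochastic recovery checks use 100 seeded replicates of the 11×5
grid at cv = 0.03, and the log-normal moment check uses 10⁴ single-draw
replicates. Noiseless recovery is asserted at 1e-8 relative for the
linear-algebra fits and 1e-4 for the iteratively fitted models; the λh
inversion identity is checked to 1e-10 over 1000 random parameter draws
(λ ∈ [10⁻⁴, 10^0.5], λh ∈ [10², 10⁴], Tm ∈ [350, 500] K).

## Known limitations

- Single solute, single or binary solvent; no ternary solvent systems.
- No alternative cosolvency models (extended Hildebrand, NRTL, UNIQUAC,
  Wilson) and no preferential-solvation (IKBI/QLQC) analysis.
- Heat capacity is fixed at ΔCp = ΔHfus/Tfus; no ΔCp = 0 or calorimetric
  variants.
- The bundled reference parameter sets are literature fit results, not raw
  data; where two published tables disagree for the same system (the pure
  Transcutol HP van't Hoff parameters differ slightly between the
  pure-solvent and mixture tables) both are kept as-is under their own
  accessors, without reconciliation.
- MRD's signed form can report near-zero for a badly biased fit whose
  deviations cancel; comparisons should use the absolute variant, as the
  report tables do.
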