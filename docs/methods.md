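# Methods

## Trait construction

Breath sniffers installed in milking stations measure CH4 and CO2
concentrations (ppm), not emission rates. The scaling to g/d uses the
animal's metabolic heat as a CO2 tracer: heat production in watts is
predicted as `5.6·BW^0.75 + 22·ECM + 1.6e-5·days_pregnant³`, converted to
heat-producing units at 1 HPU = 1000 W. One HPU corresponds to 180 L CO2
per hour, so daily CH4 volume is `(CH4/CO2)·180·24·HPU` litres, converted
to mass with the CH4 density at 20 °C (0.668 g/L). The printed heat
equation returns watts while the volume equation expects HPU; the /1000
conversion is applied explicitly — without it MeP lands three orders of
magnitude above the observed ~338 g/d mean.

MeC is `100·ln(ppm)` of the weekly mean concentration (the log corrects
right skew; ×100 matches the scale of the other traits). Whether to average
before or after the log is not determined by the trait definition; this
package logs the weekly mean. ΔBW, needed for RFI2, is the centered first
difference of weekly body weight per cow, `(BW_{t+1} − BW_{t−1})/2`, with
forward/backward differences at the series ends.

Residual traits follow the two-step approach: one OLS fit of the trait on
the model's fixed effects (experiment-year-season, lactation week, parity,
age-at-calving covariate) plus the trait-specific covariates (ECM and MBW;
plus ΔBW for RFI2), with the residuals then analysed under a mean-only
animal model. By construction the residuals are exactly orthogonal to the
covariates on the fitting sample. A footnote-style alternative definition of
RMeP that also adjusts for DMI exists; this package uses the ECM + MBW
definition throughout. RMeC keeps MeC's transformed units (log ppm × 100)
even though data tables sometimes label it g/d.

Editing filters: a weekly gas average is kept only if at most 3 of its 7
days are missing (`n_days_observed ≥ 4`); a cow is kept only with at least
3 surviving weeks. Counts removed at each step are reported and recorded in
the run manifest. Missing values are flagged (NaN), never imputed; a
cow-week missing an input is missing only for the traits that need it.

## Pedigree relationships

The numerator relationship matrix A is built by the tabular method
(`a_ii = 1 + 0.5·a_{sd}`, `a_ij = 0.5(a_{j,s} + a_{j,d})`), and its sparse
inverse directly by Henderson's rules with inbreeding, using Mendelian
sampling variances `d_i` from the parents' inbreeding coefficients; since
`A = TDT'`, `log|A| = Σ log d_i` falls out for free and is used in the REML
likelihood. Unknown parents are treated as unrelated base individuals (no
genetic groups). Pruning retains the phenotyped animals and their full
ancestor closure. A gene-dropping Monte-Carlo estimator of A (explicit
identity-by-descent sampling) serves as an independent oracle in tests.

## REML

All likelihood evaluations go through the mixed-model equations with the
residual-scaled coefficient matrix `M = D'R⁻¹D + blockdiag(0, G⁻¹⊗A⁻¹,
PE⁻¹⊗I)`, giving `−2ℓ = log|R| + q_a·log|G| + T·log|A| + q_pe·log|PE| +
log|M| + y'Py + const` via one Cholesky factorization per evaluation.
Gradients use the standard MME-inverse trace identities; the
average-information matrix is `0.5·F'PF` with one extra multi-RHS solve,
where the columns of F are `∂V/∂θ_k · Py`. Bivariate fits stack the two
traits with records missing per trait; the residual covariance acts on
cow-weeks where both traits are observed (cross-products per observation
pattern are precomputed once, so each iteration stays a single
factorization plus solves).

Numerical choices:

- **Updates.** AI step on a working scale (variances log, covariances
  natural), candidate blocks bent to the PSD cone by eigenvalue clipping;
  if the step does not improve the restricted log-likelihood it is halved
  up to 12 times, then an exact EM step is tried. Pure EM is available
  (`method="em"`) and is monotone in the likelihood, which the tests
  assert per iteration.
- **Convergence.** Relative log-likelihood change < 1e-8 **and** maximum
  relative parameter change < 1e-6, at most 200 iterations.
  Non-convergence is flagged on the result, never silent.
- **Starting values.** Univariate: the OLS residual variance split equally
  three ways. Bivariate: univariate fits per trait, covariances at half the
  geometric mean of the variances.
- **Boundaries.** Variances are floored at 1e-10 of the starting scale, so
  a zero genetic variance is estimated as a pin at the floor (h² ≈ 0).
  Optima on the PSD boundary (e.g. a permanent-environment correlation
  driven to ±1 on weakly identified data) are reached via bending; their
  gradients need not vanish.
- **Standard errors.** Inverse AI matrix at the optimum; ratio (h², pe²,
  repeatability) and correlation SEs by the first-order delta method.
- **Permanent environment** is one effect per cow across parities — the
  simplest reading consistent with a single pe variance per trait.
- **Phenotypic correlations** are computed from the summed (co)variance
  components, not from raw data.

With unrelated animals (A = I) the additive and permanent-environment
variances are confounded; only their sum is identified. The balanced-design
test therefore checks the identified quantities — the cow-level sum against
the one-way ANOVA between-cow component `(MSB − MSW)/n` and the residual
against MSW.

## Synthetic herd generator

The generator defines the study conditions: ~600 phenotyped cows with
20–50 (default 30) weekly records each, in full-sib families nested in a
random-mating pedigree (founders → one offspring generation by default;
deeper pedigrees configurable). It simulates the repeatability model
forward for four base traits — ECM, MBW, DMI, MeP — with breeding values
drawn from `A ⊗ G`, one permanent-environment draw per cow (PE) and
independent weekly residuals (E). Default G/PE/E diagonals are the
reference Danish Holstein estimates (e.g. MeP 1160.6 / 1456.8 / 2923.9,
ECM 26.9 / 9.1 / 21.1, MBW 34.7 / 26.1 / 11.7); MeP–ECM (0.79) and MeP–MBW
(0.32) genetic correlations likewise. DMI components (h² ≈ 0.30 at
phenotypic SD 2.5 kg) and the remaining correlations were never published
for that herd and are plausible one-time fill-ins, marked as such in the
source.

Fixed effects default to 12 experiment-year-season classes (a long-running
research herd would have ~10× more; configurable), a smooth lactation-curve
shape over weeks 1–44, three parity classes and a linear age-at-calving
slope. Raw streams are back-constructed so the trait pipeline reproduces
the intended values exactly: milk/fat/protein in fixed proportions
(4 % fat, 3.4 % protein) yielding the intended ECM; BW = MBW^(4/3); CO2
fixed at a 5000 ppm baseline with CH4 ppm solved from the intended MeP
through the HPU pipeline; pregnancy from lactation week 10. MeC is **not**
independently controlled — it emerges from the back-constructed CH4 stream,
as it would from a real sniffer. Intended trait values are floored at a
small positive value (a < 1e-5 tail event at the defaults, counted in the
output) to keep raw streams physical.

What the generator does not emulate: sensor noise and calibration drift,
ambient CO2 background, diurnal and diet effects, realistic lactation-curve
biology, culling and missingness patterns, selection over generations.
Passing recovery tests therefore demonstrate correctness of the estimation
machinery under the stated model, not robustness to the measurement
pathologies of real sniffer data.

## Selection index and impact

Response per generation for weight vector `a`: `i·√r²·(Ga)ⱼ/√(a'Ga)`,
with reliability r² = 0.81 and intensity i = 1 by default (one index-SD of
selection differential as the reporting unit; both configurable). This
formulation reproduces all four published ECM-only (SC0) responses from the
published inputs, which is how it was selected among index conventions; the
single-trait closed form `i·√r²·σ_A` and the correlated-response form
`i·√r²·r_g·σ_A` are exact special cases. RFI enters scenarios as RFI1.
Scenario weights: SC0 ECM 0.6; SC1 adds RFI −0.2; SC2A/B add the methane
trait at −0.005 / −0.017 €/(g/d) (for MeI: −0.0083 / −0.0283 per g/kg ECM).

Three genetic correlations the scenarios need (ECM–RFI, ECM–MBW, RFI–MBW)
have no published estimate; parameter sets must supply every needed pair
explicitly and validation fails pre-flight naming missing pairs. The
bundled demonstration set back-solves ECM–RFI (0.49) and ECM–MBW (0.01)
from the published ECM-only responses and sets RFI–MBW to a plausible 0.33;
it is labelled a demonstration, not an estimate, and the later-scenario
responses computed from it are accordingly demonstrations.

The impact cascade is a chain of single multiplications — delta (g/d) ×
305 lactation days / 1000 → kg per cow-year; × 550,000 cows / 1000 → t/yr;
× GWP (25 or 84) / 1000 → kt CO2e; × price → M€ — and is therefore exactly
linear in the delta. The carbon price supports the exact 1500/7.45 ≈
€201.3/t and the rounded €200/t modes; the rounded mode is the default and
reproduces the printed 3.5–11.7 M€ range. Rounding happens only at
presentation; internal values keep full precision.

## Problem sizes

Test and demonstration runs use the sizes the estimators are designed for:
the study-scale recovery check runs 20 replicates of 600 cows × 30 weeks
(≈ 18,000 records, ~960-animal pedigree; a univariate fit takes a few
seconds on one core); unit-level checks use 40–250 cows. Bivariate
recovery runs 20 replicates at 200 cows × 8 weeks, which already gives
r_g SEs ≈ 0.1–0.2 at the simulated parameters.

## Known limitations

- Multi-trait (> 2) joint fits, random-regression/test-day models and
  genomic evaluation are out of scope.
- SEs are asymptotic (inverse AI + delta method) and unreliable for
  parameters pinned at a boundary.
- The two-step residual traits ignore the uncertainty of the first-step
  regression; this mirrors field practice.
- Correlations with health and conformation traits are taken as zero in
  the scenario machinery (as in the source analysis), so aggregate-merit
  consequences beyond the modelled traits are not captured.
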