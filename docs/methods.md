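# Methods

## Rate estimation from scintillation counts

The estimator treats a microcosm assay as a zero-order conversion of a
labeled substrate pool: the rate is the fraction of added radioactivity
recovered (treatment minus killed control), scaled to the total substrate
pool, and normalized by assay duration and by mat carbon as the biomass
proxy. Zero-order kinetics is appropriate because the fraction of the pool
converted in a ~60-minute assay is tiny (of order 1% of the tracer, far
less of the total pool); no first-order depletion ("bottle effect") and no
¹⁴C decay correction over an hour are modeled. The isotopic discrimination
factor α (default 1.05) corrects for slower biological uptake of ¹⁴C
relative to ¹²C; it is applied identically to assimilation and
dissimilation, since both run through the same conversion arithmetic.

Counts per minute become disintegrations per minute by background
subtraction (clipped at zero — gross counts cannot be negative) and
division by the counting efficiency, interpolated piecewise-linearly on a
monotone quench curve with the quench indicator clipped to the calibrated
range. For dissimilation, the sampled fraction F_s is the syringe volume
over (residual headspace + syringe volume), with the bottle volume obtained
gravimetrically; the default geometry (26.3 mL bottle, 11.3 mL contents,
5 mL syringe) gives F_s = 0.25.

**Uncertainty.** Every factor carries a value ± sd and is propagated to
first order assuming independence; the rate is a pure product/quotient of a
difference, so the propagation is analytic. The dominant term is replicate
scatter: treatment and killed DPM enter as replicate means with the sd of
the mean. Because triplicates leave only two degrees of freedom, the sample
sd is corrected for its small-sample bias (E[s] = c₄σ, c₄(3) ≈ 0.886)
before use; without this the propagated errors are systematically
anti-conservative, which the synthetic-recovery calibration makes visible.
A negative net DPM (killed exceeding treatment) is reported as a negative
rate flagged "not distinguishable from zero" rather than clipped, so
light-minus-dark differences stay unbiased. Distinguishability from zero
uses a one-sided normal criterion at 95%.

**Treatment contrast.** Light vs dark is compared with a one-sided Welch
t-test at α = 0.05 on per-vial replicate rates — robust to unequal
variances between foil-wrapped and exposed vials. Degenerate zero-variance
groups are handled explicitly (equal constant groups give p = 0.5). With a
single replicate per treatment, rates are still computed but significance
is reported as unavailable.

## Aqueous speciation and charge balance

The speciation model is deliberately minimal: monoprotic acid/base couples
(acetate 4.756, formate 3.745, bisulfate 1.99, ammonium 9.25, HF 3.17 at
25 °C; all overridable), the diprotic carbonate system, and water. Ion-pair
complexes (CaSO₄⁰, MgSO₄⁰, FeSO₄⁰, …) and redox speciation are omitted.
At the ionic strengths of these waters (I < 0.02 mol/kg) their neglect
shifts charge imbalances by a few percent and calculated pH by ~0.05 units,
which is the accuracy band this package claims — full equation-of-state
speciation codes are the right tool when more is needed. Molarity is
treated as molality (no density correction) at these dilutions.

Temperature corrections: monoprotic couples use van 't Hoff with a fixed
reaction-enthalpy proxy per couple; the carbonate system uses the empirical
freshwater polynomials of Harned & Davis (pK₁) and Harned & Scholes (pK₂),
valid 0–50 °C (pK₁ = 6.35 at 25 °C, 6.44 at 12.6 °C, 6.31 at 35 °C), and
the water ion product uses the Harned & Owen fit. Activity coefficients
follow the extended Debye–Hückel equation with A and B interpolated from
standard 0–60 °C tabulations and Kielland ion-size parameters (default
4.0 Å for species without a tabulated size). pH is −log₁₀ of the H⁺
*activity*; the H⁺ concentration entering ionic strength and charge balance
is activity/γ(H⁺).

**Iteration.** Species distribution and activity coefficients are coupled
through ionic strength, so the solver fixed-point iterates (speciate at
current γ → recompute I → update γ) to a relative tolerance of 10⁻¹⁰ on I,
max 100 iterations; convergence takes ~5 iterations for these waters. Mass
balance is exact by construction (species are fractions of each measured
total); a brute-force simultaneous root-find of the coupled mass-action
equations is kept in the test suite as an independent cross-check.

**Charge balance.** Imbalance is percent of the mean charge:
100·(Σ cation eq − Σ anion eq)/(½(Σ cation eq + Σ anion eq)). The
charge-balance pH is found by Brent's method on pH ∈ [0, 12] with full
re-speciation per trial (the imbalance is strictly decreasing in pH);
the round-trip residual is below 10⁻⁴ %. A composition that cannot balance
within the bracket raises an error reporting both endpoint imbalances.

## Isotope and elemental budgets

Δ¹³C is defined as the plain delta difference δ¹³C(mat) − δ¹³C(DIC) — the
convention used in field data tables — rather than the exact fractionation
ε = 1000(α − 1); at these magnitudes the two differ by ~0.1‰. Errors add
in quadrature. The molar C:N ratio is (wt%C/12.011)/(wt%N/14.007) with
relative errors in quadrature. δ¹⁵N is carried through unchanged. Values
are stored at full precision; presentation rounds the error to its leading
significant figure and the value to match.

## The synthetic experiment generator

The generator inverts the rate equation: a chosen true rate implies an
expected net DPM on each vial's filter, to which killed-control adsorption
is added; killed vials get adsorption only. Gross counts are Poisson over
the counting time with mean (DPM·efficiency + background)·t_count — the
physical noise model for scintillation counting — and vial-to-vial
biological variability is a mean-one log-normal multiplier on the true
rate. All randomness flows from one seed.

Defaults emulate the package's worked-example DIC assay: triplicate
light/dark/killed vials, 10 mL spring water + 1 mL slurry + 0.2 mL spike
(+0.1 mL DCMU), a 5.3 µCi bicarbonate spike at 54 mCi/mmol into an 11 mM
DIC pool (spike <0.1% of the pool), 0.020 ± 0.001 g dry mat of
9.11 ± 0.07 wt% C, a 1-hour incubation, F_s = 1. Instrument defaults —
10-minute counts at 90% efficiency over a 30 CPM background, 500 DPM
killed-control adsorption, 15% biological CV, 3% DIC and 1% spike-activity
uncertainties — are realistic ballpark values for this assay class, stated
here because raw field counting data of this kind are rarely published.

What the generator does *not* emulate: isotopic exchange with headspace
CO₂, time-resolved kinetics, substrate depletion, quench variation between
vials, or correlated replicate failures. Passing recovery tests therefore
demonstrates that the estimator and its error model are self-consistent
under the declared noise model, not that any particular field dataset is
error-free.

**Calibration check.** Over 100 seeded simulations of the triplicate
design, the mean recovered light-minus-dark rate falls within 5% of truth,
≥95% of per-seed estimates fall within truth ± 2× their propagated error,
and the empirical scatter is consistent with the mean propagated error
(ratio within [0.7, 1.4]; the propagated error is slightly conservative
because it includes systematic terms — substrate pool, dry mass, spike
activity — that do not vary between simulated assays). The dissimilation
variant (F_s = 0.25, ~10⁴ net DPM) recovers truth with <2% bias.

## Numerical and design notes

- Problem sizes: the recovery suites use 100 simulated assays of 9 vials;
  Monte-Carlo propagation checks use 10⁵–2×10⁵ draws. The full test suite
  runs in a few seconds.
- The µCi→DPM constant is fixed at 2.22×10⁶ (definition of the curie).
- Bundled analyses for the four field sites (two Yellowstone springs, two
  reference waters) serve as worked-example inputs; they are measured
  totals, and all derived numbers in the README are recomputed from them at
  run time.
- Known limitations: no ion pairs or redox couples in speciation (do not
  expect sub-percent charge-imbalance agreement with full speciation
  codes); independence assumed in error propagation; the Welch test is the
  package's choice of contrast — field designs with n = 3 have little
  power, and the propagated-error flag is the more informative output.
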