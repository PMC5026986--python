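# Methods

## Isotope arithmetic and calibration

Delta notation is defined as δ = (R_sample/R_standard − 1) × 1000 ‰, with
R = ¹⁸O/¹⁶O against VSMOW and ¹⁵N/¹⁴N against atmospheric N₂.  All mixing
arithmetic is carried out in δ space, which is exact for the linear
two-pool mass balances used here; the absolute reference ratios are kept
only as configuration constants.  Internal-standard correction is an
ordinary-least-squares line of assigned-on-measured δ fitted through at
least two reference materials.  A per-run linear fit is the standard
practice for denitrifier-method data reduction and reduces to the identity
when the standards are unbiased; per-standard offset or two-point schemes
would be special cases of the same affine map.  Analytical precision
defaults to 0.59 ‰ (δ¹⁸O) and 0.19 ‰ (δ¹⁵N), one σ, overridable per
measurement; these values drive both the simulator's noise and the
envelope-clamping rule below.

## The mixing model

`nitrification_endmember` evaluates
δ_new = w·δ_water + (1−w)·δ_O2 at both bounds of the ambient-water range
(defaults: water ∈ [−10, −5] ‰, O₂ = +23.5 ‰, w = 2/3), giving an interval
end member.  `mixing_fraction` computes f = (δᵢ − δ_f)/(δᵢ − δ_new), the
fraction of the **final** pool that is new; `new_to_original_pct` maps it
to 100·f/(1−f), production as a percentage of the **original** pool.  Both
denominators are exposed under explicit names because conflating them is
the classic error in this calculation.

Numerical choices:

* **Envelope violations.** δ_f must lie between δ_new and δᵢ.  Analytical
  noise can push an observation slightly past a bound, so violations
  within 2 measurement SDs are clamped to the bound with a warning;
  larger violations raise an error that carries the offending value.
  Tolerate noise, refuse nonsense.
* **Interval propagation.** f is monotone in δ_new, so evaluating at the
  two end-member bounds and sorting brackets every pointwise result; a
  grid test asserts this.
* **Consistency tolerance.** The concentration cross-check is declared
  consistent when it falls within the isotopic interval widened by 2
  percentage points per side — enough to absorb printing precision of the
  inputs plus propagated analytical noise, small enough to flag genuinely
  disjoint estimates.
* **No δ¹⁵N end member is predicted.** The nitrogen isotope argument is a
  sign check only: `implied_new_delta15N` inverts the mass balance at a
  given f and the produced nitrate should come out lighter than the pool
  (ammonium in throughfall is generally < 0 ‰).  Rayleigh fractionation of
  the ammonium pool during consumption is deliberately out of scope; the
  attribution is a pure mixing calculation.
* **Rounding.** Reported ‰ and percentage values are printed to one
  decimal; all internal computation is unrounded.

## Nitrogen budget

Budgets are endpoint differences (final minus initial week), matching a
before/after incubation design; no rate constants are fitted.  Ammonium is
often measured at fewer weeks than the oxidized species, so its delta
falls back to the latest determined week and never blocks the nitrate and
nitrite deltas.  Oxidized-N production is ΔNO₃ + ΔNO₂, and the excess over
ammonium consumption (production − max(0, −ΔNH₄)) isolates the
contribution of mineralized organic N.  Classification cutoffs —
nitrifying iff ΔNO₃ ≥ 20 µM and ≥ 10 % of the initial nitrate pool,
nitrite-accumulating iff ΔNO₂ ≥ 5 µM without that, else inactive — are
configuration parameters; the defaults separate an actively nitrifying
sample, coarse-filter fractions that retain only ammonia oxidizers, a
weakly transforming sample, and inactive rainfall, while staying invariant
to uniform concentration scaling well above the absolute thresholds.
"Mineral nitrogen" includes nitrite.

## qPCR normalization

Copies per reaction scale to copies per filter through the fraction of the
DNA extract loaded per reaction (default 1.0, i.e. reported totals are
already per-filter), and to copies per mL through the filtered volume.
The limit of quantification (default 44 copies per reaction) is inclusive:
a mean exactly at the LOQ is quantifiable.  Censored records never expose
point values — only LOQ-equivalent upper bounds — and the pipeline output
preserves that.  SDs propagate by pure rescaling because replicate-level
data are not modelled.

## Synthetic incubations

The generator emulates a filter-treatment incubation: weekly sampling over
four weeks, treatments that switch guilds off (sterile 0.2/0.4 µm
fractions have zero oxidation rates in every template), first-order
transformations DON→NH₄ (k_min), NH₄→NO₂ (k_amo), NO₂→NO₃ (k_nob), and
NH₄→biomass (k_immob, tracked so total N is conserved and the unexplained
ammonium loss seen in sterile fractions is representable).  Each step's
newly produced nitrate carries a point end member (the sourcing rule at
the midpoint water value, +2.83 ‰; δ¹⁵N −17.3 ‰) and is mixed exactly, so
the noise-free pool equals the two-pool closed form and the truth record
is well defined for recovery tests; the interval enters only at analysis
time.  Noise is applied last: multiplicative Gaussian on concentrations
(CV 0.03, truncated at zero), additive Gaussian on δ values at the
analytical precisions.

The integrator uses trapezoidal (Heun) flux updates at 7 steps per week.
A plain forward-Euler step at this resolution leaves a visible
discretization error in the fast-decaying ammonium pool (≈0.8 % shift on
halving the step), whereas the second-order update is refinement-stable to
< 0.02 % at identical cost; conservation is exact either way because
updates are flux-based.  Outflow fluxes are capped at the pool size, a
guard that is inert at the default rates.

Default scenario parameters were chosen once to emulate the study
conditions: the active tree template starts at NH₄/NO₂/NO₃ =
174/11/219 µM with 150 µM DON and rates k_amo = 0.23, k_nob = 6,
k_min = 0.05, k_immob = 0.05 wk⁻¹, yielding ≈ +114 µM nitrate (52 % of the
original pool), δ¹⁸O falling 74.1 → 49.8 ‰ and δ¹⁵N 6.1 → −1.9 ‰; the
coarse-filter template zeroes k_nob so nitrite accumulates; the weak-tree
template reduces k_amo to 0.008 wk⁻¹; the rainfall template has no
microbial activity and 59 µM total mineral N.  qPCR synthesis is
qualitative only — an active ammonia-oxidation rate maps to a quantifiable
coarse-filter copy number and zero rates map below the LOQ — because no
quantitative copies-to-rate law is defensible from incubation data alone.

What the generator does **not** emulate: microbial growth (rates are
constant, not Monod), Rayleigh isotope fractionation of the ammonium pool,
within-treatment replication structure (replicates are independent
experiments), pH/temperature dependence, and any coupling between gene
copy numbers and process rates.  Passing recovery tests therefore show
that the analysis chain inverts its own generative assumptions under
realistic noise — not that those assumptions hold in real throughfall.

`recovery_study` simulates replicates, runs the interval attribution on
the noisy δ¹⁸O endpoints, and reports coverage (truth inside the interval
± the 2 pp tolerance) and bias.  Replicates whose observed δ¹⁸O change is
below the noise floor (2·√2·σ, the SD of a difference of two
measurements) — or whose final value drifts above the initial — are scored
as zero-production estimates rather than errors, mirroring the pipeline's
insufficient-signal rule.  At the study conditions (200 replicates,
default noise) coverage is 0.90 with negligible bias.

## Pipeline

`run()` validates inputs up front, echoes the full configuration into the
output directory, logs every default in effect, and writes budget,
attribution, qPCR and detection CSVs plus a plain-text report.  The
attribution is skipped with an explicit "insufficient isotopic signal"
note when |Δδ¹⁸O| < 2 analytical SDs, so rainfall-like series are never
forced through the mass balance.  The pipeline is deterministic:
identical inputs produce byte-identical outputs; randomness lives only in
the seeded generator.

Bundled fixtures carry the published worked-example numbers.  Where a
printed source gives only an aggregate (rainfall mineral N of 59 µM, or
sub-LOQ counts known only as "< 44"), the fixture's per-species split or
per-reaction mean is a synthetic placeholder consistent with the printed
constraint, and is marked as such in the source.

## Known limitations

* The attribution assumes a closed two-member system: no nitrate loss
  (denitrification, uptake) and a constant atmospheric end member during
  incubation.  Nitrate consumption would bias the estimate low.
* The end-member interval reflects water-δ¹⁸O uncertainty only; O₂ δ¹⁸O
  and the 2/3 sourcing ratio are treated as fixed, though both vary in
  nature (kinetic O fractionation, abiotic exchange).
* Classification thresholds are heuristics for endpoint data; weekly
  kinetics are simulated but not exploited for inference.
* qPCR SDs are rescaled, not modelled; censoring is a hard threshold at
  the LOQ with no uncertainty on the LOQ itself.
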