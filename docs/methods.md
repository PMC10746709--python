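# Methods

This note documents the models, units, numerical choices and known
limitations behind each `marshcarbon` stage, and what the synthetic-data
generators do and do not emulate.

## Data model and units

Depths are centimetres below the sediment surface, positive downward,
with half-open slice intervals [top, bottom); cores are capped at
100 cm (coring refusal depth). Stocks are Mg OC ha⁻¹ (1 g cm⁻² =
100 Mg ha⁻¹; 1 Mg = 1 t), accretion rates mm yr⁻¹, burial rates
g OC m⁻² yr⁻¹, isotope signatures ‰. Missing numerics are empty CSV
cells surfaced as `None`, never 0 — a site whose cores were too
bioturbated to date carries an absent accretion rate and is excluded
from rate summaries. Floats are serialised with `repr`, so
write-then-read round-trips are exact. All record invariants are
enforced at construction; invalid rows never reach a downstream stage.

## Stocks

OC mass fraction is the difference of the total-C percentages of
non-incinerated and incinerated (450 °C) subsamples, divided by 100. A
negative difference is measurement noise and is floored at 0 with a
logged warning rather than propagated as negative stock. Dry bulk
density is dry mass over slice volume (corer cross-section 9.05 cm² by
default). The sediment stock integrates OC density × thickness over the
slices actually cored — never extrapolated to 1 m — and is multiplied by
(1 − f), where f is the areal burrow fraction.

Burrow geometry: burrows are treated as vertical cylinders of the
measured entrance diameter spanning the cored depth, so the volumetric
void equals the areal fraction f = N̄ π (d̄/2)² / A. This is the simplest
geometry consistent with a surface survey; a `taper` factor in
`integrate_sediment_stock` scales the void downward for burrows that
narrow with depth. When several quadrats exist per site × species, f
uses the site-mean count and the mean of all measured diameters (not
the mean of per-quadrat void fractions), matching how field surveys
summarise burrow abundance. Root stocks (cored to 50 cm) are added to
the sediment stock without depth rescaling; `assemble_stock_record`
refuses a separate root stock when roots are declared to be already
inside the core measurement, to prevent double counting.

## Geochronology

The ²¹⁰Pb decay constant is ln 2 / 22.3 yr. Excess activity is total
²¹⁰Pb minus ²¹⁴Pb (supported proxy); slices at or below background are
flagged and excluded, and fewer than three positive-excess slices is an
"excess not separable" error (the fallback condition for ¹³⁷Cs dating
in `date_core(method="auto")`). The CF:CS fit is an unweighted OLS of
ln(excess) on linear depth (cm); cumulative mass depth is a reasonable
alternative regressor when compaction is non-negligible, but the cores
this supports are verified for <10% compaction (`compaction_check`,
inclusive boundary), making linear depth defensible. A non-negative
slope is an error, not a zero rate. The ¹³⁷Cs peak is the
maximum-activity slice midpoint, shallowest first on ties; a maximum at
the deepest slice (activity never declining) is rejected as "no peak".
The reference fallout year defaults to 1963 and is configurable; the
elapsed-time convention is whole calendar years (collection year minus
reference year). Burial rates use the burrow-corrected,
thickness-weighted mean OC density of the paired stock core
(`mean_oc_density`), restricted to the dated interval via `max_depth`
when the caller knows it; whole-core density is the default since the
dated interval varies by core.

## Isotope mixing

The likelihood treats each tracer observation as Gaussian with mean
Σₖ pₖμₖ and variance Σₖ pₖ²σₖ² + σ²ᵣₑₛ: source signatures enter as
fixed literature (mean, SD) pairs, and σᵣₑₛ is a per-tracer residual
scale with a half-normal prior of scale 1 ‰ — weakly informative on the
per-mil scale of both tracers. The prior on proportions is
Dirichlet(1,…,1). No concentration dependence and no trophic
discrimination are applied (the mixture is sediment organic matter, not
a consumer). The residual term can be disabled (`residual=0`) or fixed.

Sampling is random-walk Metropolis on additive-log-ratio coordinates
(step 0.35, acceptance typically 0.2–0.5), jointly with log σᵣₑₛ; the
ALR Jacobian keeps the simplex prior flat. Chains are pure functions of
the seed. Effective sample size uses the initial-positive-sequence
autocorrelation estimator; ESS < 100 warns but does not fail. The
independent oracle (`grid_posterior`) evaluates the same posterior on a
simplex lattice (step ≤ 0.01) and marginalises σᵣₑₛ by 80-point midpoint
quadrature under the same prior — the tracer likelihood factorises, so
the two residual scales integrate independently. MCMC and grid means
agree within 0.02 for K ≤ 3 in the test suite. `two_source_exact` gives
the analytic noiseless K = 2 limit, clipping out-of-hull mixtures to
[0, 1] with a warning.

## Path analysis

Each endogenous node of the metamodel gets a linear mixed model with a
single site random intercept, fit by maximum likelihood (not REML) so
that p-values from sequentially refit models are mutually consistent.
The fixed effects and residual variance are profiled out analytically
(block Woodbury inversion of I + θJ per site), leaving a bounded 1-D
search over log θ, θ = σ²_b/σ²_e ∈ [e⁻¹², e¹²]; the θ = 0 boundary is
evaluated explicitly and preferred when its likelihood is not worse, so
zero-variance data reproduce OLS exactly. Coefficient tests are Wald z.

The d-separation basis set contains one claim per non-adjacent pair
(x, y), ordered so y is not an ancestor of x (topological, then
lexicographic order), conditioning on the union of both nodes' parents;
each claim is tested as the Wald p-value of x in a mixed model of y on
{x} ∪ parents with the same random intercept. Fisher's C = −2 Σ ln pᵢ
is compared to χ² with 2k df. Model simplification removes the
least-supported path with P > α (default 0.05) one at a time while the
d-sep P stays above α or improves, skipping caller-forced `keep` paths;
if the simplified model fails the d-sep test, edges from a declared
candidate (metamodel) set matching the most significant violated claim
are added back. A final model that still fails is returned flagged,
never silently. Analysis-scale transforms (log₁₀ for sediment stock,
belowground biomass and the three C:N ratios; square root for burrow
surface, litter and aboveground biomass) are applied before fitting and
standardization; standardized coefficients are β·sd(x)/sd(y) on that
scale. Heterogeneous per-group residual variances (sometimes used for
senescent-tissue C:N responses) are out of scope: no acceptance surface
depends on them and a single residual variance keeps the profiled
likelihood exact.

Marginal R² is var(Xβ̂) / (var(Xβ̂) + σ²_b + σ²_e); conditional R² adds
σ²_b to the numerator. An all-zero-variance fit is undefined and raises.

## Synthetic data

Generators are pure functions of (parameters, seed); a master seed fans
out to stage seeds by fixed offsets. Defaults follow the study region's
magnitudes: accretion 0.5–3.5 mm yr⁻¹, stocks ~5–110 Mg OC ha⁻¹, burrow
densities up to >120 m⁻², two-to-three isotope sources ~10 ‰ apart.

* Cores: OC fraction c₀e^(−kz) evaluated at slice midpoints (so the
  noiseless integral has a closed form), constant bulk density, slicing
  at 5, 10, then every 10 cm.
* Radionuclide profiles: exponential excess decay with multiplicative
  lognormal noise, constant supported level, Gaussian ¹³⁷Cs pulse at
  the fallout-peak depth, 1-cm slices.
* Burrows: Poisson counts per 625 cm² quadrat, lognormal diameters;
  expected void fraction λ·π·E[d²]/4/A is stored as ground truth.
* Isotopes: mixtures drawn from exactly the process + residual model
  the fitter assumes.
* SEM: exogenous nodes standard normal; endogenous nodes linear in
  their parents plus a site intercept and iid Gaussian noise.

What the generators do *not* emulate — and hence what green tests do not
demonstrate about field data: spatial autocorrelation within sites,
core compaction and mixing (bioturbated chronologies), non-constant
²¹⁰Pb flux (CRS-type histories), isotope source signatures that vary in
space or season, non-Gaussian or heteroscedastic plot covariates, and
measurement error in depths and masses. Recovery results on synthetic
data are a correctness check of the estimators under their own
assumptions, not a field-validation of those assumptions.

## Problem sizes and tolerances

The test-suite simulations use sizes where the checks are sharp but
cheap: 200-replicate Monte-Carlo for CF:CS noise recovery, 50 seeded
replicates for mixing-interval calibration (1,500 MCMC draws each),
20,000 draws for the headline mixing comparison, and 10 sites × 30
plots for SEM recovery. The mixed-model boundary check constructs noise
centred within groups so the realised site variance is exactly zero and
the profiled likelihood peaks at θ = 0, making the OLS comparison
deterministic at 10⁻⁶ rather than dependent on a lucky draw. Numeric
tie-breaks worth knowing: ¹³⁷Cs peak ties resolve shallowest-first;
basis-set claims and reported coefficients are emitted in canonical
topological-lexicographic order; printed-table comparisons round half
away from zero at two decimals.

## Known limitations

* The per-site summary tables ship as transcriptions of printed values;
  rows inherit any upstream rounding (the per-site total-tons column
  sums to 4,136,493 while the study text reports 4,136,190, and one
  site's root-stock entry exceeds its own belowground total — both kept
  as printed, neither used as a machine target). The table-level mean
  total stock (44.50 Mg OC ha⁻¹ over 20 rows) is not the plot-level
  mean a study computes from raw replicates, so both views are printed
  where relevant. Likewise the accretion-rate maximum recomputed from
  the site table is 3.44 mm yr⁻¹ (Río Negro, lower marsh).
* CRS/CIC age models, ²²⁶Ra equilibrium, detector physics, GIS area
  delineation and granulometry protocols are out of scope; only derived
  covariates (e.g. the inverse sorting coefficient) are consumed.
* The mixing model supports K ≤ 3 sources; the grid oracle is the
  binding constraint and the study systems have at most three sources.
* No latent variables, correlated errors or non-Gaussian responses in
  the path analysis; model search is restricted to the stated
  removal/addition rule.
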