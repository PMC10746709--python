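# marshcarbon

Blue-carbon accounting for salt marshes densely inhabited by burrowing
crabs (e.g. *Neohelice granulata* on the southern SW Atlantic coast).
The package turns raw field tables — sediment-core slices, vegetation
biomass, burrow surveys, radionuclide activities, stable-isotope
signatures and plot covariates — into the quantities blue-carbon studies
report: per-compartment organic-carbon (OC) stocks, sediment accretion
and OC burial rates, source contributions to the sedimentary OC pool,
and a path analysis of stock drivers. Every stage has a seeded
synthetic-data generator with stored ground truth, so the whole pipeline
is testable without any field data.

## What it computes

**Stocks** (`marshcarbon.stocks`). OC content per core slice is the
loss-on-ignition difference between the total-C of non-incinerated and
incinerated subsamples; the stock integrates OC density over the depth
actually cored (no extrapolation to 1 m),

  S = Σᵢ cᵢ ρᵢ Δzᵢ · (1 − f) · 100  [Mg OC ha⁻¹],

where f is the areal fraction of the surface occupied by crab burrows,
f = N̄ · π(d̄/2)² / A for mean burrow count N̄ and mean entrance diameter
d̄ per quadrat of area A. Vegetation stocks are biomass × C fraction;
belowground = sediment + roots; totals scale to tons via site areas.

**Geochronology** (`marshcarbon.geochron`). Under constant flux and
constant sedimentation, excess ²¹⁰Pb (total minus the ²¹⁴Pb-proxied
supported level) obeys ln A(z) = ln A₀ − (λ/s)·z with λ = ln2 / 22.3 yr;
an OLS fit of ln A on depth gives the accretion rate s = −λ/slope.
Where excess ²¹⁰Pb is inseparable from background, the ¹³⁷Cs activity
peak is dated to the 1963 southern-hemisphere fallout maximum. Burial
rate = SAR × mean OC density × 1000 (g OC m⁻² yr⁻¹).

**Source partitioning** (`marshcarbon.isomix`). A two-tracer
(δ¹³C, δ¹⁵N) Bayesian mixing model with Dirichlet(1) prior on the
source proportions and Gaussian process + residual errors,
obsₜ ~ N(Σₖ pₖμₖₜ, Σₖ pₖ²σₖₜ² + σ²ᵣₑₛ,ₜ), sampled by random-walk
Metropolis on additive-log-ratio coordinates and cross-checked against
a deterministic simplex-grid integration.

**Path analysis** (`marshcarbon.pathsem`). Piecewise SEM: one
random-intercept linear mixed model per endogenous variable (site as
the random factor, fit by profiled maximum likelihood), Shipley
d-separation basis set, Fisher's C = −2Σln pᵢ vs χ²(2k), standardized
path coefficients β·sd(x)/sd(y), and Nakagawa marginal/conditional R².

**Aggregation** (`marshcarbon.aggregate`) computes the study-level
summaries (means ± SE, ranges, regional tonnages, pooled updates of
literature compilations) and ships small transcriptions of the per-site
summary tables used by tests and demos.

## Worked example

```sh
python examples/dating_core.py
```

```
true accretion rate: 2.00 mm/yr
CF:CS  fit: 2.06 mm/yr (r^2 = 0.984, 30 slices above background)
137Cs peak: 1.98 mm/yr (peak at 105 mm)
OC burial at mean OC density 0.015 g/cm^3: 30.9 g OC/m^2/yr
```

A synthetic core deposited at 2 mm/yr with 15% lognormal activity noise
is dated independently by the two chronometers: the CF:CS regression
recovers 2.06 mm/yr (3% high, within the noise), the ¹³⁷Cs peak depth
(105 mm over 53 years) gives 1.98 mm/yr, and combining the accretion
rate with the burrow-corrected mean OC density of the paired stock core
yields the burial flux. The other scripts in `examples/` demonstrate
stocks (`stocks_from_cores.py`), mixing (`source_partitioning.py`),
path analysis (`path_analysis.py`) and the study tables
(`study_tables.py`) the same way.

There is also a thin CLI over the same functions:

```sh
marshcarbon simulate --seed 1 --out demo_data/
marshcarbon stocks --cores demo_data/cores.csv --vegetation demo_data/vegetation.csv \
    --burrows demo_data/burrows.csv --sites demo_data/sites.csv --out stocks.csv
marshcarbon date --cores demo_data/cores.csv --sites demo_data/sites.csv --out dating.csv
```

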