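# Methods

## The soil-surface nitrogen balance

`nbudget` implements a county-level mass-balance model of nitrogen in
cropland, tallied at the soil surface. For each county and year the
model computes

```
N_input  = N_chem + N_atm + N_fix + N_recyc
N_recyc  = N_human + N_livestock + N_straw
budget   = N_input − N_harvest
```

with the surplus (`budget`) partitioned into denitrification, NH₃
volatilization, riverine transfer (runoff + leaching) and residue
combustion; whatever remains is "N stored in cropland", defined as the
closing residual so that mass closure holds exactly by construction
(and is asserted, not assumed, in the tests). The model is entirely
coefficient-driven: no process rates, no temperature or moisture
dependence. That is a deliberate design for statistics-driven budgets —
all information enters through county statistics and literature
coefficients.

Term by term (county c, year t; all flows kg N/y):

* **Synthetic fertilizer** `N_chem = N_pure + f_comp · W_comp`, where
  `W_comp` is compound-fertilizer product mass and `f_comp = 0.35` its
  average N content (regional N:P:K ≈ 1:1:0.8).
* **Atmospheric deposition** `N_atm = A · P(region, t)`, bulk
  NH₄⁺/NO₃⁻ deposition rate times cropland area. Rates (kg N/ha/y):
  plateau provinces (Qinghai/Xizang) 3.65 (2000) / 5.31 (2010); other
  upper+middle-reach counties 17.97 / 23.28; lower reach 20.95 / 26.55.
  The area basis is configurable (`cropland_area`, the default, or
  `paddy_plus_upland`) because multiple cropping makes "agricultural
  land area" ambiguous.
* **Biological fixation** `N_fix = Σᵢ Aᵢ · Fᵢ` over sown areas, with
  `F` = 80 kg N/ha/y for peanut and soybean (symbiotic), 30 for rice
  and 15 for wheat (crop-associated), 0 otherwise.
* **Human excrement** `N_human = 0.85 · P_adult · 5 · 0.4`: adult
  population converted to total rural population (0.85), 5 kg N per
  person per year, 40% of excrement applied to fields as manure.
* **Livestock excrement** `N_livestock = 0.4 · Σₛ Pₛ · Eₛ` with per-head
  coefficients 8 (pigs), 40 (cattle), 5 (sheep) kg N/head/y. The source
  tables print the unit of these coefficients as "kg N/ha/y"; per head
  per year is the only reading consistent with their use as multipliers
  of animal headcounts, and is what we implement.
* **Returned straw** `N_straw = Σᵢ Yᵢ · Rᵢ · Sᵢ · Pᵢ` (yield ×
  straw/seed ratio × returned fraction × residue N concentration).
* **Harvest** `N_harv = Σᵢ Yᵢ · cᵢ` with per-product N contents.
* **Losses.** County fertilizer N is first apportioned between paddy and
  upland (proportional to their areas by default; a fixed share is
  configurable, since the source applies class-specific percentages
  without stating an allocation). Fixed fractions then apply:
  denitrification 36% (paddy) / 25% (upland) / 15% (organic manure);
  NH₃ volatilization 16% / 11% / 23%; runoff 5.2% / 11% of chemical N
  and 5% of organic N; leaching 1.2% / 3.2% and 4%. The organic pool is
  applied human + livestock excrement N; returned straw can be switched
  into it (`organic_pool_includes_straw`), default off, because the
  loss percentages were derived for "fertilizers and human and animal
  wastes". N₂O and NO emissions are omitted (a very small share of
  inputs). **Residue burning** emits `Yᵢ · Rᵢ · Bᵢ · 0.00383` kg N per
  county (3.83 g N per kg residue burned).

Two coefficient tables are stand-ins rather than published numbers: the
per-crop straw parameters (R, S, P, B) and the crop N contents, which
the source work takes from an earlier regional budget study without
printing. We ship representative values from that literature (e.g. rice
straw/seed ratio 0.62, returned fraction 0.3, grain N 0.012 kg/kg),
clearly overridable via the YAML parameter file; no verification
quantity in this package depends on them beyond the pipeline running
end to end.

### Aggregation, NSI, NUE

County flows (canonical unit kg N/y) are summed to reach accounts;
the basin account is the sum of the three reaches, which makes
additivity exact rather than approximate. Aggregates are reported in
Tg N/y. N surplus intensity NSI = budget / cropland area (kg N/ha/y);
N use efficiency NUE = harvest N / total input N. The source text
contains one sentence inverting the NUE ratio; we follow its own
definition "(NUE: the ratio of N input and yield output of the
system)" and the universal output/input convention, so NUE < 1 in
normal conditions. Rounding (half-up; Tg to 1 decimal, NSI to whole
kg/ha, NUE to 2 decimals) is presentation-only and never feeds back
into computation.

## Identity decomposition of fertilizer-N change

Fertilizer N input M factors as M = A × D (cropland area × application
rate, D = M/A), so ln M = ln A + ln D and the two-point log-rates
m = ln(M₁/M₀), a = ln(A₁/A₀), d = ln(D₁/D₀) satisfy **m = a + d**
exactly — the printed equation "m = a × d" in the source is a typo for
this additive identity, which its own derivation gives. With only two
observation years, discrete log-differences replace the time
derivatives and the identity is exact, not approximate.

Contribution shares: when a and d have the same sign (or one is zero),
share_x = x / (a + d); when they oppose, share_x = |x| / (|a| + |d|)
and the direction is flagged "mixed" (the opposite-sign convention is
ours; the source only reports same-direction regions). D is defined at
region level as ΣM / ΣA — the intensive ratio of aggregates — not as a
mean of county rates; the tests pin this distinction. The degenerate
case a = d = 0 has no meaningful shares and returns them as missing.

## Monte Carlo uncertainty

Coefficients, not statistics, dominate the uncertainty of such budgets,
so the Monte Carlo stage perturbs coefficients globally (one draw
shared by all counties, matching their literature provenance) and
recomputes the basin budget per draw. Default CV map: 5% for the
compound-fertilizer N fraction, 35% for all four fixation rates, 30%
for the human and livestock excretion coefficients, 20% for the
manure-applied fraction. The printed description "human and livestock
emission factor and rate, CVs of 30 and 20%" does not say which
coefficients are "factor" vs "rate"; we map excretion coefficients to
30% and the applied fraction to 20%, overridable like everything else.

Sampling is zero-truncated normal (mean = default, sd = CV × default,
negatives redrawn) because the coefficients are physically nonnegative
and the original spreadsheet-risk-tool distribution family is not
stated; a moment-matched lognormal is available. Each coefficient draws
from its own stream seeded by (seed, crc32(key)), which (i) makes runs
bit-reproducible, and (ii) couples draws across different CV maps so
that adding an uncertain coefficient provably never decreases budget
variance in the tests. Contribution to variance is the squared Spearman
rank correlation of each coefficient with the budget, normalised to sum
to 1 — the standard "contribution to variance" of spreadsheet risk
tools, an approximation to first-order Sobol indices (interactions are
negligible here because the budget is essentially additive in the
coefficients).

Per draw, the basin budget is evaluated from dataset-level sufficient
statistics (per-region-class areas, per-crop sown/yield totals,
headcounts, population) assembled once. Because every budget term is a
global coefficient times a county quantity, this equals the sum of
per-county budgets exactly; the equality is asserted against the
per-county pipeline in the tests. 20000 draws run in a few seconds.

The headline uncertainty results of the original study (mean 8.1 Tg,
90% range 6.3–11.4 Tg for 2000) depend on its unavailable county data
and are deliberately not targets here; the Monte Carlo stage is
validated behaviourally (degeneracy at zero CVs, law-of-large-numbers
agreement with the deterministic budget, single-source contribution,
seed determinism, coupled-draw variance monotonicity).

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes:
per-reach log-normal cropland areas and fertilizer application rates
(right-skewed, positive — the distribution family is our convention;
none is given for the real data), reach-specific paddy fractions, crop
mixes, yields, livestock and rural-population densities, and a small
probability of plateau-province counties in the upper reach. Default
county counts are 177/139/39 per reach; default magnitudes put the
basin total N input at roughly 9 Tg for 2000, the right order for a
large, intensively fertilized basin, and `target_basin_scale` rescales
all extensive quantities linearly to hit a requested total exactly.

The second year is the first scaled by per-reach area and rate change
factors, so the regional log-rates (a, d) — and hence the decomposition
shares — are known exactly by construction. The bundled scenario builds
shares of 16/84 (upper), 24/76 (middle) and a joint decrease split
48/52 (lower), mirroring the qualitative regional pattern of the
original study; these are construction targets, not reproductions.

Ground truth (regional M, A, D, log-rates, shares, total inputs,
budgets) is computed by an independent accumulation inside the
generator — plain loops spelling out each formula, not calls into the
pipeline — so parameter-recovery tests are non-circular.

What passing tests on this data do **not** show: robustness to the
messiness of real yearbook tables (missing livestock categories,
inconsistent area definitions, urban-district reclassification between
census rounds), spatial autocorrelation between neighbouring counties,
or correlated coefficient errors. The generator draws counties
independently and applies region-uniform change factors; real area and
rate changes vary county by county.

## Numerical choices

* Canonical unit kg N/county/y everywhere internally; Tg (10⁹ kg) and
  kg/ha only at the reporting boundary. This prevents silent unit
  mixing between Table-style aggregates and per-hectare intensities.
* `n_stored` is a residual and may go negative under extreme parameter
  overrides; it is reported, never clamped, because clamping would
  silently break closure. The parameter validator guarantees that the
  per-pool loss fractions sum to ≤ 1, so negative storage cannot arise
  from the default loss structure alone.
* Division-by-zero cases (NSI with zero area, NUE with zero inputs,
  percent change from a zero base) return missing values with a logged
  warning rather than NaN propagation.
* The area-consistency rule (paddy + upland ≤ cropland × 1.05 by
  default) is an error on ingest but can be demoted to a counted
  warning (`on_area_violation="report"`), since real county tables are
  ragged.
* Dataset records are stored sorted by (county, year), making dataset
  equality order-independent; CSV round trips are float64-lossless
  (17-significant-digit writing, round-trip parsing).
* Identity assertions (m = a + d, exp(m)·M₀ = M₁) are checked to 1e-12
  relative; generator-vs-pipeline recovery to 1e-9.

## Known limitations

* Fixed loss fractions ignore management, climate and soil controls on
  emissions; this is inherent to the accounting frame, not a bug.
* No inter-county manure or straw transport: the 40% applied fraction
  acts where the excrement arises.
* Grassland and wetland N are outside the balance (croplands only).
* Reach membership is an input column; no spatial processing.
* The two-factor decomposition cannot separate within-region
  heterogeneity: a region with offsetting county-level changes shows
  only the net regional effect.
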