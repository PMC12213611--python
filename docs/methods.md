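# Methods

This note records the modelling assumptions, parameter choices and
numerical details behind `rootsoc`, in the spirit of a package methods
appendix. Nothing here states an empirical result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Data model and conventions

Depths are cm, positive downward, 0 at the top of the uppermost horizon;
organic (O) horizons share the same downward axis as mineral horizons,
avoiding any negative-depth convention. Depth intervals are half-open
`[top, bottom)`. Stocks are kg C m⁻². Input tables are comma-separated
UTF-8 CSV with "." decimals and empty cells for missing values.

Sites present in the metadata but lacking root rows (the field situation
where a pit was dug but roots were not sampled) are never dropped
silently: they are carried with a machine-readable exclusion code
(`no_root_data`, similarly `no_horizon_data`, `zero_total_stock`,
`too_few_measurements` downstream).

Tundra-tagged sites keep their tag on every record but are analyzed under
the grassland class by default (`AnalysisConfig.tundra_as`), since
high-latitude grasslands/tundra form one functional class in the
cross-ecosystem analyses; the mapping is configurable.

## Stocks and alignment

SOC stock per horizon is `OC%/100 × ρ × t × 10` with ρ in g cm⁻³ and t in
cm; the factor 10 is the exact g cm⁻² → kg m⁻² conversion. Root C stock
per increment is `B × c%/100 / 1000` with B in g m⁻².

Root status: FRC includes live **and** dead standing biomass by default
(`root_status="all"`), configurable to live-only. Standing dead fine roots
are part of the sampled rootstock and their inclusion is the conservative
default when the field protocol separates the classes visually. The
2-mm vs 4-mm fine-root diameter protocols are carried as metadata, not
corrected for; `models.diameter_protocol_check` provides the rank-sum test
of FRC–SOC residuals between protocol groups to verify pooling is
defensible.

Alignment assumes uniform root density within an increment and splits the
increment's stock across horizons in proportion to depth overlap. The
invariants — exact mass conservation, idempotence on coincident
boundaries, row-order invariance — are enforced by property tests over
randomized geometries. Biomass below the deepest horizon (or in a
coverage gap) goes to an explicit unallocated bucket.

The shallow/deep boundary is 30 cm, closed below: `[0, 30)` shallow,
`[30, 200]` deep; a straddling layer is split proportionally. Aggregation
by organic/mineral flag and by the 30-cm split is additive to the whole-
profile totals to 1e-9, asserted in `SiteAggregate.validate`.

Aridity is `MAP/(MAT + 13)` (mm °C⁻¹, lower = more arid); the +13 offset
keeps the denominator positive down to MAT = −12 °C. At MAT ≤ −13 the
index is undefined and reported as NaN with a warning.

## Beta depth-distribution fit

The cumulative profile puts a point at every layer bottom,
`Y(d) = (stock above d)/(total)`. The fit minimizes
`Σᵢ (Yᵢ − (1 − β^{dᵢ}))²` over β ∈ (0.5, 0.99999). Bounds rationale:
ecological β clusters in 0.9–0.99; the open lower half-interval guards
against boundary stalls without excluding extreme shallow profiles.

Numerics: the optimizer starts from the median of the per-point
closed-form solutions `β = (1 − Y)^{1/d}` and polishes with bounded Brent
in a ±0.05 window; a 512-point coarse scan of the full interval with Brent
refinement in the bracketing cell safeguards against a poor start. The two
candidates are reconciled by SSE; convergence tolerance is 1e-10 on β. Any
bounded scalar minimizer meeting the grid-oracle tolerance (agreement with
an exhaustive 1e-4-step grid search to 2e-4) is conformant; the objective,
not the optimizer, is the contract. `grid_search_beta` ships as the
brute-force oracle.

Profiles with fewer than `min_points = 3` cumulative points are excluded
(`too_few_measurements`), 3 being the smallest count leaving residual
degrees of freedom in a 1-parameter fit; profiles with zero total stock
are excluded as `zero_total_stock`. All points are weighted equally.
Profiles shallower than 200 cm are fit on their own depth support; no
extrapolation.

One numerical property worth knowing: a cumulative profile computed from
layers is normalized so its final Y is exactly 1, while the model reaches
1 only asymptotically. For a profile truncated at depth D this shifts the
SSE minimizer by O(β^D)-size terms relative to a generating β (measured:
~−5e-6 at β = 0.95, ~−8.5e-4 at β = 0.98, D = 200 cm on the standard
grid). The bias is inherent to fitting this model to renormalized
truncated profiles — real profiles have it too — and sits well inside the
±0.005 recovery band verified under 10% layer noise.

## Accrual/priming residuals

Standardization uses sample (n−1) standard deviations. The default
grouping pools all sites within a depth class (ecosystems share one 1:1
line, preserving cross-ecosystem contrasts); per-ecosystem grouping is
available (`standardization="by-ecosystem"`), in which case ecosystems
with fewer than two sites cannot be standardized and are left out of that
analysis. Residuals within a standardization group sum to zero by
algebraic identity, asserted to 1e-9.

Labels: residual > 0 accrual, < 0 priming, with a ±1e-12 neutral band so
constructions lying exactly on the line are not relabelled by float
rounding; statistically the neutral case has measure zero.

Within-ecosystem depth-class slopes (z_SOC on z_FRC) can exceed 1 only
because the z scale is anchored to a pooled population wider than the
regressed cohort; the synthetic depth-cohort generator therefore emits
z-scale values directly and is deliberately not re-standardized within the
cohort. Residual-explaining regressions (on aridity, MAP, clay, and a
configurable micronutrient-proxy column) are complete-case OLS per
ecosystem × depth class, with rank-deficient designs rejected naming the
collinear columns.

## Model fitting and selection

Specifications without a random term are OLS; with a random term they are
random-intercept linear mixed models, delegated to statsmodels `MixedLM`.
Maximum profile depth cannot serve directly as a grouping factor
(it is continuous), so it is binned to {≤100, 100–150, >150 cm}; this
preserves its role as a sampling-depth control. Coefficients and their
standard errors come from the REML fit; because fixed-effect structures
cannot be compared on REML likelihoods, AIC/AICc use the ML fit of the
same model. `AIC = −2ℓ + 2k` with k counting regression coefficients plus
variance components plus the residual variance (R's `AIC()` convention),
and `AICc = AIC + 2k(k+1)/(n−k−1)`. Mixed-model fixed-effect p-values use
the large-sample Wald normal approximation; a cross-check test verifies
the fixed-effect estimates against an independent REML implementation
(R lme4). A group variance estimated at (numerically) zero is reported
with a `variance_at_boundary` flag rather than hidden. The marginal
pseudo-R² is Var(Xβ̂)/(Var(Xβ̂) + σ²_group + σ²_resid).

Selection: all subsets of the fixed terms (a superset of any single-term-
deletion path), AICc when n < 40 else AIC, full model ineligible, ties
broken by fewer parameters then lexicographic term order — fully
deterministic. Complete-case rows per model, with the n actually used
reported per fit.

## Synthetic generator

The generator emulates megapit-style sampling: root increments on the
10/20-cm grid, horizon boundaries drawn independently (optional thin
organic cap of 3–10 cm plus 2–6 mineral horizons of ≥5 cm), profile depth
drawn from {100, 140, 200} cm with weights 0.15/0.15/0.7 to exercise
bedrock truncation and the depth-bin random effect.

Default study conditions: 15 grassland-class sites (3 of them tundra-
tagged outliers), 25 forests, 3 shrublands, 1 cultivated site; climate
ranges MAT −12..25 °C and MAP 100..2500 mm with grassland mean MAP about
half the forest mean; organic-horizon probability 0.6 in forests, 0.9 in
tundra, near zero elsewhere. Coupling defaults: grassland
`SOC = 8.5 + 15.5·FRC + N(0, 2²)` (σ = 2 puts the n = 15 cohort r² near
0.8 given the FRC spread, mean 0.4 / sd 0.25 kg m⁻² lognormal); forests,
shrublands and cultivated sites are uncoupled (b = 0) with ecosystem-
specific SOC levels and spreads. Tundra outliers have their FRC multiplied
by 2.5 *after* the coupling draw, so they weaken the fitted grassland
slope exactly as high-latitude high-root-biomass outliers would.

Noise acts at two independent scales: multiplicative log-normal noise
(CV 10% by default) on the within-profile layer fractions, renormalized so
site totals are conserved exactly, and the additive site-level coupling σ.
The renormalization is what lets the β-recovery and slope-recovery
properties be tuned independently — without it, layer noise would act as
error-in-x and attenuate the recovered coupling slope. Per-site draws
(bulk density by horizon class, root C %, clay, diameter protocol with
P(4mm) = 13/43, live/dead split 80/20) are all driven by one integer-
seeded PCG64 generator; a seed fully determines the output bytes.

What the generator does **not** emulate: within-site covariance between
clay and β (independent draws), spatial autocorrelation, replicate pit
profiles (inputs are pre-averaged), root turnover or decomposition
dynamics, rock-fragment corrections. Passing tests therefore demonstrate
correctness of the computational method under the stated generating
assumptions, not ecological validity of those assumptions on real data.

## Known limitations

- The accrual/priming residual is a correlational proxy; it cannot
  separate low SOC-per-FRC caused by priming from fast decomposition of
  root litter or from unmeasured C inputs.
- Satterthwaite/Kenward-Roger degrees of freedom are not implemented;
  mixed-model p-values are large-sample approximations and will be
  anti-conservative in very small groups.
- β fits on profiles truncated well above 2 m carry the renormalization
  bias described above; comparisons across sites with very different
  profile depths should keep the depth support in mind.
- The micronutrient proxy is a single generic covariate column; no
  element-specific handling is attempted.
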