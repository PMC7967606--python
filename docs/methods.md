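# Methods

## Parcel scoring

The hazard model is deliberately simple and auditable: an ordinal age
tier (3/2/1 at the 1940/1960 breaks, exclusion after 1978), an ordinal
value tier (3/2/1 at the \$100k/\$200k breaks), their sum, and a
multiplicative grade modifier. Boundary conventions, where the prose
sources of such rules are usually ambiguous, are fixed as half-open
year bins [<1940], [1940, 1960), [1960, 1978] — consistent with the
worked examples (1961 → 1, 1955 → 2) — with 1978 itself scored and only
later years excluded; both \$100,000 and \$200,000 fall in the moderate
value tier, matching the printed inclusive range.

Excluded parcels are retained with final score 0 rather than dropped,
because area scores are normalized by *all* residential parcels; a
block of new construction should read Very Low, not No Data.

### Grade modifiers

Nine modifiers are fixed exactly by the worked examples (final ÷
cumulative): D 1.0, D+ 0.9, C−− 0.7, C− 0.6, C 0.5, C++ 0.3, B− 0.2,
B 0.1, A− 0.025. The full auditor modifier table is not publicly
reproduced, so the remaining grades are a monotone completion — A++
0.01, A+ 0.015, A 0.02, B+ 0.05, C+ 0.4, and E/E−/E−− stepped upward at
1.1/1.2/1.3 — chosen to preserve the only hard constraint the anchors
impose (modifiers non-increasing as quality improves) while staying
close in spacing to the neighboring anchors. The table validates that
constraint on construction and is fully overridable in configuration;
an input grade absent from the table is a hard lookup error, never a
silent default.

## Area classification

The five-category partition is {0} Very Low, (0,1) Low, [1,2) Moderate,
[2,3) High, [3,∞) Very High. Two printed-source ambiguities are
resolved here: an overlapping Moderate upper bound (read as a typo for
[1,2), the range its companion childcare table prints), and the gap
between "0.00" and "0.01–0.99" (any positive-but-tiny mean is Low, so
the partition is total). Childcare outputs relabel Very High as
"Highest"; the partition is identical.

No Data is emitted only for units that have recorded children but zero
residential parcels (emulating large apartment complexes and dormitory
tracts, which auditor data does not classify as residential);
parcel-less units without children are dropped.

## Childcare buffers

Distance is planar Euclidean on the mile-unit coordinate frame, with the
½-mile buffer a closed disc (boundary parcels included). The buffer
score mirrors the area normalization: sum of final scores over all
parcels in the buffer divided by their count, post-1978 zeros included.
Membership is computed with a k-d tree and is tested against brute-force
all-pairs distances.

## Equity analysis

"Non-white" is computed as 1 − White/total among under-5 children per
tract; race decomposition exists only at tract level (mirroring the
census product structure, where block groups carry age-only counts).
The non-white-share crosstab bands (≤10%, 10–50%, >50%, >75%) nest by
design; output metadata declares the band definitions so row fractions
are not misread as a partition. The opportunity association is a simple
OLS of index on tract mean score with R² = squared Pearson correlation;
no multivariable adjustment is attempted. High-risk/high-child
"priority areas" use configurable tertiles of block-group under-5
counts intersected with High/Very High risk, since no canonical tier
definition exists for that overlay.

## Synthetic county generator

The generator emulates the *structure* the analysis assumes, at desk
scale, not any real county's microdata:

- **Geography**: a rows × cols grid of 0.5-mile square blocks (default
  20 × 20 → a 10 × 10 mile county), grouped 4 blocks/block group and
  2 block groups/tract (400 / 100 / 50 units). Square planar geometry
  keeps every downstream operation (containment, aggregation, buffers)
  exact and dependency-light; real TIGER shapes add nothing the method
  uses.
- **Development era**: each parcel's post-1978 probability is logistic
  in a centrality covariate g = exp(−d/center_decay) (d = distance to
  county center, decay 4 mi) plus a per-block N(0, 2.5) cohort effect —
  blocks are built as subdivisions, so wholly post-ban suburban blocks
  and wholly pre-ban core blocks both occur, as in real counties. The
  intercept is solved numerically so the expected post-1978 share
  equals the configured 0.474 exactly; pre-ban years are normal around
  a center-age gradient (≈1924 at the core, ≈1972 at the edge, SD 12).
- **Value**: lognormal (median \$140k, σ = 0.55) shifted down toward
  the center by up to a factor e; defaults put roughly a third of
  pre-1979 parcels in each value tier (realized ≈ 26/44/30%).
- **Grade**: categorical draw conditioned on value tier; cheap housing
  skews toward D/C− grades, expensive toward B/A.
- **Children**: block-group under-5 counts Poisson(60); under-18 adds
  Poisson(2.3 × under-5); tract totals are exact sums over member block
  groups. Tract non-white share is logistic in standardized tract mean
  housing age with slope `race_gradient` (default 1.5) around a 0.35
  baseline, and the under-5 multinomial split allocates the non-white
  share 65/20/8/7% to Black/Hispanic/Asian/Other.
- **Childcare**: 150 centers, positions weighted by the same centrality
  covariate, program types drawn from the published county marginal mix
  (so Licensed Childcare Center is modal).
- **Opportunity indices**: COI = 80 − 12·score + ε, HOI = 75 − 12·score
  + ε, with the residual SD calibrated per index from the closed form
  sd(ε) = |slope|·sd(score)·√(1/R² − 1) to hit target R² 0.62 / 0.53 in
  expectation (an explicit `opp_index_noise_sd`, e.g. 0 for an exact
  line, bypasses calibration).

Determinism: one master seed fans out through fixed `SeedSequence`
spawn keys to per-generator substreams, so runs are bit-reproducible
and adding a generator never perturbs existing draws.

### What passing tests do and do not show

The generator reproduces the *couplings* the method exploits — age/value
/grade gradients, race–risk correlation, opportunity–risk slope — but
not real parcel microdata: no street network, no geocoding error, no
within-block spatial autocorrelation beyond the cohort effect, uniform
parcel density (real counties are denser centrally), and an Asian
population that follows the common non-white gradient although the real
county's Asian children concentrate in low-risk areas. County-scale
published figures (category counts per level, the 79.4%/45%/37%
disparity percentages, the exact R² pair) therefore are emulation
targets, not reproductions; tests assert the structural properties and
the calibrated quantities with stochastic tolerances.

## Problem sizes and numerical choices

Default analyses run at 20,000 parcels / 50 tracts, a scale chosen so
the whole pipeline and test suite run in seconds while every category
and coupling remains detectable; the opportunity-recovery check uses a
40 × 40 grid (200 tracts, 40,000 parcels) and 50 opportunity redraws,
where the fitted-R² Monte-Carlo mean is required within ±0.05 of the
0.62 target. Share columns are exact ratios of their count columns
(rounding is display-only). Aggregation validates geography ids against
the known universe when supplied and falls back on the parcel's carried
census ids rather than recomputing point-in-polygon, mirroring auditor
files that ship census ids; containment is nonetheless spot-checked in
tests. Currency strings ("\$156,000") are tolerated in value columns;
grade labels tolerate Unicode minus variants.

## Known limitations

- Unit-level apartment hazard is out of scope (auditor data does not
  classify large complexes as residential); the No Data category is the
  honest output for such units.
- The radial-decay spatial model is a stand-in for whatever form a real
  county's risk gradient takes; nothing downstream depends on its
  specific shape, only on the induced orderings.
- No validation against blood-lead outcomes is possible here; the
  scoring is a hazard *prioritization* index, not a calibrated exposure
  model.
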