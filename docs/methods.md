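# Methods

This note documents the models implemented by `sustdiet`, the assumptions
behind them, the parameters that matter, and what the synthetic data
generator does and does not emulate.

## The composite-diet model

A daily diet is a vector of mass shares over 14 food groups (whole grains,
refined grains, nuts, legumes, fruits, vegetables, fish/seafood, red meat,
processed meat, white meat, dairy, eggs, added oils, sugar-sweetened
beverages) with a fixed total of 1800 g/day. Shares are stored as
fractions summing to 1 (tolerance 1e-9); all I/O also accepts percent with
an explicit column-header flag. Printed scenario percentages are
interpreted as percent of total daily mass, since the scenario design
defines diets by weights summing to 1.8 kg. Cooking and storage losses and
nutrient bioavailability are outside the model: all compositions describe
uncooked ingredient masses.

The group list is a closed vocabulary with case-insensitive synonym
resolution (e.g. "fish", "milk/dairy", "beans/legumes"). One published
enumeration of the groups names only 13; vegetables is included as the
14th, consistent with its appearance throughout the scenario results.

## Scenario design

Three anchors are fixed study conditions: the current diet (S1), the
optimal diet (S10), and the feasible diet (S5) defined as the per-group
arithmetic midpoint of the two. `check_anchor_midpoint` reports per-group
deviations from exact midpointness in percent-of-mass units.

Between the anchors, each consumption model (M1: red meat; M2: red + white
meat; M3: red + white + processed meat) contributes seven intermediate
scenarios — S2–S4 between current and feasible, S6–S9 between feasible and
optimal — for 24 scenarios in total.

Two construction modes:

* **Override (default).** The substitution-active groups (legumes and the
  three meats) are pinned per scenario from an explicit table. The
  published ladder is irregular (unequal legume steps within a segment),
  so the authoritative intermediate compositions are data, not a formula.
  The packaged table carries the printed compositions verbatim
  (S1, S2M1–S2M3, S5, S7M1, S8M1, S9M2, S9M3, S10); the remaining
  intermediates are filled by piecewise-linear interpolation over the
  scenario number between the nearest printed knots, and are flagged
  `interpolated` in the returned provenance map. Interpolated rows are a
  convenience approximation, never presented as published values.
* **Linear.** Targeted meats move linearly from the segment's start anchor
  to its end anchor, and the removed meat mass is credited 1:1 to legumes.
  This matches the only fully printed step (S1→S2M1: red −0.67 pp, legumes
  +0.67 pp) and guarantees monotone substitution, but is an approximation
  of the published ladder.

In both modes, groups not pinned for a scenario take the feasible anchor's
values (the design raises fruits, vegetables, whole grains and fish to
feasible levels from S2 onward), and refined grains absorbs the residual so
that every scenario conserves the 1800 g total exactly. A pinned set that
exceeds total mass raises a mass-imbalance error; the refined-grain
absorber is validated non-negative.

## HENI

The Health Nutritional Index maps intakes of 15 dietary risk factors
(9 food groups + 6 nutrients, Global Burden of Disease risk set) to minutes
of healthy life per 100 kcal:

    HENI = -0.53 · Σ_r factor_r · d_r

with −0.53 min per µDALY-scale unit and d_r the intake per 100 kcal.
Negative factors are beneficial (seafood, −81.0, is by far the
largest-magnitude beneficial factor; the factor table validates this
ordering). The factor table is data (`heni_factors.csv`), not code: its
`unit` column declares the intake scale per risk, and corrected unit sets
drop in without code changes. The packaged table declares grams per
100 kcal for every mass risk; mineral columns (sodium, calcium), carried in
mg per 100 g in food tables, are converted to grams when the risk vector is
assembled. The published factor source prints no units, and the magnitude
of the seafood factor suggests some rows may be per-serving rather than
per-gram; this is a config-level uncertainty that affects absolute HENI
values but none of the score's linearity, additivity, or substitution-sign
properties, and none of the packaged-table statistics (which use published
scores directly).

HENI is linear in intakes, so per-day and per-100-kcal scores differ only
by the factor kcal/100. Per-100-kcal HENI is *not* monotone along the
substitution ladder even when every substitution is beneficial per day: the
score is strongly calorie-density dependent (more-caloric diets dilute
fixed beneficial components on the 100 kcal basis). The monotonicity tests
therefore assert the per-day burden, where the legume-for-meat advantage is
unambiguous, alongside the per-100-kcal global-warming decline.

## Adapted Food Compass

46 attributes in 7 domains (nutrient ratios 4, vitamins 12, minerals 9,
food ingredients 13, additives 2, specific lipids 4, protein & fiber 2);
red meats and processed meats are separate attributes, and the iodine,
trans-fat, medium-chain-fatty-acid, flavonoid and carotenoid attributes and
the processing/phytochemical domains are excluded. Each attribute is an
integer cut-point ladder over its per-100-kcal value; ladders must be
strictly ascending in thresholds and monotone in scores along the
attribute's direction. A value exactly on a cut-point takes the healthier
side (upper rung for beneficial attributes, lower rung for harmful ones).
Attributes absent from a profile score 0 and are logged, mirroring the
exclusion of unavailable data; the additives domain is therefore
present-but-zero for raw composite diets.

Aggregation: domain score = mean of the domain's attribute scores; the raw
score is the mean over the six non-ingredient domains plus the **sum** of
the food-ingredient attribute scores. (Averaging the ingredient domain too
would cap its contribution at one seventh, inconsistent with ingredient
contributions of ~41 % at the plant-rich end of the ladder.) The raw score
is rescaled affinely, FCS = 100 − ((26.1 − raw)/36.7)·99, with fixed points
26.1 → 100 and −10.6 → 1. No clamping is applied: out-of-range raw scores
yield out-of-range scaled scores plus a warning, so configuration problems
surface rather than saturate.

The shipped cut-points (`fcs_config.yaml`) are a clearly labelled
placeholder: plausible monotone ladders on per-100-kcal scales with the
correct attribute/domain structure. Absolute FCS values from this package
are therefore not comparable to published Food Compass values until
authoritative cut-points are supplied; the published score table ships as a
verbatim fixture for all statistics over published scores.

## Environmental impacts

For each representative food, mean midpoint impact per RACC ÷ RACC grams =
per-gram factor; per-gram factor × ingredient grams, summed over
ingredients, = per-day diet impact for each of 18 indicators. Impacts are
computed per diet-day and reported on both bases (per-day and per 100 kcal,
flagged explicitly). Indicator names are fixed strings; unit strings are
carried verbatim as metadata and never converted. Groups may be mapped to
several foods with mass-weight splits (weights are normalised); the default
is one representative food per group. The model is strictly linear and
additive — means only, no uncertainty propagation, no life-cycle inventory
modelling.

Percent change is reported as (baseline − alternative)/baseline × 100, so
positive values are reductions. Because scenario calories differ, per-day
and per-100-kcal percent changes differ; both bases are available.

## Trade-off statistics

* Pearson r via the standard product-moment estimator (requires n ≥ 3 and
  nonzero variance in both series).
* Subgroup summaries use the sample (n−1) SD — the published dispersion
  values recompute only under this convention. Subsets are explicit id
  lists: the published prose set labels are inconsistent (the
  "current-to-feasible" FCS statistics cover S1 + S2–S4, while the
  corresponding HENI *mean* covers S2–S4 without S1 though its SD includes
  S1), so each statistic pins its own list.
* Threshold counts use strict inequality ("above 71" admits 71.79 and
  excludes a hypothetical 71.00).
* Rankings use average ranks for ties, with the tie-corrected
  Kruskal–Wallis H available for grouped comparisons; mean ranks are
  exposed rather than only the test statistic, since ranking, not testing,
  is the primary use.
* Pareto flags mark scenarios not dominated on the joint (nutrition score,
  impact) axes; the implementation is checked against an O(n²) dominance
  oracle.
* The indicator correlation matrix flags significance at a configurable α
  (default 0.01) via the t transform of r; zero-variance columns yield NaN
  with a warning rather than failing the whole matrix.

The published correlation between HENI and calorie density (−0.918) is not
recomputable from the packaged fixtures, which carry no per-scenario
calorie densities; it requires user-supplied composition workbooks.

## Synthetic data

The generator produces, under one seeded `numpy` Generator
(default seed 20231128):

* a food table with one (configurable) representative food per group:
  group-typical uncooked macronutrient densities, micronutrient profiles
  from plant/animal archetypes with group multipliers and overrides
  (dairy-calcium, egg-choline/cholesterol, fish EPA/DHA, processed-meat
  sodium), and mean-preserving lognormal jitter (default CV 0.10, chosen as
  a realistic table-to-table variation that preserves positivity);
* an impact-factor table built from per-gram global-warming factors with
  every meat's factor floored at `meat_to_legume_ghg_ratio` × the legume
  factor (default 5, a conservative several-fold per-gram gap between
  animal meats and pulses); the other 17 indicators scale from the
  global-warming factor with indicator-specific constants calibrated to the
  published per-100-kcal ranges, and with water use and freshwater
  eutrophication weighted toward plant groups to emulate the published
  nuance that the plant-rich optimal diet peaks on those two indicators;
* the anchor set, which is deterministic: anchors are stated study
  conditions, not samples. The substitution-active groups carry the
  published shares; the other ten groups are the package's own realistic
  allocation (refined-grain-, dairy- and SSB-heavy current diet; optimal
  diet with SSB eliminated and plant groups raised).

What passing synthetic-world tests show: the pipeline's structural
behaviour — mass conservation, linearity/additivity, the monotone
improvement of daily global warming and daily HENI along every substitution
ladder, and the S9M3-beats-S1-and-S9M2 ordering. What they do not show:
agreement with the published absolute scores or impact magnitudes, which
depend on the external nutrient database, authoritative cut-points and the
source impact workbooks. Synthetic diets also land at ~3200–3700 kcal/day,
higher than typical cooked-diet intakes, because densities describe
uncooked mass — a deliberate consequence of excluding cooking
transformations.

## Numerical choices and degenerate inputs

* Share sums validated to 1e-9 by default (1e-6 for the hand-specified
  anchors); group masses re-sum to the daily total within 1e-6 g.
* Composition round-trips through the CSV writer/reader are exact to 1e-12.
* Cut-point ties go to the healthier side; cut-point ladders reject
  non-monotone configurations at construction.
* Zero-share groups enter profiles as explicit 0 g observations, so a
  harmful ingredient absent from the diet earns its healthy rung rather
  than a missing-data zero.
* Guarded degenerate inputs: zero-energy diets, zero RACC, zero baselines,
  zero-variance series, empty subsets/tables/domains, singleton subsets
  (mean returned, SD undefined and flagged).
* All randomness funnels through one seeded generator; identical seeds
  reproduce every table bit-for-bit, and pipeline reruns are byte-identical.

## Problem sizes

The full design is deliberately small (24 scenarios × 14 groups ×
18 indicators; 46 attributes; 15 risks). The test suite and the
reproduction script run the complete design — nothing is down-sampled — and
finish in seconds.

## Known limitations

* The shipped Food Compass cut-points are placeholders; absolute FCS values
  are structural, not comparable to published scores.
* Dietary-risk factor units are declared as data and default to per-gram;
  per-serving alternatives change absolute HENI values.
* Interpolated override rows for unprinted intermediate scenarios are
  approximations of the published ladder.
* No uncertainty propagation anywhere: all inputs are means.
* One representative food per group by default; real-diet heterogeneity
  within groups is out of scope.
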