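# sustdiet

Composite-diet sustainability modelling for plant-forward dietary
transitions: build meat-to-legume substitution scenarios between current,
feasible and optimal anchor diets, score each scenario's nutritional
quality, estimate its environmental footprint, and analyse the
nutrition–environment trade-off.

The package is aimed at nutrition and food-systems researchers who want to
evaluate *composite* daily diets — 14 food groups in fixed mass proportions
over a 1.8 kg day — rather than single foods, and to ask where on a
substitution ladder between today's diet and a life-expectancy-optimal diet
the joint nutrition/environment optimum sits.

## What it computes

**Scenario ladder.** Three anchor diets (current S1, feasible S5 — the
per-group midpoint of current and optimal — and optimal S10) are connected
by seven intermediate scenarios per consumption model. Model M1 replaces
red meat with legumes, M2 red + white meat, M3 red + white + processed
meat, giving 3 shared anchors + 3 × 7 = 24 scenarios. Intermediate
compositions come from an explicit override table (the published ladder is
irregular); a linear 1:1 mass-substitution mode is available as a
documented approximation.

**HENI** (Health Nutritional Index) converts intakes of 15 dietary risk
factors (d_r, per 100 kcal) into minutes of healthy life via DALY-scale
factors from Global Burden of Disease epidemiology:

```
HENI = -0.53 · Σ_r factor_r · d_r      [min per 100 kcal]
```

**Adapted Food Compass Score.** 46 attributes in 7 domains are scored by
monotone cut-point ladders; the raw score is the mean of the six
non-ingredient domain scores plus the sum of the food-ingredient attribute
scores, then rescaled affinely:

```
FCS = 100 − ((26.1 − raw) / 36.7) · 99      (raw 26.1 → 100, raw −10.6 → 1)
```

The shipped cut-point configuration is a documented placeholder with the
correct structure; authoritative cut-points drop in as data.

**Environmental impacts.** Each representative food's mean midpoint impact
per RACC (reference amount customarily consumed) is divided by the RACC
mass to give a per-gram factor; factor × ingredient grams, summed over
ingredients, gives the diet's per-day value for each of 18 midpoint
indicators (global warming short/long term, water use, ionizing radiation,
… total human health damage), also reported per 100 kcal.

**Trade-off statistics.** Pearson correlations, subgroup means with sample
(n−1) SDs, threshold counts, average-rank/Kruskal–Wallis rankings with tie
correction, and Pareto (non-dominated) flags on nutrition-vs-impact axes.

## Worked example

```python
import sustdiet as sd
from sustdiet.io_cli import load_fcs_config

fixtures = sd.load_fixtures()                      # packaged published tables
anchors = sd.generate_anchors()
scenarios = sd.build_scenarios(anchors, schedule=sd.default_schedule())
foods, factors, food_map = sd.generate_foods(sd.SynthConfig(seed=1))

s9m3 = next(s for s in scenarios if s.scenario_id == "S9M3").composition
card = sd.score_diet(s9m3, foods, fixtures.table2, load_fcs_config())
gw = {sid: sd.diet_impacts(
          next(s for s in scenarios if s.scenario_id == sid).composition,
          factors, food_map)["global warming short term"]
      for sid in ("S1", "S9M3")}
```

This prints, on the seed-1 synthetic world:

```
S9M3 legumes: 0.1000 of 1800 g (180 g/day)
scaled FCS (placeholder cut-points): 56.97
HENI: 83.58 min per 100 kcal
global warming S1 -> S9M3: 4.51 -> 2.84 kgCO2 eq/day (36.9% reduction)
published-table FCS-HENI correlation: r = 0.933
```

S9M3 is the scenario with 10 % legumes, 0.11 % red, 0.28 % processed and
2.81 % white meat by mass. On the synthetic world its daily global-warming
footprint is about a third below the current diet's, while both nutrition
scores sit near the top of the ladder — the qualitative trade-off the
scenario design is built to expose. The correlation line is computed from
the packaged published score table, not from the synthetic world.

A CLI wraps the same steps: `sustdiet run --seed 1 --out out/` writes the
24-row score table, the 24 × 18 × 2 impact table and a Pareto-flagged
trade-off series; see `sustdiet --help` for the stage-by-stage subcommands.

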