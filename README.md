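# protsim

Food-replacement scenario simulation and habitual-intake estimation for
two-day 24-h dietary recall surveys.

## The problem

Roughly half of community-dwelling older adults fall short of the expert
recommendation of ≥ 1.0 g protein per kg body weight per day (g/kg BW/d),
a level associated with preservation of muscle mass and function.  One
pragmatic counselling strategy is not to eat *more* but to eat
*differently*: swap commonly consumed low-protein foods for familiar
alternatives that are naturally protein-rich, or for protein-enriched
products, without changing portion sizes.  `protsim` quantifies what such
swaps would do to the population distribution of protein intake, starting
from standard food-consumption-survey data (two non-consecutive 24-h
recalls per participant, a food composition table, and survey analysis
weights).

It is aimed at nutrition epidemiologists and dietetics researchers who
want to prototype and stress-test substitution scenarios before running
an intervention study.

## The model

**Replacement rule (P75 rule).** Within each treated food group *g*, let
P75(*g*) be the 75th percentile (linear interpolation) of the per-item
protein contents (g/100 g) of the group's foods.  Every consumption
record of a food with protein content strictly below P75(*g*) is
rewritten, gram for gram, to the group's designated alternative, whose
protein content must strictly exceed P75(*g*).  Because grams are
preserved, every other nutrient of the record is simply re-read from the
alternative's composition row.

**Eligibility.** Replacements are confined to participants whose baseline
two-day mean intake is strictly below the cut-off *c* (default
1.0 g/kg BW/d); participants at or above *c* are untouched.  Eligibility
is frozen at baseline, so the substitution pass is one-shot and
idempotent.

**Combined scenario.** Given a protein-rich and a protein-enriched
scenario, the combined scenario takes the enriched scenario's top-3
groups by population mean protein gain (with their enriched
alternatives), then walks the rich scenario's ranking from the top,
skipping groups already chosen, until three more are added — six groups
in total.

**Habitual intake.** Two recall days per person overstate the spread of
long-run ("habitual") intake because of day-to-day within-person
variation.  `protsim` removes it with the standard one-part usual-intake
model: Box–Cox transform the pooled daily intakes (exponent λ picked by
profile likelihood on a grid, shift to admit zeros), split the
transformed-scale variance into between-person σ²_b and within-person
σ²_w by closed-form method of moments, shrink each person's transformed
mean *m_i* toward the population mean μ,

    t_i = μ + √( σ²_b / (σ²_b + σ²_w / n_i) ) · (m_i − μ),

and back-transform with a bias correction,
habitual_i = E[ g⁻¹(t_i + e) ] with e ~ N(0, σ²_w), evaluated by 9-point
Gauss–Hermite quadrature.  The fraction of the population below the
cut-off is then a weighted proportion over the habitual values.

**Synthetic surveys.** Because national survey microdata are not
redistributable, a seeded generator produces surveys with the structure
the analysis needs: a nine-group food catalog with lognormal protein
contents, person-level consumption propensities plus day-level noise and
consumption indicators (the two variance sources the habitual model
separates), and a single global grams scalar calibrated by bisection so
that 52.9 % of participants fall below 1.0 g/kg BW/d at baseline.

## Worked example

```
python -m protsim.cli simulate --seed 7 --n 727 --out demo/survey
python - <<'EOF'
import protsim as ps
s = ps.read_survey('demo/survey/composition.csv',
                   'demo/survey/participants.csv',
                   'demo/survey/records.csv')
rich, enriched = ps.default_scenarios(s)
ps.write_scenario(rich, 'demo/rich.yaml')
ps.write_scenario(enriched, 'demo/enriched.yaml')
EOF
python -m protsim.cli run --survey-dir demo/survey \
    --scenario demo/rich.yaml --scenario demo/enriched.yaml \
    --out demo/out
```

prints

```
analysed 727/727 participants (0 excluded, 388 below 1.0 g/kg BW/d)
  original: habitual mean 1.04 g/kg BW/d, 52.0% meeting the cut-off
  protein_rich: habitual mean 1.54 g/kg BW/d, 100.0% meeting the cut-off
  protein_enriched: habitual mean 1.88 g/kg BW/d, 100.0% meeting the cut-off
  combined: habitual mean 1.83 g/kg BW/d, 100.0% meeting the cut-off
```

Reading: of the 727 synthetic participants, 388 start below the
1.0 g/kg BW/d cut-off and are eligible for replacements.  After removing
within-person variance, 52.0 % of the population habitually meets the
cut-off at baseline; replacing low-protein foods with protein-rich
conventional alternatives lifts the habitual mean from 1.04 to
1.54 g/kg BW/d, and the enriched and combined scenarios go further.
`demo/out/` also contains, per scenario, the replacement counts per food
group (TSV), the full substitution audit log (CSV), weighted nutrient
mean ± sd tables (TSV), the derived combined-scenario definition (YAML)
and a JSON summary.

The library surface mirrors the CLI: `generate_survey`,
`apply_scenario`, `count_replacements`, `group_contributions`,
`derive_combined_scenario`, `estimate_habitual_distribution`,
`fraction_below`, and friends — see the module docstrings.

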