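# Methods

This note documents the models and procedures implemented in `protsim`,
the defaults chosen where the design was genuinely open, and what the
synthetic-data validation does and does not demonstrate.

## Data model

A survey is three linked tables.  The composition table holds per-100-g
nutrient contents (protein mandatory; any other nutrient optional, and a
*missing* nutrient raises when requested rather than counting as zero —
silent zeros would corrupt weighted nutrient summaries).  The participant
table holds body weight (kg) and an analysis weight correcting for
socio-demographic, day-of-week and seasonal imbalance; weights are taken
as supplied, the package does not construct them by raking.  The
consumption table holds grams as consumed per participant, recall day and
food.  Participants with unknown body weight are retained but flagged
excluded: they stay visible for audit, and every analysis operation
refuses them.  Day declaration is separate from records so that a recall
day with zero consumption is distinguishable from an undeclared day.

Daily protein density is Σ grams × protein/100 g divided by body weight
(g/kg BW/d); the participant's baseline value is the arithmetic mean of
the two days.

## Replacement engine

* **P75 threshold.** Per treated group, the 75th percentile of per-item
  protein contents, computed with the linear-interpolation definition
  (sorted values x(1..n), position 1 + 0.75(n−1)).  The default basis is
  the composition table's items for the group, each counted once and
  unweighted by consumption — the simplest reading of a percentile "of
  the protein contents in that food group".  A `consumption` basis
  (restrict to the distinct foods actually consumed in the survey) is
  available as a flag, since in practice thresholds are sometimes defined
  over the consumed set.
* **Strictness.** Foods strictly *below* P75 are replaced; alternatives
  must be strictly *above* P75.  An item exactly at the threshold is
  never replaced, so a group whose items all share one protein value
  yields zero replacements.
* **Eligibility** is strict (< cut-off) and evaluated once on the
  original survey; replacements never cascade.  Together with the
  alternative-above-P75 rule this makes the pass idempotent: re-applying
  a scenario to its own output changes nothing.
* **Accounting.** Each substitution is logged (who, day, group, from/to
  food, grams, protein delta).  Group contributions are reported as the
  analysis-weighted population mean protein gain in g/d over *all*
  non-excluded participants on the two-day-average basis; the sum over
  groups equals the change in the population mean protein intake.  Ties
  in the contribution ranking break lexicographically by group label so
  the combined-scenario derivation is deterministic.
* **Combined scenario** = enriched scenario's top-3 contributing groups
  (keeping the enriched alternatives) plus the next three groups of the
  rich scenario's ranking not already chosen (keeping the rich
  alternatives); exactly 2k groups for general k, error if fewer are
  available.
* **Nutrient summaries** use the weighted mean and the weighted
  *population* standard deviation (denominator Σw) over non-excluded
  participants' two-day average intakes.

## Habitual-intake estimator

A one-part shrinkage model in the style of usual-intake programs such as
SPADE — "SPADE-style", not SPADE-exact: the published description of that
software does not pin down its transformation and age-modelling choices,
so this module implements the standard estimator and says so.  Protein is
consumed daily by essentially everyone, so no episodic (two-part)
component is needed.

1. **Transform.** Box–Cox exponent λ from the grid {0, 0.1, …, 1},
   chosen by maximising the Box–Cox profile log-likelihood of the pooled
   daily values (scipy's `boxcox_llf`).  The grid keeps selection
   deterministic and reproducible; the likelihood is flat enough near its
   maximum that finer resolution changes nothing material.  Shift = 0
   when all values are positive, else half the smallest positive value.
   At least 20 positive values are required.
2. **Variance components.** Closed-form method of moments, exact for the
   balanced two-day design: σ²_w = mean over persons of (d₁ − d₂)²/2
   (equivalently the pooled within-person variance), σ²_b = max(0,
   sample variance of person means − σ²_w · mean(1/nᵢ)).  Verified in the
   tests against a REML mixed-model fit (statsmodels `MixedLM`), which it
   matches to ~1e-3 relative on balanced data.  An iterative ML fit was
   deliberately not made the default: the closed form is exact here,
   transparent, and trivially testable.
3. **Shrinkage.** tᵢ = μ + cᵢ(mᵢ − μ), cᵢ = √(σ²_b/(σ²_b + σ²_w/nᵢ));
   σ²_b = 0 collapses everyone to μ.
4. **Back-transformation.** habitualᵢ = E[g⁻¹(tᵢ + e)], e ~ N(0, σ²_w),
   by 9-point Gauss–Hermite quadrature.  Order 9 integrates the
   polynomial part exactly to degree 17 and matches a 10⁶-draw
   Monte-Carlo integral to better than 1e-3 relative at the noise levels
   arising here; for λ = 0 it reproduces the lognormal-mean closed form
   exp(t + σ²_w/2) to 1e-6 relative.  Arguments outside the Box–Cox
   domain (λt + 1 < 0) are clipped to the boundary and results floored at
   0.  This correction is what keeps the population mean of the habitual
   estimates within ~2 % of the mean of the raw person means; naively
   inverting the transform does not (regression-tested).

The estimator runs on the full non-excluded population, including
participants above the cut-off — scenarios restrict who is *replaced*,
not whose habitual intake is *estimated*.  Fraction-below supports both a
per-kg mode (daily values already divided by body weight, the pipeline
default) and a g/d mode (divide the habitual g/d values by body weight at
the end); the two differ only through the transform's interaction with
the body-weight division and agree closely in practice.

## Synthetic survey generator

The generator emulates the structure of a national older-adult
food-consumption survey: 727 participants by default, exactly two
declared recall days, body weight ~ N(75, 12²) kg truncated at 40, and a
nine-group catalog (bread; yoghurt, cream desserts and pudding; potatoes,
vegetables and legumes; non-alcoholic beverages and milk; soups; savoury
spreads, sweet spreads and cheese; meat and fish; cereals; fruit) with
eight conventional foods per group.  Protein contents and consumed
amounts are lognormal — non-negative and right-skewed like real intake
data; the group medians (e.g. bread ≈ 9 g/100 g and ≈ 110 g/d; meat and
fish ≈ 19 g/100 g and ≈ 100 g/d) are ordinary food-composition values for
these groups.  Consumption is driven by a per-person lognormal propensity
(between-person variance), day-level multiplicative noise whose log-sd is
`within_person_day_sd_multiplier` × the group's between-person log-sd
(default multiplier 1), and an independent per-day consumption indicator
— together the two variance sources the habitual estimator must separate.
Each group also gets one manufactured protein-enriched product (protein
1.6 × the group's conventional maximum, so it clears any P75 by
construction); enriched products sit in the composition table but are
never generated as consumed, mirroring products that are available but
not yet part of the diet.

A single global grams scalar is calibrated by bisection (geometric
midpoint, tolerance 0.005 on the fraction, cap 40 iterations) so that
52.9 % of participants fall below 1.0 g/kg BW/d at baseline — one
interpretable, provably monotone knob.  Everything is reproducible from
the seed down to the written CSV text.

The generator does **not** emulate seasonality, day-of-week structure,
correlated food choices within meals, under-reporting, or realistic
marginal distributions of nutrients other than protein.  Passing tests
therefore demonstrate that the engine and estimator are correct and
well-behaved under the stated statistical structure — not that any
particular population's numbers would be reproduced.

The known-habitual cohort (`generate_known_habitual_cohort`) is a
separate harness: true habitual values Hᵢ are lognormal and observed days
are Hᵢ × unit-mean lognormal noise, so estimator output can be compared
with known truth.  At n = 5000, two days, habitual log-sd 0.25 and
within-person log-sd 0.35, the estimator recovers σ²_w within 5 % and the
fraction below the true median within ±0.02.

## Problem sizes and defaults

Tests and the acceptance script run at the cohort's natural size
(n = 727) or, for estimator-recovery checks, n = 5000 persons × 2 days;
oracle-equivalence checks use 200 random surveys of ≤ 10 participants.
The full suite completes in a few seconds.  Default cut-off 1.0 g/kg
BW/d; default percentile basis `items`; default per-kg habitual mode.

## Known limitations

* No energy-compensation or satiety modelling: gram-preserving
  substitution can raise energy intake moderately, and the model does not
  rebalance the rest of the diet.
* No bootstrap uncertainty intervals on the habitual distribution.
* No age-covariate modelling in the habitual estimator.
* The weighted sd uses the population formula; with strongly informative
  weights and tiny n it is biased low relative to a design-based
  estimator.
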