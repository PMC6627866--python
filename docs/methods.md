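# Methods

## Scope and model of the domain

The package operates on a food-composition database of *single* items
(nutrient values assigned directly, per 100 g edible portion) and
*composite* items (values derived from a recipe over other items).  Both
kinds can appear as ingredients of further composites, so the database forms
a directed acyclic graph whose leaves are single items.  Carried nutrients
are the ones the sugars procedure needs: monosaccharides, disaccharides,
total sugars (their sum, enforced to 1 × 10⁻⁶ g), analytical fructose
(optional), and energy in kJ.

A deliberate representation choice: **missing fructose is absent, not
zero**.  The fructose-subtraction step requires an analytical fructose
value; an item without one is ineligible for that step rather than treated
as fructose-free.

## Recipe resolution

Per-100 g values of a finished composite are the yield-adjusted mass
balance

    nutrient = Σᵢ (raw_weightᵢ × nutrientᵢ / 100) / batch_post_weight × 100 ,

resolved bottom-up in lexicographically tie-broken topological order with
memoisation, so an item shared by many composites is computed once.
Cooking losses are modelled solely through the post-cooking batch weight
(water loss); sugar retention is 1.0 — the simplest defensible default in
the absence of published retention factors for sugars.  A post-weight above
the raw weight is only accepted as explicit water addition.
`flatten_to_singles` expands any item to its single-item leaves and serves
as an independent oracle: the flattened weighted sum must reproduce the
recursive resolution to 1 × 10⁻⁹ g/100 g, which the test suite checks on
100 random DAGs of depth ≤ 4.

## The ten-step procedure

Each item receives one step and one content value per sugar type (added,
free).  Single items route through steps 1–3, 5–8 and 10, in ascending
order, taking the first applicable rule; composites receive step 4 when all
components sit in steps 1–4 and step 9 otherwise, with recipe-weighted
content.  The rules are driven entirely by category, flags and
config-supplied data — never by name matching — so the procedure is total
and deterministic:

1. no sugars → 0;
2. sugars entirely intrinsic (raw fruit and vegetables, plain dairy, plain
   meat/fish, fats/oils, pseudocereals; also fruit juice, honey and syrup
   on the *added* side, and vegetable juice on both sides) → 0;
3. all sugars added/free → total sugars (fruit juice, honey and syrup land
   here on the *free* side);
5. sweetened item minus its unsweetened counterpart, clamped at 0;
6. total sugars minus analytical fructose for fruit/vegetable-containing
   items, clamped at 0 (only fructose is subtracted; other intrinsic sugars
   are deliberately not accounted for, so step-6 estimates can be slight
   overestimates);
7. override values from manufacturer/recipe information, supplied as data
   (`ProcedureConfig.override_map`);
8. proportional scaling from a comparable reference item
   (`proportional_reference_map`; reference chains are resolved in
   dependency order and must be acyclic);
10. border-case fallback: 50 % of total sugars (a configurable fraction).

Steps 1–6 are objective, 7–10 subjective; the step-distribution table
reports the objective fraction rounded to integer percent and per-step
percentages to one decimal (half-up rounding, matching how such tables are
conventionally printed).

Definition switches live in `ProcedureConfig`: counting honey as added
sugars, counting vegetable-juice or fruit-purée sugars as free sugars
(both off by default, matching the strict added-sugars definition and the
WHO free-sugars definition with vegetable juices excluded), and the bread
threshold.  Sweetened/cured/pickled products are a category of their own
routed to step-3 semantics (all sugars added) unless a counterpart enables
step 5 — the conservative mapping.

**Bread rule.** Plain breads are checked rather than assumed sugar-free:
if a dough batch carries strictly less than 9 g added sugars per 1000 g
pre-baking weight (threshold configurable), the added sugars are
discounted.  The boundary value itself is *not* discounted (strict
inequality).  The discount zeroes free sugars as well: the discounted
sugars are the added sucrose itself, and the precursor convention treated
such breads as non-sugars-containing outright.  In `assign_and_estimate`
the rule is applied automatically to plain-bread composites, whose recipe
supplies the pre-baking weight; `bread_rule` is also exposed directly for
callers holding batch data for single items.

Step 10 acts as an automatic catch-all so the procedure is total; setting
`step10_fallback=False` turns an unmatched item into a hard error, which is
useful for auditing a database's coverage.

Every estimate satisfies `0 ≤ added ≤ free ≤ total`: free sugars are a
superset of added sugars under the default definitions, and the procedure
validates the invariant on output rather than assuming it.

## Intake pipeline

Daily intakes are the standard recall-to-nutrient join: grams consumed ×
per-100 g value, summed per participant-day.  Energy percent uses 17 kJ
per gram of sugars (the EU/NNR carbohydrate convention; configurable,
since surveys differ).  Stratified summaries report medians and quartiles
(linear interpolation between order statistics — declared because p25/p75
are convention-sensitive) of g/day and E% by school year × sex plus an
overall row (10 rows for three school years), threshold adherence as the
share of participants strictly below 10 %E and 5 %E rounded to integer
percent, and a two-sided Mann–Whitney U comparison of girls vs boys within
each stratum (exact when both groups have ≤ 20 observations without ties,
normal approximation with tie correction otherwise).  E% is computed per
individual and then summarised — the standard practice — rather than as a
ratio of medians.

## Usual-intake model

Two recall days per person cannot separate day-to-day noise from true
between-person differences by averaging: the two-day-mean distribution has
tails that are too wide.  The model is an amount-only usual-intake
adjustment (everyone is treated as a consumer, which is the realistic
assumption for sugars; zero reporters are handled by an offset of half the
smallest positive value before transforming, subtracted after
back-transforming):

1. **Transform.**  Box-Cox with λ from the coarse grid
   {−1, −½, 0, ⅓, ½, 1} (0 = log), chosen by the standard profile
   log-likelihood; a coarse grid is stable with only two days per person.
2. **Day-class effect.**  A weekday/weekend (Monday–Thursday vs
   Friday–Sunday) fixed effect is removed by OLS on the transformed scale;
   predictions add it back averaged over the week's 4/7–3/7 composition.
3. **Variance components.**  One-way random-effects method-of-moments
   (ANOVA) estimators on the adjusted values; negative between-person
   moment estimates are clamped to zero with a warning.  A cohort in which
   every participant has a single day leaves σ²_w unidentifiable and is an
   error.
4. **Shrinkage.**  Each person's transformed mean is pulled toward the
   population mean.  The classical factor
   σ²_b/(σ²_b + σ²_w/nᵢ) is the best predictor of an *individual's*
   long-term mean, but the resulting collection of predictions has
   transformed-scale variance factor × σ²_b < σ²_b, i.e. it
   over-contracts the population spread, which biases percentile summaries
   (after mean calibration, medians shift up by ≈ exp((1−factor)σ²_b/2)).
   Since the pipeline's deliverable is the population distribution
   (medians, quartiles, threshold shares), `predict()` defaults to
   *distribution-preserving* scaling — the square root of the factor —
   which restores between-person variance σ²_b exactly;
   `predict(kind="individual")` gives the classical predictor.  The two
   coincide as nᵢ grows or σ²_w → 0, so the limit properties (habitual →
   person mean) hold for both.
5. **Back-transform.**  Inverse Box-Cox followed by a smearing-style ratio
   calibration: all habitual values are rescaled by one constant so their
   population mean equals the observed mean on the original scale.  This
   preserves the mean exactly (the raw-data average is the one quantity
   two days estimate without bias) while leaving location-free shape
   intact.

Contracts verified by the tests: variance of habitual values ≤ variance of
raw person-means with equality iff σ²_w = 0; tail width (p95 − p5) never
larger than the raw means'; population mean preserved within 1 %; at 50
days per person the habitual values converge to person means; habitual
values track simulated true long-term means better (lower MSE) than raw
two-day means.

## Synthetic data generator

`generate_food_db` emulates the shape of a national food-composition
database: 844 single and 639 composite items by default, composites
arranged in a DAG of depth ≤ 4, category shares chosen to resemble a
general-purpose database (raw produce and plain staples dominating, with
sweetened categories, juices, honey/syrup and a pickled-sweetened group
represented).  Every item carries analytically planted truth — the
added/free content a correct procedure must produce — computed from the
category semantics independently of the estimator, which is what makes the
end-to-end recovery test meaningful.  About one composite in twenty is a
plain-bread dough with sucrose alternately below and above the discount
threshold, so both branches of the bread rule occur.  Step-7 overrides and
step-8 references are emitted in the returned `ProcedureConfig`, closing
the synthetic world.

`generate_survey` emulates a two-day school survey: 3099 participants by
default in the strata 559/490, 574/476 and 577/423 girls/boys across three
school years.  Daily totals per nutrient follow a lognormal model with
log-scale parameters (μ, σ²_b, σ²_w) per nutrient — defaults chosen so
habitual medians land near 51/59/100 g/day of added/free/total sugars and
≈ 10/12/20 %E at ≈ 8200 kJ/day, with σ²_b = 0.16 and σ²_w = 0.25 for the
sugar nutrients (day-to-day noise larger than between-person spread, as is
typical for sugars) and 0.05/0.12 for energy.  The three sugar nutrients
share their person and day standard-normal draws, which makes
added ≤ free ≤ total hold exactly while each nutrient keeps its configured
variance components; energy is correlated with the sugars at ρ = 0.6.  A
multiplicative weekend effect (default 1.1) applies to the sugar nutrients;
each day is weekend with probability 3/7.

Day totals are drawn first and then realised *exactly* as food records:
random garnish foods (rescaled to consume at most half of every target
margin) plus four staple foods solved by back-substitution — sugar for the
added target, fruit juice for the free-only margin, fruit for the intrinsic
margin, oil for the residual energy.  The variance structure of the records
is therefore exact by construction.  The one exception: a drawn energy
total below the energy the drawn sugars themselves carry is physically
unrealisable; such rare tail days (< 0.5 % at the defaults) have the
energy raised to the feasible floor, recorded in
`records.attrs["realization_deviations"]`.  The generator also returns each
participant's true long-term mean intake (the analytic expectation over day
residuals and week composition) for recovery tests.

**What the synthetic data does not emulate.**  Real food selection
behaviour (days are staple-dominated baskets, not realistic menus), brand-
or item-level heterogeneity of real databases, seasonality, misreporting,
survey weights, and correlation between a person's food choices and their
intake level.  Passing tests therefore demonstrate that the procedure and
pipeline compute what they claim on data with known structure — not that
any particular population's intake is as simulated.

## Numerical conventions

* File numerics are 6-decimal fixed point, columns in fixed order, UTF-8,
  LF endings — write → load → write is byte-stable.
* Ties in the resolution order are broken lexicographically by item id;
  recipe cycles raise an error naming the cycle.
* Subtraction steps clamp negative results to zero and log the clamp in the
  estimate's notes.
* Rounding of reported percentages is half-up (away from the
  round-to-even surprises of binary floats).
* Every stochastic routine takes its seed from a single config field;
  identical configs give byte-identical outputs.

## Problem sizes used in the checks

Desk checks on the published step-count columns are exact arithmetic.  The
synthetic recovery checks run at the study's scale — 3000 participants ×
2 days — on an 80 + 40-item database; procedure invariants are checked on a
1000-item database; the recipe oracle on 100 random DAGs.  All complete in
seconds.

## Known limitations

* The step semantics for the subjective steps (7, 8, 10) are data-driven
  stubs of what is, in reality, a human workflow (label averaging, cookbook
  recipes); the package deliberately models only the arithmetic, with the
  human inputs arriving as config data.
* The fructose step subtracts fructose only; glucose naturally present
  alongside it is not subtracted, so step-6 estimates can overestimate
  added/free sugars slightly.
* The usual-intake model is amount-only: no consumption-probability part,
  no covariates beyond day class, no uncertainty intervals on habitual
  values.
* Composite fructose is propagated only when every ingredient carries an
  analytical value; otherwise it is absent (composites never need it, as
  they route through steps 4/9).
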