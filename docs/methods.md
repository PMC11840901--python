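# Methods

## Model structure and assumptions

The simulator is a discrete-time (monthly) system dynamics model of a group
of children who share a social norm about body weight. Two reinforcing
feedback loops connect the norm to behaviour — a higher perceived-normal BMI
raises each child's individual ideal BMI, which lowers their intent to be
active and raises their intent to eat, which raises weight and hence the
group median feeding back into the norm — and one balancing loop reflects
that a heavier body spends more energy at rest.

Key structural choices, all deliberate:

* **Synchronous updates.** Every child advances from the common month-t
  state; the group median and all perceived norms are recomputed only after
  every child has moved. Trajectories are therefore invariant to child
  ordering (property-tested).
* **Behaviour anchored at baseline.** Activity level and intake respond to
  the *current* discrepancy from baseline values (PAL₀, TDEI₀), not to their
  own previous values; the discrepancy, not its history, drives behaviour.
* **Deliberate index mix.** Expenditure for month t+1 uses the month-t BMR
  with the month-t+1 activity level, exactly as in the model's
  difference-equation form.
* **Frozen anthropometry.** Height and the age bracket of the BMR equation
  are fixed at baseline; the model's time axis is indicative (what matters
  is the stable state the group settles into), so no growth or birthday
  handling is attempted.
* **Energy-to-weight conversion.** One kg of body weight ⇔ 7700 kcal; a
  month is 365/12 days. The resulting monthly factor is exactly 73/18480 kg
  per (kcal/day), an identity the test suite asserts in double precision.
* **Child BMR.** Linear functions of weight by gender and age bracket
  (boys 3–9: 22.706·W + 504.3; boys 10–18: 17.686·W + 658.2; girls 3–9:
  20.315·W + 485.9; girls 10–18: 13.384·W + 692.6), kcal/day.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `intent_pab` | +0.05 | PAL per kg/m² | activity response to discrepancy |
| `intent_eb` | −50 | kcal/day per kg/m² | intake response to discrepancy |
| `w_hb` | scenario | — | weight of healthy-BMI knowledge in the ideal |
| `kcal_per_kg` | 7700 | kcal/kg | energy density of weight change |
| `days_per_month` | 365/12 | days | monthly time step |
| `pal_floor` / `tdei_floor` | 1.0 / 500 | — / kcal/day | behavioural floors |

The two intent parameters are calibration knobs: they are not printed in the
source material and are chosen so that one BMI unit of discrepancy moves
behaviour by a plausible fraction of its range (≈3% of PAL; ≈2.5% of
intake). The sign convention is fixed — positive discrepancy (heavier than
one's ideal) raises activity and lowers intake. The floors exist only to
prevent unphysical divergence under extreme parameter settings; floor events
are counted on the trajectory and logged, and never trigger under default
settings. All arithmetic is double precision with no rounding inside the
loop; BMI values are rounded (1 dp) only for display.

With the defaults, a 36-month run is effectively at its steady state: the
linearised per-month contraction rate is roughly 0.2–0.3, a time constant of
about four months.

## Scenarios and metrics

Presets mirror the interface the model was built for: `do_nothing`
(w_hb = 0), `individual_intervention` (w_hb = 0.5), `combined_intervention`
(w_hb = 1.0), and `behaviour_change` (w_hb = 0 plus the school buttons:
+0.175 PAL for one extra hour of exercise and −200 kcal/day for one less
snack, adhered to by exactly one in four children, drawn uniformly without
replacement and fixed for the run). Low/medium/high-intensity variants
(exercise only, snack only, both) are exposed as `INTERVENTION_BUTTONS`.

`delta_bmi` is the baseline median minus the final median (positive =
improvement). The effectiveness diminishment 100·(1 − Δind/Δcomb) is
reported per community and averaged with equal weights; it requires a
strictly positive combined effect and is otherwise an error, not a number.

Confidence intervals are 95% percentile bootstrap over children (the
natural resampling unit), default B = 1000, seeded. Adherence is resampled
inside each replicate because it is part of the scenario, not of the data.
The point estimate is not re-centred; on a homogeneous population the
interval collapses to zero width (tested).

## Synthetic populations

Real child-level calibration data are not redistributable, so populations
are synthesised from the printed per-community descriptives (six communities
of n = 155, 208, 43, 156, 201, 322; pooled n = 1085), shipped as a packaged
CSV. Construction per community:

* **Gender** Bernoulli(0.5) (split not printed).
* **Age** on {8..13} years, weights from a discretised-normal family
  grid-searched to the printed median/IQR.
* **BMI** log-normal. The printed quantiles are not exactly log-normal-
  consistent, so the median is anchored exactly (μ = ln median) and σ is the
  least-squares compromise between the two IQR endpoints on the log scale;
  an unweighted three-quantile fit would shift the pooled median by
  +0.24 kg/m², defeating the generator's purpose. Draws use randomized
  stratified inverse-CDF sampling (a 1-D Latin hypercube): marginals are
  exactly the fitted distribution, but sample quantiles track it tightly
  even at n = 43 — the printed marginals are targets to reproduce, not
  parameters to add sampling noise to. Draws are truncated to a plausible
  child range (12–35 kg/m², configurable): the stratified scheme otherwise
  forces one draw deep into the left tail (BMI < 10).
* **Height** growth-reference median for age and gender times log-normal
  noise (CV 4%); **weight** = BMI·H². The embedded height and BMI-for-age
  tables are approximate reference medians, clearly labelled as such.
* **Activity level** binary 1.46/1.7 at the printed low fraction.
* **Weight perception** three levels with counts exactly `round(f·n)` from
  the printed discrepancy-sign fractions, assigned by cutting a latent score
  rank-correlated with BMI (Gaussian copula, correlation 0.5 by default) so
  heavier children tend to feel "too heavy". The printed table gives no
  joint distribution; the single correlation knob makes that assumption
  explicit and adjustable.
* **Sociocultural ideal BMI** equals BMI where perception is "about right"
  (discrepancy exactly 0 — bit-exact, which requires deriving SCIB from the
  stored weight/height rather than the pre-rounding BMI draw), otherwise
  offset below/above by a half-normal deviation (scale 1.5 kg/m²).
* **Healthy BMI** BMI-for-age reference median (constant override
  available); **baseline intake** = BMR·PAL (baseline energy balance).

The pooled run is the concatenation of the six communities relabelled as a
single norm-sharing group.

What the generator does *not* emulate: the real joint distribution of the
measurements (only printed marginals and one declared correlation), secular
age/height growth, measurement error, school- or family-level clustering,
and the original study's supplementary derivations of PAL, SCIB, healthy BMI
and intake (re-specified here as the declared, swappable rules above).
Passing tests therefore show that the *model and pipeline* behave correctly
under populations with the printed marginal structure — not that the
synthetic children are exchangeable with the real cohort.

## Numerical and degenerate-input choices

* Even-sized groups use the conventional median (mean of the middle two).
* A non-positive weight aborts the run with an error naming the child and
  month; an empty group, an out-of-range norm weight (outside [0, 1]) and
  ages outside 3–18 are errors.
* `months = 0` returns the baseline median only; a population at its fixed
  point (discrepancy 0 and intake = expenditure everywhere) reproduces
  itself exactly.
* All randomness flows through seeded `numpy` generators with independent
  spawned sub-streams per attribute, so changing one generator knob does not
  reshuffle unrelated attributes.

## Problem sizes used in the shipped analyses

The analysis scripts and the acceptance script run the six communities
(1085 children) for 36 months — seconds of CPU. The headline figure is
averaged over 8 generator replicates (its per-replicate value varies by
roughly ±2 percentage points through the perception/SCIB sampling);
generator-fidelity percentages average 20 seeds; bootstrap CIs in the
analysis scripts default to 200 replicates (1000 via the CLI default).

## Known limitations

* The intent parameters are declared defaults, not estimates; conclusions
  about effect *sizes* (as opposed to orderings) inherit their uncertainty.
* The social norm operates within whole communities; no within-community
  network or peer-group structure.
* Behavioural responses are linear and memoryless in the discrepancy;
  floors are the only nonlinearity.
* The model reaches a steady state by construction; it cannot represent
  oscillating or drifting norms.
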