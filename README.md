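# normsim

Social-norm / energy-balance system dynamics simulation of group-level
childhood BMI.

`normsim` is for public-health modellers who want to ask *what-if* questions
about childhood obesity prevention in small communities: what happens to a
community's median BMI if children act on knowledge of a healthy BMI, if the
unhealthy social norm around body weight is dismantled, or if a school adds
an hour of exercise and removes a snack for the children who take part? The
package couples a per-child monthly energy-balance model to a group-level
social-norm feedback and ships a synthetic-population generator calibrated
to printed community descriptives, a scenario engine with bootstrap
confidence intervals, and a three-command CLI.

## The model

Each child carries fixed baseline attributes (gender, age, height H,
baseline activity level PAL₀, baseline intake TDEI₀, sociocultural ideal BMI
SCIB, healthy-BMI knowledge HB) and evolves monthly. Writing Norm_t for the
child's perceived norm and MedianBMI_t for the group median:

    IIB_t      = w_hb · HB + (1 − w_hb) · Norm_t        individual ideal BMI
    D_t        = BMI_t − IIB_t                          discrepancy
    PAL_{t+1}  = PAL₀  + Intent_PAB · D_t               activity response
    TDEI_{t+1} = TDEI₀ + Intent_EB  · D_t               intake response
    TDEE_{t+1} = BMR_t · PAL_{t+1}                      expenditure
    W_{t+1}    = W_t + (TDEI_{t+1} − TDEE_{t+1}) · (365/12) / 7700
    BMI_{t+1}  = W_{t+1} / H²
    BMR_{t+1}  = a·W_{t+1} + b                          child equations, by
                                                        gender and age bracket
    MedianBMI_{t+1} = median over children of BMI_{t+1}
    Norm_{t+1} = (MedianBMI_{t+1} + SCIB) / 2

All children update synchronously from the common month-t state; the median
and norms are recomputed afterwards. The norm weight w_hb ∈ [0, 1] is the
scenario lever: 0 leaves the ideal BMI entirely to the (possibly unhealthy)
social norm, 0.5 activates healthy-BMI knowledge (the individual-level
intervention), 1 additionally deactivates the norm (the combined
individual + social-environment intervention). School-based behaviour
buttons add +0.175 PAL (one hour of exercise) and/or −200 kcal/day (one less
snack) for a randomly adherent quarter of children.

The headline comparison metric is the *effectiveness diminishment*
100 · (1 − ΔBMI_individual / ΔBMI_combined), where ΔBMI is the
baseline-minus-final group-median BMI of a 36-month run: the share of the
achievable improvement that an unhealthy norm takes back.

## Worked example

```bash
python analysis/01_generate_populations.py --seed 1
python analysis/02_scenario_trajectories.py --seed 1
python analysis/03_compare_interventions.py --seed 1 --reps 200
```

The first script generates the six synthetic communities (1085 children)
from the packaged printed marginals and reports fidelity, e.g.

```
community          n   BMI med (tgt)    PAL1.46% (tgt)    disc=0% (tgt)
community_1      155    18.86 (18.8)       64.5 (69.0)      61.9 (61.9)
community_3       43    18.21 (18.1)       79.1 (76.7)      81.4 (81.4)
```

(generated median BMI within ~0.1 kg/m² of target; the zero-discrepancy
fraction is exact by construction). The second runs the four scenarios on
the pooled group:

```
do_nothing                 median BMI 18.36 -> 18.40 (delta -0.03 kg/m^2)
behaviour_change           median BMI 18.36 -> 17.47 (delta +0.89 kg/m^2)
individual_intervention    median BMI 18.36 -> 17.67 (delta +0.69 kg/m^2)
combined_intervention      median BMI 18.36 -> 17.21 (delta +1.16 kg/m^2)
```

Doing nothing leaves the median drifting with the unhealthy norm; the
combined intervention roughly doubles the improvement of the individual one.
The third script quantifies that per community and prints the headline:

```
Unhealthy social norms diminish the individual-level intervention's
effectiveness by 41.7% on average across the six communities.
```

The same pipeline is available as a CLI (`normsim generate`,
`normsim simulate`, `normsim compare`); see `normsim --help`.

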