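# beeforage

Does being a fast learner pay off for a foraging bumble bee?  This
package implements a complete, testable pipeline for studies that
assess the visual learning performance of individual *Bombus
terrestris* workers in the laboratory and then follow the same bees'
free-foraging careers in the field with RFID tagging and a
weighing-station at the nest entrance.  It is aimed at behavioural and
cognitive ecologists who want the full chain — learning-curve fitting,
bout detection, collection-rate estimation and information-theoretic
model comparison — as reusable, tested code, together with a synthetic
cohort generator so every stage can be validated without field data.

## The analysis

**Learning performance.**  In the assay a bee makes 100 sequential
choices between blue (unrewarding, innately preferred) and yellow
(sucrose-rewarding) artificial flowers.  Choices are aligned to the
first yellow flower the bee feeds from, errors (blue choices) are
counted per block of 10 choices, and a first-order decay curve

> y = y₀ + A·e^(−x/t)

is fitted by bounded least squares: y₀ is the saturation error level,
A the amplitude, and t the decay constant (learning speed).  A single
Learning Performance Index (LPI) sums the curve-predicted errors at 5,
50 and 100 choices, each clamped to [0, 10], so LPI ∈ [0, 30]; low LPI
means a fast learner.

**Foraging career.**  A nest-entrance RFID reader records "out" and
"in" events; an out paired with the next in is a foraging bout (bouts
shorter than 2 min are treated as entrance loitering).  Bees completing
more than five bouts are foragers.  Per bee the pipeline computes days
foraged, mean bouts per day and mean bout duration, and — from
weighing-station observations matched to bout boundaries — nectar
collection rate ((mean incoming − mean outgoing mass)/mean trip
duration, mg/min, over pollen-free bouts) and pollen collection rate
(mean ordinal load score 1–4 divided by mean trip duration), each
requiring at least three observed bouts.

**Model comparison.**  For each of the five responses a basic model
(intercept + colony random intercept) is compared by AICc,

> AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1),

against single-covariate models (colony age, worker age, worker mass,
and experience for the collection rates); learning performance is then
added to the best model and judged predictive only if ΔAICc > 2.  Days
foraged uses a Poisson GLMM with log link; bouts per day and bout
duration are square-root transformed Gaussian mixed models; rates are
Gaussian.  All fits are maximum likelihood: the Gaussian marginal
likelihood is profiled in closed form, and the Poisson random intercept
is integrated by adaptive Gauss–Hermite quadrature (cross-checked
against lme4's `glmer`).

## Worked example

Simulate a full study (5 colonies, 15–21 tested bees each, with the
default effect structure: LPI +0.06 per unit on log days foraged,
colony-age effects on bouts/day and duration, no LPI effect on
collection rates) and run the whole analysis:

```sh
$ beeforage simulate --seed 4 --outdir sim
wrote 91 bees, 9505 RFID events, 910 observation records to sim
$ beeforage report --indir sim
nectar_rate: LPI does_not_predict
pollen_rate: LPI does_not_predict
days_foraged: LPI predicts
mean_bouts_per_day: LPI does_not_predict
mean_bout_duration: LPI does_not_predict
tables written to sim
```

The five `model_table_<response>.csv` files hold the AICc comparison
(model, AICc, ΔAICc, k, estimates ± SE, best-model flag).  For this
seed the days-foraged table shows the basic model at AICc 337.81 and
basic + LPI at 305.27 — adding learning performance lowers AICc by far
more than 2, so slower learners (higher LPI) foraged on more days,
while collection rates and daily effort show no learning effect.
`descriptives.csv` carries the supporting statistics; here the LPI
differs among colonies no more than chance would produce (one-way
ANOVA F(4,86) = 1.49, P = 0.21) and LPI correlates positively with the
decay constant t (Spearman ρ = 0.20).

The same stages are importable directly (`beeforage.simulate_study`,
`score_cohort`, `extract_bouts`, `compute_efficiency`,
`compare_candidates`, ...) for scripted use.

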