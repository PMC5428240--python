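# Methods

This note documents the models, the defaults and the numerical choices
behind `beeforage`, and what the synthetic-data tests do and do not
establish about real field data.

## Learning curves and the LPI

Choice sequences are aligned at the first yellow flower the bee feeds
from ("probes"); everything before and including that probe is
discarded.  Aligned choices are partitioned into consecutive full
blocks of 10 (a trailing partial block is dropped), errors = blue
choices per block, and the block abscissa is its midpoint: x = 5, 15,
…, 95 for a 100-choice record.  Midpoint placement makes the first
block's abscissa coincide with the first LPI evaluation point (x = 5).
Whether the original assay scored blocks at midpoints or endpoints is
not documented anywhere we could check; the convention is a package
choice, and `align_and_bin` takes `bin_size` as a parameter.

The decay curve y = y₀ + A·e^(−x/t) is fitted by bounded least squares
(`scipy.optimize.curve_fit`, trust-region reflective) with y₀ ∈ [0, 10],
A ∈ [−10, 10], t ∈ (0, 10·n_choices].  Initialisation: y₀ from the mean
of the last two blocks, A from the first block minus y₀, and a
multi-start over t₀ ∈ {5, 20, 80}; the lowest-RSS start wins.  If every
start fails the bee is marked unfittable and excluded downstream, with
a reason code, rather than raising.  Constant block data short-circuit
to (y₀ = c, A = 0, t = missing) — the smallest-|A| member of the
degenerate solution family — with zero residual.

LPI = Σ_{x ∈ {5,50,100}} clamp(ŷ(x), 0, 10).  Clamping each evaluation
to one block's error ceiling is what bounds the index to [0, 30] for
*any* admissible parameters, including negative amplitudes; the bound
is a structural guarantee, not an empirical one.  Evaluations at x = 50
and 100 use the smooth fitted curve, not block data.

**Identifiability caveat.**  Ten binomially noisy block counts identify
y₀ and A well but t only coarsely.  With cohorts drawn from the
generator's default latent distributions and true t ∈ [10, 50], the
median relative error of t̂ is ≈ 0.34 — and an exhaustive bounded
global least-squares search (fine t grid with the conditionally linear
(y₀, A) solved exactly) achieves the same, so this is an information
limit of the design, not an optimiser artefact.  Only cohorts pinned
near the maximal-amplitude corner (y₀ ≈ 0, A ≈ 10) push the median
error below 0.2.  Consequently LPI — which weights the whole curve —
is far more stable than t (rank correlation with true values ≈ 0.93
vs ≈ 0.50 in simulation), which is the practical argument for using
LPI rather than t as the primary learning measure.  The positive
LPI–t correlation is real but weak in simulation (ρ ≈ +0.17); the
property test uses a 600-bee cohort because an 85-bee cohort cannot
resolve its sign reliably.

## Bout extraction

Events are sorted per bee, exact duplicates collapsed, and
same-direction runs resolved conservatively: of consecutive "out"
reads only the last is kept, of consecutive "in" reads only the first,
so incomplete trips implied by missed reads are discarded rather than
imputed with invented durations.  An out paired with the next in is a
bout; candidates shorter than `min_duration` (default 2 min,
configurable) are treated as entrance-platform loitering.  The floor is
far below realistic trip durations (per-bee means of tens of minutes)
so it suppresses re-reads without censoring real trips.  A terminal
unmatched out is a censored departure, not a bout.  The bout's day is
the calendar date of its start; day-flying bees do not span nights.
Foragers are exactly the bees with more than five bouts.  The pairing
rule is verified against an independent brute-force oracle on random
event streams.

## Observation matching and collection rates

An outgoing weighing record attaches to the nearest bout start within
2 min (incoming records to bout ends), nearest-neighbour with a stable
earlier-bout tie-break; each record attaches to at most one bout, a
filled slot is not overwritten, and unmatched records are logged and
dropped.  A bout is observed only with both records.  Pollen-load
presence on the incoming record classifies the bout (pollen vs
nectar); nectar rates use only pollen-free bouts, with no attempt to
mass-correct pollen loads.  Rates require ≥ 3 observed bouts of the
resource, are means-based (order-invariant), and the trip-duration
denominator averages the *observed* bouts — the records being averaged
— rather than all RFID bouts (selectable).  Negative nectar rates are
retained with a QC flag: the estimator is reported as defined, not
truncated.  Experience defaults to the bee's total completed RFID
bouts, the only experience-like quantity recoverable from the reader
log alone; a resource-specific variant over observed bouts can be
selected instead.

## Mixed models and AICc selection

All candidate models carry a colony random intercept and are fitted by
maximum likelihood, never REML: AICc comparisons across different
fixed-effect structures are meaningless under REML because the
"restricted" data change with the design matrix.

* Gaussian families (`nectar_rate`, `pollen_rate` on the identity
  scale; `mean_bouts_per_day`, `mean_bout_duration` on the square-root
  scale, which stabilises their right skew): the marginal likelihood is
  evaluated in closed form per colony block, with β and the residual
  variance profiled out by GLS at each variance ratio λ = σ²ᵤ/σ²ₑ; λ is
  optimised on a log grid refined by bounded scalar minimisation, and
  the boundary λ = 0 is always checked.  A boundary estimate is kept
  (variance 0, flagged singular, warning logged) — at that point the
  fit coincides with OLS to 10⁻⁶ in log-likelihood, which is tested.
* Poisson log-link (`days_foraged`): the random intercept is integrated
  per colony by adaptive Gauss–Hermite quadrature — the integrand is
  re-centred at its mode (1-D Newton) and rescaled by the curvature,
  then integrated with 15 nodes, the scheme `glmer` uses.  β and σ are
  optimised by Nelder–Mead with a BFGS polish from a Poisson-IRLS
  start; standard errors come from the numerical Hessian.  The fitted
  absolute log-likelihood differs from `glmer`'s reported value by the
  saturated-model constant (lme4 reports deviance-scale GLMM
  likelihoods); the constant cancels in every ΔAICc.  Zero-day bees are
  excluded — the model describes foragers — and no zero-truncation,
  offset or overdispersion correction is applied, matching a plain
  Poisson count analysis.

k counts the intercept, the fixed effects, the random-intercept
variance, and (Gaussian) the residual variance, so likelihood-based
criteria count every estimated parameter.  Selection is bottom-up:
basic and single-covariate models (colony age, worker age, worker mass;
plus experience for the two collection rates), lowest AICc wins with
ties broken toward fewer parameters, then LPI is added to the winner
and declared predictive only if it lowers AICc by more than 2.  ΔAICc
is reported against the minimum over all rows, so tables always contain
exactly one zero.  Non-convergent candidates stay in the table with a
missing AICc.

Supporting descriptives are Spearman's ρ (average ranks, t
approximation), classical one-way ANOVA, and a Mann–Whitney test
reported as a z statistic (tie-corrected normal approximation, no
continuity correction, two-sided p) because z is the conventional
report for this design.

## The synthetic cohort generator

The generator emulates the study conditions: 5 colonies × 15–21 tested
bees; latent curves with y₀ ~ 10·Beta(1, 9), A = (10 − y₀)·Beta(5, 2)
(so block error counts stay in [0, 10] by construction) and
t ~ log-normal(log 20, 0.5); a short run of blue visits before the
first yellow probe (innate colour bias); 58% of tagged bees becoming
foragers, the rest leaving once and never returning; days foraged
Poisson with log E[D] = 1.7 + 0.06·LPI; foraging dates consecutive for
92% of bees; sqrt-scale bouts/day and bout-duration means linear in
colony age (coefficients −0.52 and +0.06 per day, colony age at
transfer uniform on 7–12 days, bee-level sqrt-scale spreads 0.8 and
1.5) with within-bee log-normal duration scatter (σ = 0.4);
weighing-station sampling of 9.4% of bouts, 45% of observed bouts
carrying pollen with uniform load classes, body mass ≈ 180 ± 15 mg and
nectar loads ≈ 50 ± 15 mg with ±2 mg balance noise and ≤ 30 s
timestamp jitter.  Intercepts were placed so cohort means sit at the
reported mid-range values (≈ 8 days foraged, ≈ 12.5 bouts/day, ≈ 48 min
bouts); where no distribution is reported (pollen classes, mass
spreads, day scheduling) values are single realistic choices, not
revisited.  Bouts are laid out sequentially inside a 06:00–21:00 flight
window with 2–10 min nest visits between them; a day's first bout is
truncated to the window if necessary so every sampled foraging day
yields at least one bout, which keeps realised days-foraged equal to
the Poisson draw.  Everything is a pure function of (config, seed), and
a flat `key = value` config file mirrors the dataclass.

What the generator does **not** emulate: spatial foraging landscapes,
weather, within-nest behaviour, reader hardware error patterns beyond
missed-read runs, colony husbandry, correlations between learning and
body size, or overdispersion in day counts beyond what the LPI spread
induces.  Passing recovery tests therefore show that the pipeline's
estimators and the AICc decision rule recover the effect structure the
generator encodes at the study's sample sizes — not that the original
field data would yield the same tables.

## Problem sizes used by the tests

Monte-Carlo checks use 10 000 replicate choices; generator rate checks
use 500–1000 bees with activity scaled to ~1 bout/day so event logs
stay small; the decay-parameter recovery suite uses 200 bees; the bout
oracle runs 1000 random streams; the end-to-end selection-recovery
suite runs 100 replicate cohorts at the default study size and checks
the LPI verdict pattern (selected for days foraged, rejected for the
four null responses, ≥ 80% each) plus coefficient coverage at a
500-forager cohort.

## Known limitations

* t is weakly identified from binned 100-choice records (see above);
  per-bee t values should be interpreted as ordinal at best.
* The Gaussian fits treat per-bee means as observations, ignoring that
  bees contribute different numbers of bouts (no weighting) — as the
  original analysis design does.
* The Poisson model conditions on being a forager; it does not model
  the forage/never-forage decision, which the generator draws
  independently of LPI.
* Standard errors for β in the mixed models are conditional on the
  variance estimates (the usual GLS/Hessian approximation).
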