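# Methods

## Model structure

`saltimpact` implements a comparative risk assessment (CRA) of gradual
population salt reduction on first-ever cardiovascular events in China.
The world state is a stratified baseline table — 2 regions × 2 sexes ×
5 age bands (35–44 … 75–84) — holding population counts, salt intake
(g/day), systolic blood pressure (SBP, mm Hg), hypertension prevalence,
first-event IHD and stroke incidence (per person-year) and fatal
fractions. Only ages 35–84 are modelled, because the SBP→risk gradients
exist for exactly those bands; strata outside them are refused rather
than silently dropped.

For each scenario the chain is evaluated per stratum and calendar year
against a counterfactual in which baseline salt is held constant:

1. **Salt path.** `fixed_gram` reductions ramp linearly in g/day and
   complete at the achieve year. `percent_total` and `target_level`
   reductions compound a constant per-year percentage cut, solved in
   closed form (`(1−a)^n = 1−f`, or `base·(1−a)^n = target` per
   stratum). The first step falls in the year after baseline
   (baseline 2020, achieve 2025 ⇒ 5 steps, which is what makes a 30%
   total cut ≈ 7%/year). After the achieve year the level is sustained.
   The per-year target solver is honest: from 11.1 g/day to 5 g/day
   over 10 steps it gives 7.7%/year (9 steps give 8.5%); a published
   8.2%/year for that scenario is not reproducible from any integer
   step count at the national mean and is plausibly an average over
   stratum-specific rates, so we do not force it.
2. **SBP.** ΔSBP = β·Δsalt, linear in grams, since the effects are
   stated per 1 g/day. Two β variants: `trial_based` mixes the
   normotensive (0.75 mm Hg) and hypertensive (1.89 mm Hg) per-gram
   effects by the stratum's hypertension prevalence (a stratum without
   one gets 0.40, the national adult figure, which makes the national
   average −1.2 mm Hg per gram); `population_based` applies 1.93 mm Hg
   per gram to everyone, reflecting the more prolonged effect of salt
   reduction observed over ~8 years.
3. **Risk.** RR = (1−r)^ΔSBP with r the per-mm-Hg proportional risk
   reduction by disease and age band. The gradients are stated per
   1 mm Hg only; we scale to other SBP falls log-linearly (the
   proportional-hazards reading). Naive linear scaling (1−r·ΔSBP) would
   overshoot badly at the ~12 mm Hg falls of the strongest scenario.
4. **Events.** Prevented events in a stratum-year are N·I·(1−RR) —
   expectations, not sampled counts. Deaths multiply by the fatal
   fraction; premature deaths (before 70) take bands 35–64 in full,
   none of 75–84, and a configurable share (default 0.5) of 65–74,
   which straddles age 70 with no stated apportionment.

All dose-response parameters live in `src/saltimpact/data/defaults.yaml`
with their 95% CIs, as versioned data.

### Approximations held deliberately

- Population counts and incidence rates are constant over the horizon:
  no demographic projection, cohort ageing, or depletion of the
  susceptible pool. This is the standard CRA reading of
  per-population-member first-event rates and is configurable only by
  editing the baseline table.
- No lag between an SBP fall and the risk fall; no secondary
  (recurrent-event) prevention; no non-CVD outcomes; no attenuation of
  the age-related SBP rise; no haemorrhagic/ischaemic stroke split.

## Uncertainty propagation

5000 Monte Carlo iterations (default). Per iteration, one draw per
parameter, shared across all strata — the parameters are estimates of
common effects, so independent per-stratum draws would understate
between-scenario correlation. Draws:

- national baseline salt mean: normal, SD 1.6 g/day, applied as an
  additive shift to every stratum (the published "11.1 ± 1.6" is read
  as the spread for Monte Carlo draws of the mean; this reproduces the
  published interval for 30% of baseline salt, 2.3–4.2 g/day);
- national baseline SBP mean: normal, SD 13 mm Hg (same reading; it
  does not affect downstream outputs, which depend on SBP *changes*);
- each β and each r: normal with mean at the point estimate and SD =
  (CI upper − lower)/(2·1.96); β truncated at 0, r to (0, 1);
- incidence: one mean-preserving lognormal multiplier per disease,
  CV 0.10 by default (the distributions used for the published
  intervals are unstated; lognormal keeps rates positive).

Outputs are medians with 2.5/97.5 percentile uncertainty intervals. A
draw is a deterministic function of (seed, iteration index), so any
iteration is reproducible in isolation and summaries are seed-stable.
The Monte Carlo engine is vectorised over iterations but applies the
same arithmetic as the deterministic modules (it shares the salt-path
function with the trajectory builder); with all spreads set to zero the
median of every output equals the deterministic pipeline's value, which
the tests assert at 1e−9 relative tolerance. One known tension is kept
on the principled side: sharing a single national β draw across strata
makes the 1 g/day SBP interval exactly the β CI, slightly wider than
some published intervals, which hint at partial averaging of
independent draws.

Reported per scenario × SBP model: the population-weighted salt and SBP
reductions at the achieve year, the event-weighted percentage risk
reduction per disease at the achieve year, and cumulative prevented
events / deaths / premature deaths per horizon (2030, 2040) per disease
and combined (CVD = IHD + stroke).

## Synthetic baseline population

The real region/age/sex-stratified baseline data for China are in an
unavailable supplement, so the generator builds a stand-in with the
documented structure:

- 20 strata; band population shares (0.30, 0.27, 0.21, 0.14, 0.08) of
  690 M adults aged 35–84, split north/south 44/56 and by sex evenly,
  with 5% lognormal jitter;
- salt: male-female offset ~0.6 g/day, mild decline with age, a
  north−south gap of 1.5 g/day (the salient regional structure of
  Chinese salt intake), small jitter, then exact per-region recentring
  so the weighted national mean is 11.1 g/day and the gap is exact;
- SBP: +8 mm Hg per decade of age, small sex/region offsets, recentred
  to a weighted 128.1 mm Hg;
- hypertension prevalence rising with age, rescaled to a weighted 0.40;
- incidence: steeply age-increasing profiles (IHD 0.09%→2.1%, stroke
  0.12%→3.4% per person-year across bands, stroke above IHD as in
  China), region/sex multipliers, 8% jitter — monotone in age by
  construction;
- fatal fractions rising with age, rescaled so the event-weighted
  aggregate is 0.44 (consistent with roughly 4 M fatal out of 9 M
  events in headline figures).

The numbers not pinned by published aggregates (band shares, incidence
profiles, offsets) are stylised, chosen once at plausible magnitudes
for Chinese surveillance data. Consequences: exposure-side outputs
(salt, SBP, % risk reductions) depend only on the published parameters
and calibrated aggregates and are directly comparable to published
values; absolute event counts scale with the synthetic incidence and
population and are *not* expected to match national totals. Passing
tests therefore demonstrate correctness of the machinery and
calibration, not validation against Chinese registry data.

## Numerical and design choices

- Integer calendar years; no sub-annual steps; no rebounding paths.
- Generator calibration is exact (affine recentring after jitter), so
  the weighted salt mean is within 0.05 g/day of target for every seed.
- A Monte Carlo salt draw that falls at or below a `target_level`
  scenario's floor simply has nothing left to cut (Δsalt = 0 for that
  stratum) rather than raising intake.
- Rounding in formatted reports is half away from zero; reductions are
  rendered with a leading minus, intervals as "(lo to hi)" in draw
  order; event counts print in millions to one decimal.
- CSV dialect: comma-separated, UTF-8, '.' decimal, mandatory header;
  floats are written at shortest round-trippable precision and parsed
  with correctly-rounded conversion so write∘load is the identity.
- Default problem sizes (20 strata, 21 years, 5000 iterations) run the
  full three-scenario × two-model study in a few seconds on one CPU.

## Limitations

Beyond the approximations above: the synthetic generator emulates
structure, not any real survey microdata; the 65–74 premature split is
an assumption exposed as a parameter; parameter draws are independent
across parameters (no correlation structure); and truncation of normal
draws at domain boundaries very slightly biases the extreme tails of
the sampled gradients.
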