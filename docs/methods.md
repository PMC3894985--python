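# Methods

## The analysis in brief

`rotabayes` estimates how the crop grown in a cotton field the year
before affects (a) the lint yield of the focal cotton crop and (b) the
early-season density of the plant bug *Lygus hesperus*, using
commercial field-year records rather than experimental plots. Five
model stages share one machinery:

1. **Model 1** — yield (kg/ha) on prior-crop identity;
2. **Model 2** — mean June *L. hesperus* density (insects/sweep) on
   prior-crop identity;
3. **Model 3** — a second-stage regression of the 14 posterior-mean
   yield contrasts on the 14 posterior-mean pest contrasts;
4. **Model 4** — yield on the number of consecutive prior cotton
   plantings (1–4);
5. **Model 5** — June density on consecutive prior cotton plantings.

## The hierarchical model

For record *i* in field *j(i)* and year *t(i)*:

```
y_i   = x_i' β + u_{j(i)} + v_{t(i)} + ε_i,   ε_i ~ N(0, σ²)
u_j   ~ N(0, σ_f²)          v_t ~ N(0, σ_y²)
β_k   ~ N(0, 100²)          σ², σ_f², σ_y² ~ InvGamma(0.001, 0.001)
```

Field and year enter as *crossed random effects*: most fields
contribute only one to three records, so per-field fixed effects would
badly overfit, while the random-effects distribution pools information
across fields and allows statements about fields not in the data. The
random-effect means are pinned at 0; free means would be
unidentifiable against the fixed intercept.

Fixed effects for Models 1/2 are: intercept; 14 indicator columns for
the prior crop with **cotton as the reference category**, so each
coefficient *is* the published contrast "crop X grown the year before
vs. cotton grown the year before"; a species indicator (1 = upland,
0 = Pima); and the 15 counts of each crop among the 8 adjacent fields,
included to keep landscape composition from confounding the rotation
effect. Models 4/5 replace the crop indicators with the consecutive
prior-cotton count (a numeric 1–4 predictor) and keep only the
adjacent-cotton count.

### A note on the "noninformative" β prior, and why the sampler centres

The Normal(0, 100²) prior is effectively flat for contrasts and slopes
on both response scales, but it is *not* flat for the level: the
intercept sits near 1450 kg/ha. Applied literally on raw scales, the
prior shrinks whichever covariate combination carries the level — and
because the consecutive-cotton count and the adjacency counts have
nonzero means, that combination includes their slopes. The result
(verified against flat-prior and fixed-effects least-squares
cross-fits, which recover the truth) is a systematic bias leaking into
slopes of uncentred covariates, plus a year-variance posterior
inflated to the squared response level as the year effects absorb the
mean.

The sampler therefore fits with the response and every non-intercept
column centred at their sample means and maps the intercept draws back
to the original parameterization afterwards
(`McmcConfig.center_response`, on by default; switch it off to
reproduce the literal raw-scale prior). Centring changes only what
the intercept's prior is *about* — deviations rather than the level —
and leaves every slope and contrast definitionally untouched; it is
the standard regression practice that makes a fixed-scale prior
behave as the noninformative prior it is described as.

## Sampling

Every full conditional of the model is available in closed form, so
the posterior is sampled by Gibbs updates with no tuning or gradients:

* **(β, u, v) jointly** from one Gaussian full conditional per
  iteration. The joint precision `W'W/σ² + D` (with `W = [X | Z_f |
  Z_y]` and `D` the diagonal prior precision) has a *diagonal* block
  for the field effects, which is eliminated by Schur complement: the
  (year + fixed)-effect sub-vector is drawn from its marginal and the
  field effects from their diagonal conditional — an exact joint draw
  whose per-iteration factorization is only (p + T)-dimensional, so
  cost grows linearly, not cubically, in the number of fields.
* **σ²** from its conjugate inverse gamma.
* **σ_f² jointly with u**: first σ_f² from its conditional with the
  field effects integrated out — per field the marginal covariance is
  `σ²I + σ_f²11'`, giving a closed-form 1-D density sampled exactly by
  slice sampling on log σ_f² — then u refreshed from its Gaussian
  conditional. σ_y²/v are updated the same way.

Two design points deserve explanation. First, updating β, u and v in
*separate* Gibbs steps (the textbook cycle, available via
`McmcConfig(joint_effects=False)`) mixes very slowly here: with one to
three records per field, the field effects and the fixed-effect
columns (especially the adjacency counts, which sum to 8 in every row
and are therefore collinear with the intercept up to the prior)
compete for the same variation, and the alternating updates random-walk
along that ridge. Drawing the full coefficient vector as one block
removes the coupling. Second, the conjugate σ_f² update conditions on
the current u, creating the classic "funnel": small σ_f² keeps u
small, which keeps σ_f² small. With many singleton fields this stalls
for thousands of iterations. The collapsed update draws σ_f² from its
marginal conditional and so moves freely. Both devices change only the
transition kernel; the invariant distribution is the exact posterior,
and the test suite verifies that the blocked kernel and the plain
conjugate cycle agree on posterior quantiles of every parameter, and
that with random effects disabled and σ² pinned the β draws match the
analytic Gaussian posterior.

Protocol: 3 chains × 10,000 iterations, the first 5,000 discarded, no
thinning; inference pools the remaining draws. Chains start from
jittered states (β near 0, effects at 0, variances near the response
variance) on independent substreams of one master seed, so identical
inputs give bit-identical output. Convergence is monitored with the
classic (non-split) Gelman–Rubin potential scale reduction factor for
every fixed effect and variance; the pipeline warns (and the CLI exits
nonzero) at R-hat ≥ 1.1. Variance draws are floored at 1e-12 against
the near-improper prior; floor hits are counted and reported (zero in
all shipped runs).

## Posterior summaries

Each effect is reported as its posterior mean, a 95% highest-
posterior-density interval, and the posterior probability of a
negative effect. The HPDI is the narrowest contiguous window of the
sorted pooled draws containing `ceil(0.95 n)` of them; ties go to the
leftmost window, `mass=1` returns the sample range, and the
implementation is tested against an exhaustive window search. Sign
probability counts draws strictly below zero (a draw exactly at zero
counts as non-negative — a measure-zero event for these continuous
posteriors). The Model-4 slope is also converted to percent change per
additional cotton year; because the natural denominator is not
determined by the model, the default baseline is the mean observed
yield among the records Model 4 fitted, with a config override
(`percent_baseline`).

## Preprocessing

**June density.** Consultants sampled on irregular dates, so the June
mean is the integral of the piecewise-linear density-versus-day curve
over the intersection of the sampled span with calendar June (days
152–181, non-leap), divided by the days covered. Samples outside June
contribute only through interpolated boundary values; a record whose
samples never reach June has a missing response and drops out of
Models 2/5. The June window is a `JuneWindow` argument, not a
constant.

**Consecutive cotton.** A record is eligible for Models 4/5 only when
the four preceding years are all recorded; the predictor is the length
of the unbroken cotton run starting the year immediately before,
capped at 4. By default runs of zero (previous crop not cotton) are
excluded, matching the published 1–4 predictor range; `include_zero`
admits them.

**Missingness.** Complete-case deletion throughout: rows lacking the
response, the prior crop (Models 1/2), adjacency data, or an eligible
history (Models 4/5) are dropped, one reason per row in a fixed
priority order, and the drop report always reconciles (kept + dropped
= input). Records are sorted by (field, year) before design
construction so fits are bit-reproducible under input permutation. A
prior-crop category with no remaining rows is dropped from the design
and its contrast reported as unavailable rather than silently omitted.

## The second stage (Model 3)

Model 3 regresses the 14 posterior-mean yield contrasts on the 14
posterior-mean pest contrasts with the same machinery (a mixed model
with zero random-effect groups). Regressing point estimates discards
stage-one uncertainty — a deliberate fidelity choice; the module also
provides a draw-pairing sensitivity mode
(`fit_effect_regression_draws`) that refits across random joint
stage-one draws to show how much that matters. Pairs are unweighted
(no record-count weighting). Note that stage-one shrinkage attenuates
the fitted slope relative to the generative slope linking *true*
effects; the recovery test therefore scores Model 3 on true effect
pairs, where the estimand is unambiguous.

## The synthetic generator

The commercial database is proprietary, so the package generates its
own record sets with known truth. Per field: a species (upland with
probability 0.6), a crop trajectory over the ten years before and
through the study span simulated as a repeat-or-redraw chain (repeat
probability 0.5, redraw from a cotton-heavy landscape frequency
vector), with cotton forced in observed record years; a recorded
history depth drawn geometrically (about half of records have the
4-year depth Models 4/5 need). Yields compose a Pima base (1450
kg/ha), a species effect (+160), the prior-crop effect, −40 kg/ha per
consecutive prior cotton year, small per-crop adjacency nuisance
coefficients, field (sd 250), year (sd 150) and residual (sd 250)
terms, floored at 1 kg/ha. June densities compose analogously on the
insects-per-sweep scale (base 0.8, species −0.33, run effect +0.04,
field/year/residual sds 0.25/0.12/0.18, floored at 0.02). Weekly sweep
samples are emitted June–July around the latent June mean times a
linear seasonal ramp whose June average is exactly 1, with
truncated-at-zero Normal observation noise (sd 0.15; an overdispersed
Poisson option exists). Yield and adjacency are masked at the observed
marginal rates (258/1498 and 472/1498). Crop pest effects are drawn
Normal(0.12, 0.28²) and yield effects derived from them through a
configurable linear relation (default slope −300 kg/ha per
insect/sweep, noise sd 40), which gives the second stage a known
generative slope. Default sizes mirror the real database: 1498
records, 566 fields, 1997–2008.

What the generator does *not* emulate: spatial field geometry (the
adjacency counts are drawn, not mapped), weather, count-valued sweep
data (Gaussian noise by default), or the real rotation-frequency
distribution, which is unpublished. Passing recovery tests therefore
demonstrate that the machinery is calibrated when its assumptions
hold, not that the published estimates are correct. Three truncations
(yield at 1, latent density at 0.02, sweep observations at 0) bias the
affected tails slightly; at the default scales the clipped mass is
negligible.

### Estimands on mixed-regime data

When data carry both prior-crop and consecutive-run effects, the
"crop X vs cotton" estimand is `effect[X] − run_effect × E[run | prior
cotton]` over the fitted rows, because the cotton-baseline rows carry
run effects (run ≥ 1) while crop-X rows do not. `GroundTruth.
contrast_truth` computes this exactly from the realized records. The
recovery suite, however, scores each model on data generated under
that model's own assumptions (run effects off for Models 1/2; the full
regime for Models 4/5, whose eligible rows carry no crop effects) —
a calibration check is only meaningful when the fitted model matches
the generative process; on mixed-regime data it would instead measure
prior-data conflict, since the shifted estimands sit far from the
Normal(0, 100²) prior.

## Problem sizes used in tests and acceptance runs

The shipped recovery suite uses 50 replicates of 700 records from 200
fields over 6 years (record density chosen to match the real
database's 2.6 records per field), fitted at 3 chains × 2,000
iterations with 1,000 burn-in. The structural end-to-end checks use
seeded fixtures of 200 and 420 records generated at test time. The
acceptance script runs the full five-model pipeline once at the full
default scale (1498 records) and full MCMC protocol, then the recovery
suite at the sizes above.

## Known limitations

* Observational contrasts, not causal effects: the models condition on
  recorded confounders (field, year, species, adjacent landscape) but
  cannot rule out unrecorded ones.
* The second stage ignores stage-one uncertainty by default (see
  above).
* The classic R-hat is reported (not the split-chain variant), and
  HPDIs are univariate; no joint credible regions.
* With very few levels (the 6–12 years), the year-variance posterior
  is heavy-tailed under InvGamma(0.001, 0.001) and its draws should
  not be over-interpreted; see the prior note above.
* No multiple-comparison adjustment across the 14 contrasts.
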