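# Methods

`surgdelay` implements a pipeline for prioritising elective and
semi-elective surgeries when operating capacity is scarce. Health-related
quality of life (HRQoL) values for pre- and post-operative health states
are elicited from respondent panels on a visual analogue scale (VAS),
screened, compared across panels, and propagated through a cohort
state-transition model whose outcome — DALYs accrued per month of
surgical delay — orders the waiting list. This note records the model,
its assumptions, the numerical choices, and what the synthetic data can
and cannot show.

## Panel valuation

Respondents rate 2 × *S* vignettes (a pre-operative and a post-operative
health state for each of *S* surgeries, default *S* = 10) on a 0–100 VAS
anchored at "worst imaginable health" and "best imaginable health", with
five Global Burden of Disease reference states (dementia, severe
depression, blindness, deafness, infertility) shown as calibration
points. Utilities are VAS/100. In a two-round Delphi design the second
round displays the first round's median and interquartile range
(linear-interpolation quantile convention) per vignette; all analyses
use final-round values.

Three exclusion rules drop doubtful respondents after the final round:

1. any negative rating;
2. all ratings exactly zero;
3. post-operative rating strictly below pre-operative for **every**
   surgery.

"Consistently lower" post-operative values (rule 3) is operationalised
as *all* surgeries — the most conservative reading; a majority rule
would exclude more respondents. Rules are checked in the order 1→2→3 and
each excluded respondent carries exactly one label, so per-rule counts
are disjoint. A respondent with an incomplete vignette set is an input
error, never a silent exclusion. Panel aggregation reports mean, SD
(n−1 denominator) and n per vignette; pooling citizen panels CP1 and CP2
into CP is the n-weighted mean.

## Agreement between panels

Three complementary analyses, all reporting *second-minus-first* group
differences with the convention carried in the output label:

* **Bland–Altman** on per-vignette mean utilities: bias = mean
  difference, 95% limits of agreement = bias ± 1.96 SD of differences
  (the conventional multiplier), t-interval on the bias, and the
  (average, difference) pairs for plotting. Computed pooled and
  stratified by health-state phase.
* **Mixed-effects bias estimation** on respondent-level utilities:
  utility ~ intercept + panel + health-state with crossed random
  intercepts for surgical procedure and for participant, fitted by
  REML; the panel coefficient and its Wald 95% CI estimate the
  systematic bias ("no significant bias" when the CI includes zero).
  Stratified fits drop the health-state term. Participants are unique
  to one panel, so the crossed structure is identifiable. The fitter
  (`surgdelay.lmm`) profiles out the fixed effects and residual
  variance and optimises the two log variance ratios with Woodbury
  identities, giving millisecond fits that are numerically stable on
  balanced panel data; a variance component estimated at the boundary
  (zero) is a valid fit. If the optimiser fails, the vignette-level
  paired estimate is substituted and flagged.
* **Consensus comparison**: per-vignette SDs are differenced pairwise;
  the point estimate is the mean difference standardized by the SD of
  the differences, with the paired t interval mapped to the same scale,
  and the raw mean difference is stored alongside (the standardized
  definition is an interpretation; a constant difference makes the
  standardized value degenerate and is flagged). A lower SD means more
  consensus.

## Decision model

A three-state cohort model (pre-operative, post-operative, deceased;
deceased absorbing) with a one-week cycle — the delay grid is weekly and
its shortest entry is two weeks, so a week is the natural resolution.
Seven inputs per surgery: annual survival before and after surgery,
HRQoL before and after, mean age, and two treatment-futility windows
(weeks until surgery stops improving survival, resp. HRQoL). Annual
survival *s* converts to a weekly death probability 1 − s^(1/52)
(constant hazard). The cohort starts pre-operative; at the scheduled
delay the survivors transition (surgery first, then that week's
post-operative hazard); under cancellation nobody transitions. The
horizon runs until the cohort turns 100. Futility windows are step
functions: the post-operative survival (utility) reverts to its
pre-operative value when the delay reaches the window. No discounting,
half-cycle correction, or background life-table mortality is applied;
none is part of the model definition here, and the accounting keeps the
closed-form oracles exact.

Healthy life years are occupancy-weighted utilities summed over cycles
(disability weight = 1 − utility; the deceased contribute zero). For
each delay *d* ∈ {2, 12, 22, 32, 42, 52} weeks the loss is
HLY(2) − HLY(*d*); **DALY per month of delay** is the ordinary
least-squares slope of loss against delay in months (weeks × 12/52)
over the six grid points. Cancellation is reported separately as a
total loss and never enters the slope. With constant hazards the
occupancies are geometric, so HLY has a closed form; the trace-based
and closed-form routes agree to 1e-10 and the tests check both.
Substituted panel utilities may be inverted (mean pre above mean post)
for surgeries whose true states nearly coincide; they are propagated
as-is rather than clamped.

## Probabilistic sensitivity analysis

All (0, 1)-bounded inputs — the two utilities and the two survival
proportions — get beta distributions via method of moments
(α = m(m(1−m)/σ² − 1), β = (1−m)(·)); age and futility windows stay
fixed. Utility σ defaults to the standard error of the panel mean
(SD/√n): the PSA reflects how precisely the panel pinned the value
down, not respondent heterogeneity (both choices are arguments).
Survival uncertainty defaults to an absolute SD of 0.02. Draws with
pre-utility above post are jointly resampled — truncating either
marginal would bias it asymmetrically — except when the panel estimates
themselves are inverted, where the constraint is infeasible and draws
pass through unconstrained. Intervals are empirical 2.5th–97.5th
percentiles (linear interpolation) over 1000 draws by default; a given
seed is bit-reproducible.

## Ranking

Surgeries are ranked by descending DALY/month (PSA means by default, to
match reporting of average outcomes; deterministic outcomes are a
switch). Ties — absent in practice — break lexicographically by label
so output is deterministic. Rankings from two HRQoL sources are
compared by Spearman's rho on the integer ranks, 1 − 6Σd²/(n(n²−1)).
The two-sided p-value uses the exact permutation null for n ≤ 12,
computed by a dynamic programme over subsets that counts permutations
per Σd² value (no factorial enumeration), and the t approximation
above. The shift report marks each surgery up/down/same and flags
whether every moved surgery changed by exactly one position (adjacent
swaps only). Note that up- and down-counts balance only in that
adjacent-swap regime; in general only the net displacement is zero.

## Synthetic data: what it emulates and what it does not

The generator emulates the study conditions: citizen panels of 47 and
41 final-round entrants, a physician panel of 15, ten surgeries, and
injected offenders (1 negative / 1 all-zero / 6 inverted in CP1;
2 / 4 / 3 in CP2) so the exclusion flow yields 39 + 32 = 71 retained
citizens. Ratings follow a clipped linear random-intercept model,

    VAS/100 = clip(u_true + δ·1[physician] + b_resp + b_vignette + ε, 0, 1),

with physician offset δ = 0.07 utility points (physicians rate health
states higher), respondent SD 0.05, vignette SD 0.03, and residual SD
0.12 for citizens vs 0.08 for physicians — physicians more concordant,
citizens more dispersed. The linear structure deliberately matches the
mixed model the agreement stage fits, making parameter recovery a
well-posed check. Latent truths are uniform: pre on [0.1, 0.6], post on
[0.5, 0.95] with post ≥ pre enforced. Surgery parameters draw annual
pre-operative survival from U(0.80, 0.98), a post-operative gain of
U(0.005, 0.15) capped at 0.995, age from U(30, 85) and futility windows
from U(26, 208) weeks, spreading the ranking without implying
implausibly lethal waiting times.

Limitations to keep in mind: clipping to the scale ends slightly
attenuates the realised panel contrast when true utilities sit near 1
(measured attenuation is small at the default spread but grows with the
offset); real VAS data show digit preference, heaping at multiples of
5/10 and non-normal residuals that the generator omits; offenders are
injected deterministically as the last respondents of a panel rather
than modelled behaviourally; round 1 is not simulated separately (all
analyses use final-round data; feedback statistics are exercised on the
same table); and no respondent drop-out between rounds is modelled.
Passing recovery tests therefore show the pipeline is correct under its
own assumptions, not that those assumptions hold in any particular
field study. The synthetic surgery parameters are draws, not estimates
of any real procedure, so absolute DALY/month magnitudes are
illustrative only; rankings and panel contrasts are the meaningful
outputs.

## Problem sizes

Default runs use the study-sized panels (103 respondents × 20
vignettes), 1000 PSA draws per surgery and source, and 200-replicate
recovery studies for the mixed model (a fit takes ~5 ms, a full
pipeline run under a second), chosen so the entire test suite and a
full reproduction run complete in about a minute on one CPU.
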