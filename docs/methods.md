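# Methods

`difagree` analyzes measurement invariance and cross-informant agreement in
paired-informant Likert questionnaires — the motivating case is an
adolescent's self-report and a parent's proxy report of health-related
quality of life on the 23-item PedsQL 4.0 Generic Core Scales (physical 8
items; emotional, social, school 5 items each; responses 0 = never a
problem … 4 = almost always a problem).

## The hybrid OLR/IRT DIF model

An item shows differential item functioning (DIF) when respondents with the
same level of the underlying trait but from different groups (child vs
parent) have different response probabilities. Each subscale is analyzed
separately on its own unidimensional trait.

**Matching variable.** Samejima's graded response model (GRM) is calibrated
on the pooled two-group data. Cumulative category probabilities are
two-parameter logistic curves, `P(Y >= k | θ) = logistic(a(θ − b_k))`,
with item discrimination `a > 0` and ordered thresholds `b_1 < … < b_{K−1}`.
Calibration is marginal maximum likelihood via EM on a fixed quadrature
grid (49 equally spaced nodes on [−4, 4] with standard-normal weights,
configurable); the latent trait is identified as N(0, 1). The M-step
maximizes each item's expected complete-data log-likelihood by L-BFGS with
analytic gradients in an order-preserving parameterization
(`log a`, `b_1`, log-increments). EM stops when the largest absolute
parameter change drops below 1e−4 (at most 500 iterations; the marginal
log-likelihood trajectory is recorded and asserted non-decreasing).
Respondent traits are expected-a-posteriori (EAP) scores — posterior means
under the N(0, 1) prior on the same grid — which are defined for every
response pattern, including all-extreme ones. Starting values: `a = 1`,
thresholds at normal quantiles of the observed cumulative category
frequencies. Any observed category with fewer than 5 responses in either
group is merged with its less extreme neighbor before fitting (logged
mapping); this prevents unstable thresholds in small samples.

**Per-item DIF tests.** Conditioning on the EAP trait, three nested
proportional-odds models are fitted to each item:

    Model 1: logit P(Y >= k) = α_k + β1·trait
    Model 2: logit P(Y >= k) = α_k + β1·trait + β2·group
    Model 3: logit P(Y >= k) = α_k + β1·trait + β2·group + β3·trait·group

The group indicator codes the focal (second-listed) group as 1, so β2 > 0
means the focal group endorses higher categories at equal trait — the sign
the domain-level cancellation rule relies on. Uniform DIF is the
likelihood-ratio comparison of Models 1 vs 2 (β2 ≠ 0), non-uniform DIF of
Models 2 vs 3 (β3 ≠ 0); twice the log-likelihood difference is referred to
χ²(1). Magnitude measures: the McFadden pseudo-R² difference between
adjacent models (ΔR² = (ll_small − ll_big)/ll_null) and the Crane–van
Belle–Larson proportionate β1 change |β1(M1) − β1(M2)|/|β1(M1)| (reported
descriptively against its own empirical threshold). The fitter is a damped
Newton iteration on the exact Hessian in (α, β) coordinates, warm-started
from the next-smaller nested model; a quasi-Newton run in a
monotone-intercept parameterization is the fallback. The intercept-only
null model is solved in closed form (empirical cumulative log-odds). The
trait enters as estimated (already standardized by the prior); the
interaction column is the plain product of that trait and the indicator.

**Classification.** An item is flagged non-uniform when the non-uniform
p-value beats its threshold — even when the uniform test also fires
(uniform-in-the-presence-of-non-uniform is treated as non-uniform);
otherwise uniform when the uniform p-value beats its threshold; otherwise
unflagged. "Practically important" means the corresponding ΔR² exceeds its
empirical threshold. No multiple-testing correction is applied across
items; type-I control is the per-item Monte-Carlo calibration below.

**Iterative purification.** Round 1 scores everyone from the all-items
pooled calibration. Each later round re-calibrates the GRM giving currently
flagged items separate parameters per group (unflagged items anchor the
metric), re-scores, re-tests every item, and re-classifies. The loop stops
when the flagged set repeats (fixed point; an initial empty set is
confirmed by one extra round) or after `max_iter` (default 10) rounds; an
oscillating set is reported as the union of the last two states and marked
unstable rather than silently resolved. The full per-iteration trace
(flag sets, statistics, traits) is part of the result and is always
serialized. An alternative purification mode that drops flagged items from
trait estimation instead of refitting them per group is available
(`dif_items` handling in `grm.fit_grm` — group-specific calibration is the
default because it retains the flagged items' information for scoring).

## Monte-Carlo empirical thresholds

Logistic DIF screens are anti-conservative, especially when groups differ
in the trait. Instead of nominal χ² critical values, per-item thresholds
are derived from a parametric bootstrap of the no-DIF null matched to the
observed calibration: the pooled (shared, hence DIF-free) item parameters
and every respondent's EAP trait are held fixed; responses are re-drawn
from the GRM at each respondent's trait, preserving group sizes and any
true group trait difference. Each replicate gets one non-iterative analysis
pass — the trait is re-estimated by EAP re-scoring of the simulated
responses under the calibration's parameters (a full GRM re-fit per
replicate is available via `refit_params=True`; re-scoring is the default
because it conditions the null on the observed calibration exactly and
keeps 1000-replicate runs tractable). Defaults are 1000 replicates at
α = 0.01. Replicates whose fits fail are resampled within a retry budget
(max(10, nrep/10)).

Thresholds are order statistics of the null draws: the α-quantile of the
null p-values taken as the *floor* order statistic and the (1−α)-quantile
of the magnitude measures as the *ceiling*. With these estimators the
probability that a fresh null draw beats the threshold is ≈ α at any
replicate count (≈ k/(nrep+1)); interpolated quantiles would roughly double
the realized type-I rate at nrep = 100. ΔR² thresholds legitimately differ
across items because the category distributions differ — the reason
per-item thresholds exist at all. Under the dual test (uniform + non-uniform
per item) the probability that an item is flagged for *any* reason under the
null is ≈ 2α by construction; calibration checks therefore count each
comparison's rejections separately.

## Scoring and cross-informant agreement

Raw responses are reverse-transformed to the 0–100 metric
(`score = (4 − raw) × 25`; higher = better quality of life). A subscale
score is the mean of its transformed answered items (defined when ≥ 50% of
the items are answered — configurable; the 5% missingness filter makes this
nearly moot); the total score is the mean over all answered items, not the
mean of subscale means, so the 8-item physical scale weighs
proportionally.

Per informant pair and scale the agreement table reports means ± SD, the
classical paired t-test (conventions: all-zero differences → p = 1;
constant non-zero difference → p = 0), the unsigned effect size
|m1 − m2| / sqrt((sd1² + sd2²)/2) with Cohen labels ([0, 0.2) negligible,
[0.2, 0.5) small, [0.5, 0.8) medium, ≥ 0.8 large — half-open intervals
close the gaps the conventional cutoffs leave), and the intraclass
correlation. The ICC is the two-way, single-measurement, absolute-agreement
form ICC(A,1) computed from the paired ANOVA mean squares (the consistency
form is a switch); labels: poor ≤ 0.40, moderate ≤ 0.60, good ≤ 0.80,
excellent above.

**DIF-corrected scores.** At the domain level, uniform-DIF items biased in
opposite directions offset each other; an uncancelled uniform item
transfers its bias to the scale score. Uniform-flagged items are therefore
greedily paired by opposite β2 sign, strongest |β2| first; unpaired uniform
items are removed and the agreement block recomputed on the retained items
(non-uniform items are never removed by this rule — their bias changes
direction along the trait, so no cancellation argument applies; removing
*all* uniform items instead is a config switch). A subscale whose items are
all removed reports "no corrected score"; the row stays in the table,
marked undefined.

## Data handling

Input is wide CSV (UTF-8, header; one row per respondent with
`respondent_id`, `dyad_id`, `group` and one integer column per item;
missing = empty cell or `NA`). Out-of-range or non-integer cells are
reported with row and column, never clamped. Respondents with more than 5%
of items missing are excluded; because every item-level comparison needs
both members of a dyad, the exclusion drops the whole dyad. Within retained
respondents, missing items are mean-imputed per item within group (rounded)
for model fitting — a minimal-assumption default, switchable — while scale
scores always use the mean of available items.

## Synthetic dyadic generator

Because real dyadic PRO data of this kind are rarely shareable, the package
ships a generator that produces the structure the analysis assumes: latent
traits of the two members bivariate normal with correlation ρ and a mean
shift, responses from the GRM. Uniform DIF is injected as a common
threshold shift δ for the focal group (location DIF → β2); non-uniform DIF
as a discrimination ratio γ (→ β3). Defaults: discriminations evenly spaced
over 1.2–2.0 and thresholds spread over [−2.5, 2.5] (informative items
typical of PRO scales); ρ = 0.5 and a focal-group trait shift of 0.15 in
the full-instrument preset, matching the small-to-moderate self/proxy
agreement and the slight parent underestimation of child HRQoL reported in
this literature; 573 dyads in the `pedsql_like` preset and 500 in the
single-subscale presets (a few hundred dyads is the realistic scale of such
field studies). Missingness beyond MCAR is out of scope.

What the generator does *not* emulate: multidimensional traits (subscale
traits are drawn independently of each other), response styles,
acquiescence, clustering by school/family beyond the dyad, and
non-ignorable missingness. Passing tests therefore demonstrate correctness
of the machinery under the stated model, not robustness of the method to
real-data violations — notably, dyad members are treated as independent
groups by the analysis itself, a known limitation of the approach.

One identifiability caveat matters for interpreting saturated DIF
patterns: a common same-direction threshold shift on *every* item of a
subscale is indistinguishable, within that subscale, from a group
difference in the trait — the pooled calibration absorbs it, and no item
is flagged (the `saturated_uniform` preset demonstrates this). DIF
detection is always relative to the anchor items. Consequently an
"all items uniform-flagged, nothing cancels" state — the case where no
corrected score exists — arises from real multi-subscale data, not from a
single-subscale generating scenario; the reporting path for it is
exercised directly at the correction/reporting level.

## Verification batteries and problem sizes

The test suite pins every closed-form statistic to independent oracles
(statsmodels `OrderedModel` cross-fits to 4 decimals, fine-grid posterior
integration for EAP to 3 decimals, ANOVA mean-squares and pingouin ICC(A,1)
to 4+ decimals, χ²(1) tail values). Stochastic batteries use fixed seeds:
GRM simulate-then-refit at n = 1000 / 10 items (pilot-pinned mean absolute
errors: a < 0.15, b < 0.12); null-calibration of the full pipeline with
Monte-Carlo thresholds at 500 dyads × 5 items, nrep = 100, α = 0.01 over a
few dozen outer replicates (per-comparison rejection rate tested against
the 95% binomial band around α); power/recovery of injected DIF
(δ = 0.6 uniform, γ = 1.8 non-uniform at 500 dyads) at nominal α = 0.01
over ~100 replicates. Replicate counts were chosen to keep the default
suite a few minutes long while leaving the binomial checks informative; the
generating conditions themselves are never scaled.
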