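# Methods

## Event model

A scored display is a pair of per-side event tracks. Each movement is the
closed frame interval `[start_frame, end_frame]`: the start is the first
frame with visible mantle contraction, the end the frame where the lure
returns to rest. Frames are 0-based integers. Whether the end frame is
inclusive is a convention, not an observable; the closed interval was chosen
so that the start frame — defined by a visible event — is symmetric with the
end frame. Start frames must be strictly increasing within a side (two
movements of one flap cannot begin on the same frame), but movement *bodies*
may overlap, since a new contraction can begin before the previous one has
fully relaxed; overlaps are accepted with a logged warning.

Defaults mirror the field protocol the package is built around: 120
frames/s, a 20,000-frame analysis window (2.8 min) starting at frame 5,000
to skip camera-setup disturbance. All window and rate parameters are
per-recording metadata, so other protocols need no code changes.

## Synchrony classification

Movements on opposite sides are synchronized when their start frames differ
by at most `tolerance_frames` (default 4; "within" is read inclusively, so
|Δstart| ≤ 4). The classifier builds a one-to-one matching by sweeping left
events chronologically and pairing each with the earliest still-unmatched
right event inside the tolerance. Because each left event's feasible
partners form a contiguous window of right events, yielding the earliest
feasible partner can never exclude a later left event from a match it would
otherwise have had (the standard exchange argument for interval matching),
so the greedy pairing attains the maximum possible number of matches; the
test suite verifies this against an exhaustive maximum-matching oracle on
random tracks. Ties (two equidistant unmatched partners) resolve to the
earlier, making the classifier fully deterministic.

The proportion synchronized is `n_sync / (n_sync + n_left_only +
n_right_only)`; matched pairs count once in the denominator. When both
tracks are empty, the proportion is reported as absent rather than 0,
distinguishing "did not display" from "displayed but never synchronized".

## Summaries

Per side: mean and SD of start-to-start intervals between consecutive
movements, mean start-to-end duration, and movement count, all in seconds at
the recording's frame rate. The SD is absent — not zero — when a side has
fewer than two intervals. Intervals are computed independently per side,
regardless of synchrony. Group-level comparisons default to the left side's
interval statistics; a flag selects the right side or the per-recording mean
of both.

## Group comparisons

The omnibus test across lure groups is Kruskal–Wallis; pairwise contrasts
are two-sample rank-sum (Mann–Whitney U) tests — exact for tie-free samples
up to n = 25 per group, normal approximation with continuity correction
beyond — with Bonferroni adjustment over the pairwise family (3 comparisons
for 3 groups). The reported statistic is the U of the first group, the W
that R's `wilcox.test` prints; complete separation with the first group
shifted low yields W = 0. A paired signed-rank test is not meaningful for
independent groups of unequal size, which is why the unpaired rank-sum test
is the implemented contrast. The temperature analysis is a Spearman rank
correlation of water temperature against mean movement interval, requiring
at least three usable recordings.

### Bootstrap-fed mixed model

Individuals differ in how many movements fall inside the analysis window, so
interval observations are equalized by resampling: for each recording,
`n_boot` (default 1,000) interval values are drawn with replacement from its
observed intervals. The resampled values enter a linear mixed model

    interval ~ lure_group + (1 | recording),   REML

fit via statsmodels' MixedLM. The per-recording random intercept absorbs the
artificial inflation of within-recording n: the test suite checks that a
10-fold increase in `n_boot` moves fixed-effect standard errors by less than
10%, i.e. inference is driven by between-recording variation.

Fixed-effect contrasts are tested with Satterthwaite denominator degrees of
freedom, computed in-package (statsmodels does not provide them): with
θ = (τ², σ²) the between/within variances, the contrast variance
f(θ) = c′(X′V(θ)⁻¹X)⁻¹c and the restricted log-likelihood have closed forms
for this compound-symmetric blocked covariance, and

    df = 2 f(θ̂)² / (∇f′ · Cov(θ̂) · ∇f),

with the gradient by central differences and Cov(θ̂) from the numerical
Hessian of the restricted likelihood — the same construction lmerTest uses.
For a balanced design with many bootstrap draws this reproduces the
between-recording df (recordings − groups), as the tests verify. When the
REML optimizer fails on degenerate inputs (e.g. zero between-recording
variance), ANOVA moment estimators of (τ², σ²) are substituted and the fit
is flagged; a near-zero τ̂² is likewise flagged as singular, with estimates
still reported.

All resampling flows from an explicit integer seed; per-recording child
streams are spawned in sorted recording order, so results do not depend on
container iteration order.

## Polymorphism statistics

**Ratio stability.** A 2×2 table (sampling period × morph) is tested with
both the Pearson chi-square *without* continuity correction and the
two-sided Fisher exact test (summing all tables with hypergeometric
probability ≤ the observed table's). Both are always reported, clearly
labeled, because published small-sample practice mixes the two and only the
uncorrected chi-square reproduces values computed under that convention.

**Segregation.** A single-locus, two-allele dominance model is specified by
the dominant morph, the dam's genotype, and the frequency of the dominant
allele among the sires' successful gametes — a parameterization that covers
unknown and multiple paternity without counting sires. The Mendelian
expectation follows from random union of gametes: the recessive morph
appears iff both gametes carry the recessive allele. The observed count of
the maternal morph is tested with an exact binomial: the one-sided p is the
tail toward the observed deviation and drives the verdict at α (default
0.05); the two-sided p sums outcome probabilities ≤ the observed outcome's
(the convention of standard exact-test routines, so an observation exactly
at expectation gives p = 1). Models expecting proportion 0 or 1 that the
data contradict return p = 0 and the verdict "impossible under model".

## Synthetic-data generator

The display generator is a *coupled renewal process*. One driving train of
candidate movement times is drawn with gamma inter-event times (default;
non-negative and right-skewed, matching erratic displays — lognormal
available), parameterized by mean and SD in seconds. Every candidate is
expressed on both flaps:

* with probability `p_sync` the right start equals the left start plus a
  jitter drawn uniformly from ±`jitter_frames` — a synchronized pair;
* otherwise the right-side partner is displaced into a narrow band just
  beyond the jitter-plus-tolerance slack, with a neighbor-safety check so a
  displaced partner can neither match its own candidate nor a neighboring
  one — one left-only plus one right-only movement.

With jitter at or below the classifier tolerance this gives the closed form
E[P] = p/(2−p) for the proportion synchronized (each coupled draw adds one
matched pair; each uncoupled draw adds two one-sided movements), which the
tests use as a Monte-Carlo oracle. Because both sides express every
candidate, each side's interval distribution equals the driving
distribution, so preset interval means are recovered per side. Inter-event
gaps are floored at `2·jitter+1` frames, which keeps jittered partners in
their candidate's order and makes full coupling score as proportion
synchronized exactly 1.0, not merely approximately.

Presets are loosely calibrated to the three display groups the package is
aimed at: a fast, metronomic, fully synchronized congener (mean interval
0.21 s, SD 0.05 s, `p_sync` = 1) and two slower, erratic, partly
synchronized morphs (darter: 3.2 s mean, SD 2.0 s; leech: 1.0 s mean, SD
0.7 s; both `p_sync` = 0.6). Interval SDs and `p_sync` for the morphs are
free choices — no published dispersion or coupling estimates exist — set so
the morphs are visibly erratic and partly synchronized. Durations (0.4 s
mean, 0.1 s SD by default; shorter for the fast congener so movements rarely
overlap) are likewise invented, as no duration estimates are published.
Study-set simulation scales each recording's interval mean by a lognormal
factor with 10% coefficient of variation, emulating individual tempo
differences; without it, between-individual variance is exactly zero and the
mixed model is rightly singular.

The brood sampler draws one dam gamete (from her genotype) and one sire
gamete (from the sire-pool allele frequency) per offspring and applies the
dominance relation.

What the generator does *not* emulate: biomechanical waveform shape,
temperature dependence of tempo (temperature is metadata only), drift or
fatigue within a recording (the renewal process is stationary), and
observation error in manual frame annotation. Passing tests therefore
demonstrate correctness of the scoring and inference machinery under the
stated stochastic model, not robustness to annotation noise.

## Problem sizes

Test and acceptance runs use windows of 6,000–1,500,000 frames chosen per
check: long windows (≥10,000 events) for Monte-Carlo convergence of the
closed-form proportion, the standard 20,000-frame window for study-scale
runs, and 20 seeds for the mixed-model ordering check. The whole suite runs
in well under a minute on one CPU.

## Known limitations

* The classifier's greedy matching is provably maximum for the interval
  structure used here, but the `pairs` themselves (not their count) can
  differ from other maximum matchings when several partners are feasible.
* The mixed model assumes a homoscedastic residual across groups; with group
  interval variances differing by an order of magnitude the REML σ̂² is a
  pooled compromise, and τ̂² partially absorbs the imbalance. Group-mean
  estimates are unbiased regardless; contrast SEs are approximate.
* The exact rank-sum path requires tie-free data; heavily tied metrics
  (e.g. proportions hitting 1.0 in several recordings) fall back to the
  normal approximation.
* Fisher's exact test is implemented for 2×2 tables only; larger tables
  raise rather than silently switching test.
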