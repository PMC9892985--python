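# Methods

`crowdkappa` analyses inter-rater reliability for binary dermoscopic-feature
annotations collected from three reader cohorts — an expert panel, a
nonexpert crowd, and a small expert crowd replicating the crowd protocol —
and ships a generative rater simulator so the whole analysis is testable
end to end without any proprietary rating data.  This note records the
models, the defaults and why, and what the synthetic data do and do not
establish.

## The agreement model

Agreement between two raters is Cohen's κ,

    κ = (p_o − p_e) / (1 − p_e),

with `p_o` the fraction of shared images labelled identically and `p_e`
the agreement expected from each rater's own marginal label frequencies.
κ is computed from the integer 2×2 cell counts as a ratio of integers,
`κ = (n·agree − pe_num) / (n² − pe_num)`, so textbook examples evaluate
exactly in floating point.  Pairs in which both raters applied a single,
identical label have `p_e = 1`; κ is undefined there.  Such degenerate
pairs are flagged and excluded from medians rather than scored 0 — scoring
them would bias medians downward for low-prevalence features.  κ values
are non-normally distributed across pairs, so cohorts are summarised by
the median κ over evaluated pairs, binned as poor (κ < 0.4, including
negative values), fair-good (0.4 ≤ κ < 0.75), and excellent (κ ≥ 0.75);
the lower bound of each band is inclusive.

With sparse, partially overlapping crowd raters, a pair is evaluated only
if both raters saw at least `min_overlap` images (default 62, one panel
substudy block).  The constraint is applied uniformly to every cohort; the
panel design has complete 62-image blocks, so it is unaffected.

## Taxonomy collapse

The feature vocabulary is the consensus set of 31 subfeatures of
melanocytic lesions under 9 superfeatures; 6 superfeatures (dots,
globules, lines, network structures, regression structures, vessels) are
active downstream.  A rater marks a superfeature present on an image iff
they marked ≥1 constituent subfeature present; a superfeature counts as
rated iff ≥1 of its subfeatures was rated.  Reaction times are not
propagated through the collapse, which is a logical OR, not a timed event.
In the bundled default, shiny white structures carries no subfeatures and
"structureless brown areas / homogenous" is a single subfeature: this is
the unique reading consistent with a 31-subfeature total and with vessels
being the largest group (6 subfeatures).

## Consensus, qualification, thresholded reader

Gold standard: per (image, superfeature), the label is *present* when ≥3
of the 5 panel raters voted present, *absent* when 0 did, and *test*
(ambiguous, unlabelled) for 1–2 votes.

Qualification: labelled gold items are split, seeded and stratified by
(superfeature, status), into training and validation halves (fraction
configurable; the platform's true proportions are not public, so 0.5 is a
declared approximation, as is the static rather than online split).  A
crowd user qualifies for a task when their validation-item correctness is
at least θ_q = 0.83 (inclusive); users with no rated validation items are
excluded — qualification requires evidence.

Thresholded consensus reader: for each task the five "first completers"
are condensed into one synthetic rater that says present iff ≥3 of 5 said
present.  Completion timestamps are usually absent from exports, so the
default proxy for "first five completers" is the five raters with the
most rated images (ties broken by rater id), overridable by an explicit
list.  Images not rated by all five selected raters are excluded with a
warning.

## The simulator

Latent truth `z_if ~ Bernoulli(π_f)` per (image, superfeature).  Default
prevalences derive from the published per-feature gold counts (present at
≥3/5, divided by 248): dots 0.25, globules 0.37, lines 0.24, network
structures 0.56, regression structures 0.24, vessels 0.27.

Difficulty `δ_if ∈ [0, 1)` follows a two-component mixture: an easy bulk
`Beta(μc, (1−μ)c)` with μ = 0.03, c = 4, and a hard mode `Beta(8, 2)`
(mean 0.8).  The study images were curated exemplars, yet each feature
also had a sizeable set of genuinely ambiguous images (those with 1–2 of
5 expert votes); the default per-feature hard fractions are those
ambiguous-image counts divided by 248 (dots 0.38, globules 0.40, lines
0.24, network 0.18, regression 0.31, vessels 0.12).  A unimodal
difficulty cannot simultaneously reproduce the published κ range and the
ambiguous-image counts; the mixture does both and also populates the
mid-range of average responses that the reaction-time regression needs.

A rater of ability `a ∈ [0.5, 1]` answers correctly with probability
`q = 0.5 + (1 − δ)(a − 0.5)`: difficulty shrinks everyone toward chance,
so hard images lower agreement for experts and crowd alike.  Sensitivity
and specificity are symmetric by design; an asymmetric extension is a
non-goal.  Abilities are `0.5 + 0.5·Beta(α, β)`: panel (40, 1), crowd
(14, 2), expert crowd (20, 1.5).  These place panel experts near ceiling
on easy images (needed for the observed upper κ range), give the crowd a
realistic spread in which most but not all users clear the 83%
qualification gate, and order the cohorts expert > expert-crowd > crowd.
The real platform population's accuracy distribution is unpublished;
these are declared modelling choices, not estimates.

Study structure: the panel design partitions 20 experts and 248 images
into 4 non-overlapping substudies (5 experts × 62 images each, untimed);
crowd tasks draw per-user rating counts from a log-normal with the
published per-task medians (91–177), σ = 0.6, truncated to [10, 248]
(users with fewer than 10 ratings are unusable for pairwise κ anyway),
over uniformly random image subsets; the expert crowd's 7 raters rate
every image of every task.  Crowd user pools are independent across tasks.
Randomness derives from one seed by stable hashing of stage names, so
enlarging one cohort never perturbs another stage's draws.

Reaction times follow `log(1 + RT) = α_j + β_U·4p(1−p) − β_P·z + ε`,
`ε ~ N(0, σ_ε)`, floored at 0.05 s; `p` is the model-expected proportion
of the cohort answering present for the item (computable from z, δ and
the cohort's mean ability), keeping generation causal and seed-stable.
Defaults: α_j ~ N(1.1, 0.18) log-seconds (typical RT ≈ 2 s, within-user
spread exceeding across-user spread, as observed), β_U = 0.2 (indecision
slowing), β_P = 0.6 (presence speed-up, ≈ 45% faster when present),
σ_ε = 0.45.  β_P was set large relative to β_U because the reported
pattern — the linear term negative in every task for both cohorts —
requires the presence effect to dominate the linear leakage of the
inverted-U.

## Reaction-time regression

Per item: mean of `log(1 + RT)` over timed ratings, and the average
response (proportion answering present, over all ratings of the item;
qualified users only by default).  OLS of mean log RT on
`{1, t, t²}` with `t = x − 0.5`: centering at the point of indecision
makes the linear coefficient the present-vs-absent speed contrast
(negative = faster when present) and leaves the fitted curve unchanged;
the equivalent uncentered coefficients are exposed exactly.  An
uncentered parametrisation cannot represent the reported sign pattern for
low-prevalence features (its linear coefficient is ≈ β_P(1−4π) + 4β_U ≥ 0
whenever π ≤ 1/4), which is why the centered form is the default.  The
fit has exactly 3 coefficients; residual df = n_items − 3 is surfaced
rather than forced to any particular printed value.  Items are unweighted
by default (no weighting statement exists for the original analysis); a
rater-count-weighted option is available.  Natural log throughout.
t-values are coefficient/SE with two-tailed p-values on t(df); exactly
interpolated fits (SE = 0) report t = 0 for null coefficients and ±inf
otherwise.

## Difficulty calibration and design replication

`replicate_study_design` bisects the per-feature hard-image fraction
until the simulated panel median κ hits per-feature targets (the
published study-1 medians by default).  The objective holds all uniform
draws fixed and maps difficulty through the mixture quantile transform,
so it is monotone in the hard fraction (bisection is well posed), and it
averages the 40-pair median over 5 independent panel realisations to cut
single-draw noise; the internal tolerance is 0.015, comfortably inside
the ±0.03 acceptance band.  It then simulates fresh crowds (80 users per
task by default) at the calibrated difficulties and reports how often the
feature calibrated hardest/easiest yields the lowest/highest crowd median
κ, plus the Spearman correlation between targets and mean crowd medians.

## Problem sizes and numerical choices

Analyses run at the published scale (248 images, 20+5-of-7 experts,
79–111 crowd users per task) in seconds; test-suite simulations use the
same structure, scaled where the check does not need the full size (e.g.
48-image pipelines for orchestration tests, 10,000 shared items for the
chance-rater κ calibration).  Pairwise κ for all pairs is computed via
boolean matrix products over rater × image incidence matrices.  All κ and
p_o/p_e arithmetic is integer-exact; medians use the even-count
mean-of-middle convention.  Ties in completer selection break by rater
id; pair enumeration is lexicographic, making every output file
byte-stable under a fixed seed.

## What passing tests do and do not show

The simulator reproduces the *structure* of the three studies — design,
prevalences, rating-count distributions, a difficulty continuum with an
ambiguous mode, qualification behaviour, the reaction-time sign regime —
and the analysis code is validated against independent oracles (an
external κ implementation, exact enumeration, closed-form regression
recovery).  It does not model platform learning or fatigue within a
session, repeated ratings of one image by one user (so simulated total
rating counts sit below the published totals, which include repeats),
per-subfeature crowd behaviour, asymmetric error rates, or image content.
Agreement with the published per-feature κ values is therefore assessed
as ordinal-pattern replication under calibration, not as numerical
reproduction of the published summary statistics from raw data, which
are not public.
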