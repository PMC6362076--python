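# Methods

## The detection model

LOF is a relative density estimate: for subject *p*, the k-distance is the
Euclidean distance to its k-th nearest other subject; the neighborhood
N_k(p) contains every subject within that distance (tie-inclusive, so it can
exceed k); the reachability distance reach_k(p,o) = max(k-distance(o),
d(p,o)) smooths distances near cluster cores; the local reachability density
lrd(p) is the inverse mean reachability from *p* to its neighbors; and
LOF(p) is the mean ratio of neighbor densities to *p*'s own. A subject
embedded in material of its own density scores ≈ 1 regardless of what that
density is — LOF is a *contrast* statistic, not an absolute one. That
property cuts both ways and drives several choices below.

Degenerate geometry: a group of at least k+1 coincident subjects has
reachability sum 0 and formally infinite density. Such groups receive
LOF = 1 exactly (a maximally dense clump is the opposite of an outlier);
any other vanishing reachability sum is floored at 1e-12. Both the
vectorized scorer and the literal pure-Python oracle implement the same
convention, and agree to 1e-10 on random instances; on tie-free data both
also agree with scikit-learn's exactly-k implementation, which serves as an
independent cross-check in the tests (never as the scorer).

The scorer materializes the full pairwise distance matrix (scipy `pdist`),
which is exact and fast for cohort-scale data (n up to ~10^4; memory grows
as n²). Approximate neighbor search is deliberately out of scope.

## Preprocessing

Features are z-scored per column (population SD) before distance
computation. The instruments live on incommensurate scales — a vocabulary
count in the hundreds would otherwise dominate every distance. Zero-variance
columns are flagged, excluded from distances, and restored by the inverse
transform. Sex is carried in the cohort table but excluded from the default
distance features: a 0/1 code contributes a constant-size displacement that
distorts Euclidean density contrast between the sexes. Missing values are
not imputed; rows are expected complete.

Every re-scoring context (reduced sample after removal, each half-sample)
refits the standardization on the data actually scored, so no information
leaks from the full sample into a subsample's scale.

## Thresholding

The cutoff is the linear-interpolation percentile (the q-quantile at sorted
position 1 + q(n−1)), default 95, and flagging is strictly `score > cutoff`
— ties at the cutoff are never anomalies. With tie-free continuous scores
this flags at most ⌈0.05 n⌉ − 1 subjects.

The knee heuristic makes the informal "the score histogram turns from a
bump into a flat tail here" reproducible. It evaluates a Gaussian KDE at the
quantiles of a percentile grid (default window [85, 99], step 0.5) and
suggests the first percentile opening a sustained run (default 4 steps)
that is simultaneously *flat* — relative density slope per score unit,
scaled by the IQR, below 1.0 — and *low* — density below half the modal
density. Flatness alone would fire inside any dense bulk (in percentile
space dense regions always look flat) and the low-density condition alone
would fire on any tail; together they identify a flat, sparse regime. The
KDE bandwidth is the robust Silverman rule 0.9·min(SD, IQR/1.34)·n^(−1/5);
the plain-SD Scott rule is inflated by the very tail being scanned and
smears the bulk. All quantities compared are ratios, so the suggestion is
invariant to positive rescaling of the scores. If no knee exists (uniform
scores, pure Gaussian scores) the configured fallback percentile is returned
with a diagnostic. The heuristic needs ≥ 200 scores to populate the tail.

## Validation protocols

**Omit-and-recompute.** Remove the flagged subjects, refit standardization,
re-score, and count subjects strictly above the *original* cutoff. For a
genuinely separated low-density subpopulation this count is small and
concentrated near the cutoff; for a pure percentile artifact (no
contamination) re-scoring regenerates a fresh ~5%-sized tail. The test
suite asserts exactly this contrast on matched seeds.

**Half-sample resampling.** Each replicate draws ⌊n/2⌋ subjects without
replacement (per-replicate substreams spawned from one seed sequence, so
the report is reproducible and parallelizable), re-scores within the half,
and records: the percentage of within-half anomalies (half-score >
primary cutoff) that are also full-sample anomalies; the Pearson (optionally
Spearman) correlation between half and full scores over the sampled
subjects; and the percentage of within-half anomalies whose *full-sample*
score is ≥ a relaxed secondary cutoff, default the full-score percentile at
(percentile − 2.5). Replicates with zero within-half anomalies are excluded
from the two percentage means and counted separately. Whenever the
secondary cutoff is at or below the primary one, the secondary fraction
dominates the overlap by construction.

**Label-based recovery.** For synthetic cohorts with hidden labels,
precision/recall/F1 of the flagged set against the atypical labels; an empty
flagged set has recall 0 and, by convention, precision 0.

## The synthetic cohort generator

The generator emulates the *structure* a community toddler-screening table
is assumed to have, not any instrument's item-level psychometrics.

Typical subjects: a 5-dimensional latent Gaussian drives the social total
and four repetitive subscales; the social↔repetitive latent correlation is
configurable (default 0.4) and the repetitive subscales intercorrelate at
0.5. Latents map linearly onto plausible scale ranges — social 20 ± 5,
repetitive subscales roughly 5–8 ± 2–2.5 — floored at zero (the floor is
4+ SDs out, so the attenuation of means/correlations is negligible).
Vocabulary is an overdispersed negative binomial (mean 150, dispersion 3,
matching the very wide spread of expressive vocabulary at this age) coupled
to age through a Gaussian copula at default correlation 0.5; age is uniform
on [17, 25] months; sex is a balanced, independent Bernoulli carried for
realism only.

Atypical subjects are a fixed-count subgroup (round(rate × n), half-up, so
tests can assert exact counts). Their deviation model matters more than any
other choice in the package. Each atypical child shifts *upward* on every
social/repetitive scale by `effect_size_sd` × scale-SD × g, with g drawn
per child and scale from Gamma(shape 0.7, mean 1): a right-skewed severity
continuum — many milder cases, few severe ones, heterogeneous profiles —
whose mean standardized shift is exactly the configured effect size.
Baseline scatter is additionally inflated ×1.5, vocabulary is decoupled
from age (copula correlation 0) and its mean halved.

Why not a simple shifted cluster? Because LOF is a contrast statistic: a
subgroup of ~79 children cloned around a shifted centroid is *internally*
dense, each member's k = 20 neighbors are other members, and the whole
cluster scores ≈ 1 — the classic masking failure when an anomaly cluster
exceeds k. Symmetric within-group scatter does not fix this (it re-embeds
part of the group in the typical bulk). The unidirectional severity
continuum is both the clinically sensible picture — severity varies
continuously, children differ in which domains are affected, deviations run
toward greater atypicality — and the regime in which a density-based
detector is the right tool: the subgroup is a diffuse low-density tail, not
a second mode. Users studying the masking regime itself can lower
`severity_shape`'s spread or the dispersion and watch recall collapse.

What passing tests therefore show: that the pipeline recovers a diffuse,
unidirectionally shifted subpopulation at the configured effect size, and
that its scores and calls are stable under subsampling. What they do not
show: performance on real screening data, where the atypical geometry is
unknown, instruments are bounded and discrete, and missingness exists. The
cutoff values the pipeline prints (e.g. 1.464 on the reference cohort) are
properties of this synthetic geometry and the chosen k, not reusable
clinical constants.

## Problem sizes and numerics

The reference evaluation cohort is n = 1570 with 5% contamination at a 3-SD
effect, scored at k = 20 — scoring takes well under a second, and the full
pipeline with 1000 half-sample replicates runs in ~10 s. Statistical
recovery checks use larger generated cohorts chosen so the assertion band
is a multiple of the estimator's sampling error: correlations at n = 20 000
(±0.05 and ±0.03 bands), the standardized effect size at n = 100 000 —
under the severity continuum the atypical group SD is ≈ 3.9 typical SDs, so
the group-mean SE at n = 20 000 would be ~0.12, wider than a ±0.1 band; at
n = 100 000 the band is ~1.9 SE. Determinism is exact: one `default_rng`
stream with a fixed draw order makes identical specs produce bitwise
identical tables, and the pipeline report is byte-identical across reruns
of a fixed config.

## Known limitations

- O(n²) distance matrix; not intended beyond ~10^4 subjects.
- The knee heuristic assumes a unimodal bulk; strongly multimodal score
  distributions can trigger early or fallback suggestions.
- Generated marginals are continuous (scales) and unbounded above
  (vocabulary); real instruments are bounded sums of items.
- No missing-data handling beyond requiring complete rows.
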