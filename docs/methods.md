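# Methods

This note records the models, conventions and numerical choices behind
`carieseval`, and what the synthetic generator does and does not emulate.

## Geometry and matching

Boxes are axis-aligned rectangles in pixel coordinates, origin top-left,
stored as closed intervals `[x_min, x_max] × [y_min, y_max]` with strictly
positive area. The closed-interval convention makes the centroid-containment
boundary case well defined: a centroid lying exactly on the other box's edge
counts as contained. Two boxes *match* when either box's centroid lies inside
the other; the relation is symmetric but not transitive.

Label Studio rectangles arrive as percentages of the original image
dimensions and are converted to absolute pixels; COCO `bbox = [x, y, w, h]`
converts with `x_max = x + w` and no ±1 pixel adjustment (COCO coordinates
are continuous). Rotated rectangles are rejected rather than approximated:
the consensus and matching rules are defined on axis-aligned boxes, and
silently bounding a rotated box would change centroids.

## Consensus reference standard

Per image, expert boxes form a graph with an edge wherever the pairwise
match holds; connected components are lesions. Connected components are the
minimal transitive closure of the stated pairwise rule, deterministic, and
cheap to verify against brute-force closure of the match matrix (a standing
oracle test). Three consequences of this choice:

* **Vote over experts, not boxes.** An expert contributing two boxes to one
  component counts once toward the majority vote (`n ≥ 2` → majority set S,
  `n = 1` → minority set S′).
* **Combined box = union hull** of the member boxes. The hull preserves all
  expert evidence and is order-independent. An alternative (e.g. averaging
  member boxes) would shrink the target and bias centroid matching against
  candidates who agree with only one expert; the hull is the permissive,
  symmetric choice.
* **Chaining is possible** — A matches B, B matches C, A does not match C —
  typically for lesions on adjacent proximal surfaces. This is exactly the
  failure mode a human reviewer corrects. Corrections are declarative
  `MatchOverride` records (forced / forbidden pairs referenced by annotation
  id) applied before component formation, so every manual adjustment is
  reviewable in version control. An empty override list is a no-op; forced
  pairs are always edges; forbidden pairs never are.

Healthy-surface counts derive as `N_surfaces − |S| − |S′|`, under the same
one-lesion-per-surface approximation used for TN (below). The per-surface
caries prevalence is reported as a bracket: `|S|/N` counting only consensus
lesions, to `(|S|+|S′|)/N` including tentative ones.

## Scoring a candidate

Matching is staged: candidates first compete for majority (S) lesions; only
unmatched candidates may then match minority (S′) lesions. A candidate
matching both is therefore always a TP, never tentative — S′ exists to
absorb diagnostically uncertain marks, not to dilute ground-truth matches.

Within a stage the assignment is one-to-one and *optimal*: among all
assignments of centroid-matching (candidate, lesion) pairs, the one with the
maximum number of pairs and, among those, the maximum total IoU, computed
with the Hungarian algorithm (each feasible pair receives a constant bonus
larger than any achievable IoU total, so cardinality dominates). A greedy
best-IoU-first scan was considered and rejected: it can strand a candidate
whose only lesion was taken by a two-lesion candidate, producing a spurious
FP + FN pair where a two-TP assignment exists, and therefore cannot agree
with the brute-force enumeration oracle the matcher is tested against.
Optimal assignment is deterministic and O(n³) in per-image box counts
(single digits in practice).

IoU is computed between the candidate box and the lesion's *combined* box —
the reference standard is the combined lesion, not any single expert's
stroke. Mean IoU pools all matched pairs across images (each lesion weighted
equally) rather than averaging per-image means; with lesion counts varying
several-fold between images, per-image averaging would overweight sparse
images.

The TN approximation assumes the maximum number of lesions equals the number
of tooth surfaces, one lesion per surface:
`TN = N_surfaces − (TP + FP + FN + N_tentative)`. `N_tentative` is the
dataset-level minority count |S′|, not the per-annotator count of tentative
matches — the surfaces occupied by tentative lesions are unavailable as true
negatives regardless of whether this annotator marked them. (The dataset-level
reading also uniquely reproduces both published TN values from their rows'
other counts.) TN < 0 is treated as a hard error: it signals surface
metadata inconsistent with the annotation volume. The identity
`TP + FP + FN + TN + |S′| = N_surfaces` and the conservation law
`TP + FN = |S|` hold for every complete evaluation and are asserted as
invariants.

## Metrics and summaries

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy, precision
TP/(TP+FP), and F1 (harmonic mean of precision and sensitivity) are computed
on cumulative dataset-level counts. A zero denominator yields NaN — an
explicit undefined marker, never a silent 0 — and undefined values are
excluded from group summaries per metric with their count logged;
zero-filling would bias group means downward. Group summaries report the
mean, sample SD (n−1 denominator, the convention for small reader groups),
median, and IQR with linear-interpolation quantiles. Ratios are displayed at
2 decimals; full precision is retained internally and in CSV exports
(rounded columns are additional display columns).

## Statistical testing

Pre/post improvement per annotator is the per-metric delta `post − pre`
(errors included, so an improvement appears as a negative errors delta).
The paired test is a **sign-flip permutation test**: under the null each
annotator's delta is symmetric around zero, so the null distribution negates
deltas independently; the statistic is the mean delta, two-sided. All 2^n
sign patterns are enumerated exactly when 2^n ≤ 2^20 (n ≤ 20, which covers
reader-study group sizes), via subset-sum doubling; beyond that, seeded
Monte Carlo with the add-one convention (the observed pattern counts in
numerator and denominator), so p > 0 always and identical seeds reproduce
identical p-values. Comparisons of |T*| against |T_obs| use a 1e-12 relative
guard so ties generated by exact sign symmetry are not lost to float
round-off. At n = 17 the exhaustive test is exact: its simulated type-I
error at α = 0.05 sits inside [0.04, 0.06], and its power against a 1-SD
mean shift exceeds 0.95.

The normality screen is scipy's Shapiro-Wilk (re-deriving its coefficients
is out of scope); constant samples and n < 3 are rejected as degenerate
rather than returning a misleading W. Kruskal-Wallis (scipy-backed, tie
corrected, χ² reference with k−1 df) compares improvements across training
methods and academic stages; an all-constant pooled sample short-circuits to
H = 0, p = 1. **Dunn's post hoc** is implemented in-package (no installed
library provides it): pairwise z statistics on pooled ranks,

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1))) · (1/n_i + 1/n_j)),

two-sided normal p-values multiplied by k(k−1)/2 and capped at 1. It is
cross-checked through the k = 2 identity z² = H against the independent
Kruskal-Wallis implementation, and through Bonferroni-dominance and cap
properties. The significance level α = 0.05 is a report column, never a data
filter.

## Synthetic reader studies

The generator emulates the *structure* of a two-dataset pre/post training
study; its defaults are the study conditions the package is tested under.

**Geometry.** Each image is a grid of disjoint surface cells (default 50
images × 20 surfaces, 1000 × 500 px, two rows of ten cells). Each surface
carries a true lesion with probability `prevalence` (default 0.21), drawn
inside its cell. One lesion per surface by construction, so the TN
approximation is *exact* in simulation and testable as an identity.

**Difficulty and the minority set.** Every lesion has a latent difficulty
d ~ Beta(1.0, 1.5). An annotator's detection probability interpolates
linearly from `hit_prob_majority` (d = 0) to `hit_prob_minority` (d = 1).
The default expert panel (0.95 → 0.05, no false alarms — expert variability
is carried entirely by difficulty) yields, for three experts, a
detected-lesion split of ≈ 73% majority / 27% minority (ratio |S′|/|S| ≈ 0.41)
and ≈ 14% of lesions missed by all experts; with prevalence 0.21 this
produces ≈ 128 majority and ≈ 52 minority lesions per 1000 surfaces and an
annotated prevalence bracket of ≈ 13–18%, matching reported bitewing panels.
Difficulty is the abstraction of incipient lesions, which dominate real
minority sets.

**Students.** Student profiles default to *flat* detection probability
(`hit_prob_minority = hit_prob_majority`), making the profile's hit
probability equal to its expected measured sensitivity against S — the
property the parameter-recovery and calibration tests rely on. Group mean
profiles (sensitivity / per-surface false-alarm rate, pre → post):
lecture 0.75/0.034 → 0.73/0.014 (specificity rises), dataset 0.62/0.018 →
0.78/0.012 (sensitivity rises), AI 0.68/0.026 → 0.73/0.004 (both improve) —
group sizes 16/17/19. Each student adds a persistent ability offset
(Gaussian, SD 0.10) to the group hit probability and a persistent log-normal
multiplier (log-SD 0.5) on the false-alarm rate, identical in both sessions,
so pre/post deltas are paired within student. Note that simulated students
can "falsely" mark true lesions that no expert confirmed; these score as FP
against the reference, as they would in a real study — false-alarm rates
were chosen with this contribution included.

**Noise.** Marked boxes get log-normal scale noise and Gaussian corner
jitter (students 6 px / 0.25 log-scale; experts 2 px / 0.08). By default
jitter is resampled (up to 50 draws, then the true box) until the
centroid-containment relation with the true box survives, so default noise
never breaks matching; `preserve_containment=False` allows
containment-breaking jitter for matcher stress tests.

**Seeding.** One global seed expands into per-annotator substreams via
`SeedSequence` spawn keys derived from annotator ids (CRC-32), so adding an
annotator never perturbs anyone else's draws; seeded runs are byte-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: anatomy (no tooth shapes, no FDI surface
localisation, surfaces are equal-sized grid cells), lesions spanning
multiple surfaces or sharing one (the TN approximation is exact here,
approximate in reality), severity grades, correlated errors between
annotators viewing the same confusing image region (errors are independent
given the lesion), and reading-order or fatigue effects. Group effect
profiles reproduce the *direction and rough size* of published training
effects, not any study's exact tables.

## Problem sizes in the test suite

The acceptance-grade checks run at the sizes their claims name: the type-I
simulation uses 2000 replicate studies of n = 17 (exhaustive, exact
p-values); parameter recovery uses one 500-image dataset (≈ 10,000
surfaces); the matcher oracle enumerates 1000 random images with up to 6
boxes per side. The remaining suite runs on 5–50-image studies. The full
suite completes in well under a minute on one CPU.

## Known limitations

* The matcher's FN list identifies *which* S lesions went unmatched, but
  when multiple maximum-cardinality assignments tie on total IoU the pair
  composition (not the counts) may depend on the assignment solver's
  internal order.
* Overrides apply to expert consensus only; there is no override mechanism
  for candidate-to-reference matching.
* The Label Studio reader supports rectangle results only (no polygons,
  no relations) and treats each `completed_by` identity as one annotator.
* Dunn's test uses the normal approximation; for very small groups (n < 5
  per group) its p-values are approximate, as in standard implementations.
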