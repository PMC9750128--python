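# Methods

## Curve construction and geometry

An ROC curve is stored as an ordered polyline of (FPR, TPR) vertices with
its positive/negative counts. `build_roc` sorts genes by decreasing score
and emits one vertex per tie block. Two tie policies exist because they
answer different questions: the default `trapezoid` policy draws a single
diagonal across each tie block, so the trapezoidal area equals the
Mann–Whitney statistic U/(n_pos·n_neg) with tied pairs counted ½ (this
equivalence is tested against brute-force pair counting at 1e−12); the
`walk` policy orders positives first within a block and reproduces the
step-curve exactly as plotted. Straight-line detection is only meaningful
in the absence of ties — a tie block is trivially straight — so the
detector is normally run on continuous scores.

Interpolation resamples a curve at m evenly spaced FPR values (default
m = 200, the resolution used to harmonize curves of heterogeneous origin).
A vertical segment sitting exactly on a grid FPR is represented by its
upper TPR (supremum convention); the lower envelope systematically loses
area under resampling, the upper one does not. Interpolated curves
therefore may start at (0, t) with t > 0. Averaging of cross-validation
fold curves is vertical (pointwise mean TPR on the common grid) — the
fold-combination rule is not uniquely determined by convention, and
common-grid vertical averaging is the simplest choice consistent with
reporting "the average ROC curve"; the averaged curve carries the rounded
mean n_pos of its members so that normalized KS statistics remain
computable downstream. Note one geometric consequence checked in the
tests: vertically averaging a perfect and an anti-perfect curve gives the
constant-½ line (area 0.5), not the diagonal.

## Linearity statistic

For a subcurve rescaled to the unit square, the deviation from the
diagonal is `Dₙ = sup |TPR′ − FPR′|`. The sup is two-sided (absolute),
matching the two-sided one-sample KS convention; the deviation is
piecewise linear along the polyline so vertices suffice. The normalized
statistic is `D′ = Dₙ·√n` with `n` the number of positives the subcurve
spans, estimated as `max(1, round(n_total_pos · tpr_span))` — subcurve-
local, which is what makes a worked value like `D′ = 0.85` for a 5-positive
subcurve of a 20-positive curve come out right. For digitized curves with
unknown totals the conventional default is `n_total = 100`.

The p-value is the asymptotic Kolmogorov survival function
`Q(λ) = 2 Σ (−1)^{k−1} e^{−2k²λ²}`, implemented directly with the series
truncated when terms fall below 1e−10 and the result clamped to [0, 1].
It is verified against an independent Jacobi-theta-form implementation
(1e−8 on λ ∈ [0.3, 3]) and against `scipy.special.kolmogorov`. Anchor
values: Q(1.0) = 0.2700, Q(0.85) = 0.4653, Q(1.2) = 0.1122.

Why √n_pos and not the two-sample effective size √(n_p·n_n/(n_p+n_n)):
in the genomic regime positives are rare (1–10% of genes), where the two
coincide. Within a balanced subcurve the n_pos normalization overstates
the effective n by up to √2, making D′ conservatively large — the
linearity tag errs toward "not straight" there. This shows up in the
simulations (below).

## FEC extraction

Candidates are all vertex pairs of the working curve (default: the
200-point interpolation; `grid=None` uses native vertices, appropriate for
curves with few exact vertices) whose FPR span is at least 5% — a straight
line is only claimed over a meaningful share of negatives. A candidate is
linear when `D′ ≤ 1` (asymptotic p ≥ 0.27), a deliberately permissive
cutoff: the null here is the hypothesis we *want* to accept. Horizontal
subcurves (zero TPR span) have undefined KS — a run of negatives is a
perfect straight line — and are reported with missing statistics (`NA`)
while still counting as linear candidates; vertical subcurves have zero
FPR span and are never candidates nor counted toward coverage.

Selection is greedy: repeatedly take the linear candidate with the largest
FPR span (ties: smaller D′, then smaller FPR₀ — added for determinism),
discard all candidates sharing interior FPR with it, stop when none
remain. Removed candidates are not re-tested or trimmed. Coverage is the
summed FPR span of the final list. The pairwise D table is computed in
O(m³) via a cross-product cumulative-maximum recurrence, ~0.1 s at
m = 200.

## Longest-segment approximation and subcurve flipping

The longest detected FEC supplies two anchors; the curve is replaced by
chords (0,0) → (FPR₀,TPR₀) → (FPR₁,TPR₁) → (1,1), collapsing to 3 or 2
anchors when the segment touches a corner. The error is the relative
trapezoidal-area error against the original curve (relative, not absolute:
a 0.02 absolute error means something different at AUROC 0.55 than at
0.95). The reduction can be exact for a 3-segment curve only when the
longest segment is the middle one; when an outer segment is longest, one
interior kink necessarily falls outside the anchor set.

"Flipping" a subcurve is point reflection of its interior vertices about
the midpoint of the chord joining its endpoints (order reversed). This is
the unique involution that fixes the endpoints, maps straight segments to
themselves, and corresponds to inverting the classifier within that score
range. The area change of flipping (i, j) is
`(x_j − x_i)(y_i + y_j) − 2·A_sub` with `A_sub` the trapezoidal area under
the subcurve, so the optimum over all vertex pairs is found in O(m²) from
prefix areas; the identity is always a candidate, making the result a
guaranteed weak improvement. An exhaustive flip-and-integrate search is
kept as the test oracle.

## Neighbor voting (EGAD)

For a symmetric non-negative weight matrix X and training one-hot P:
degree `D_i = Σ_j X_ij`, votes `V = X·P`, normalized votes `V′ = V/D`
(zero-degree genes vote 0 with a warning). Cross-validation is 3-fold over
the annotated genes, folds assigned by seeded shuffle with remainders to
the first folds. Training positives are masked out of their fold's
evaluation set entirely — they are neither positives nor negatives;
scoring known positives as negatives would deflate the AUROC. The diagonal
of X participates in degrees and votes as given, since the defining sums
run over all j. The reported result is the mean fold AUROC and the
vertically averaged fold curve. Sets below a configurable minimum size
(default 20) are skipped.

## Network preparation

Shortest-path propagation densifies a sparse network: `w_ij = 1/d_ij` with
`d_ij` the hop-count shortest path over the nonzero entries (weighted
inputs are thresholded at > 0 — hop count is an approximation there),
`w_ii = 1`, disconnected pairs 0. TF-IDF cosine similarity converts a
binary item×feature matrix into an item similarity network; the default
idf is the smooth variant `ln((1+n)/(1+df)) + 1`, which stays finite and
positive for ubiquitous features, with the classic `ln(n/df)` available by
option. Top-fraction binarization thresholds a real score matrix at the
global (not per-feature) quantile of its nonzero entries — "top 10% of
interactions" reads as a global cut — then drops features supported by
fewer than 20 items.

## Simulation models

**Gaussian model.** Each gene has a latent state with mean score μ;
assessing a gene draws N(μ, σ). Presets: on/off (μ ∈ {0, 1}, proportions
{0.8, 0.2}, σ_ann = ½), on/low/off (μ ∈ {0, ½, 1}, {0.5, 0.3, 0.2},
σ_ann = ⅓), continuous (μ ∈ {0, ⅓, ⅔, 1}, {0.4, 0.3, 0.2, 0.1},
σ_ann = ¼); default 10 000 genes. The annotating assessment thresholds its
scores at 0.2, so ~20% of genes are truly functional in the on/off preset
while the annotation itself is noisy — both facts the preset is meant to
embody. Re-assessments at σ ∈ {0.1, 0.2, 0.3, 0.4} are independent of the
annotation; across σ levels they share one standard-normal draw per gene
(common random numbers), so σ acts as a pure noise dial and the AUROC is
non-increasing in σ along every sample path. With independent draws the
expected AUROC gap between σ = 0.1 and 0.2 on the on/off preset is ~4·10⁻⁴
— far below seed noise — so the coupled design is what makes the
degradation property testable at all.

A consequence worth stating plainly: with σ_ann = ½ and threshold 0.2,
about 35% of non-functional and 95% of functional genes end up annotated.
The functional-state segment of the low-noise on/off curve then spans only
~2% of the FPR axis — below the 5% minimum span — so the detector
typically reports one or two FECs on that preset rather than one per
state, and the two-state structure is visible mainly through the curve's
kink and the coverage statistic. The three-state presets, whose segments
all span well over 5%, are the ones on which segment-per-state recovery
and the longest-segment approximation behave as advertised (≥ 85% of
replicates within 5% relative AUROC error at σ = 0.1, n = 2000).

**Network model.** 4 communities of equal size (default 2500 genes each);
between-community weights N(2, 2), within-community N(μ_w, 2) with μ_w
swept over {2.0, 2.1, 2.2, 2.3} for increasing observed modularity (a
per-community list is also accepted). Negative draws are clipped to 0 —
N(2, 2) has ~16% negative mass and the voting algebra requires
non-negative weights. Each unordered pair gets one draw mirrored to both
entries; the diagonal comes from the within distribution. Annotation
presets give the per-community labeling probability: non-modular (all
0.5), on/off (0.8, 0.1, 0.1, 0.1), on/low/off (0.8, 0.5, 0.1, 0.1),
continuous (0.4, 0.3, 0.2, 0.1).

What the simulators do not emulate: real degree heterogeneity and hub
structure, overlapping annotations and multifunctionality, dependence
between annotation quality and expression level, and the identifier-
mapping noise of real resources. Passing tests on these models show the
statistics behave as designed under their stated null and alternative,
not that any particular biological dataset is piecewise linear.

## Problem sizes and numerical choices

Tests and the reproduction script run at 2000 genes (networks: 4×500),
50 simulation replicates, 20 seeds per network condition and 1000
null-calibration replicates, sizes at which every reported quantity is
stable to well within its stated tolerance. The null calibration places
100 positives among 2000 genes — the imbalanced regime the √n_pos
normalization presumes; its exceedance frequency of the D′ ≤ 1 cutoff is
checked against the nominal 0.27 within ±0.04. Floating-point tie-breaks
use 1e−12 slack throughout; interval overlap means shared interior, so
FECs may share endpoints. Digitized curves are never auto-repaired:
non-monotone TPR raises an error unless isotonic repair is explicitly
requested, because silent straightening biases the KS statistic the
curves are read for.
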