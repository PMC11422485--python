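# Methods

This note documents the models and procedures implemented in `wormspaces`,
the parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Posture representation

Each frame is thresholded (default: the midpoint of its dynamic range) and
contoured with marching squares (`skimage.measure.find_contours`); when
several contours appear, the one with the most points is kept and the frame
is flagged. The ring is normalized to counter-clockwise orientation using
the signed polygon area so that turning-angle signs are consistent across
frames. For end detection the ring is circularly smoothed with a Gaussian
of width σ_c = 2 points; curvature at each point is the signed turning
angle divided by half the chord through its neighbors, and the two largest
strict local maxima are the candidate body ends (ties broken toward the
lower index). End labels are carried across frames by choosing the labeling
with the smaller summed travel since the last successful frame; the ratio
of the chosen to the alternative sum (the *distance ratio*, always in
[0, 1]) measures how unambiguous that choice was.

The midline is computed by splitting the contour at the two ends and
fitting a chord-length-parameterized cubic spline to each half
(`scipy.interpolate.splprep`). The halves are fitted on the *raw* contour
rather than the Gaussian-smoothed ring: smoothing a closed ring shrinks the
high-curvature tips inward by 1–2 px, which biases the midline ends, while
a small spline smoothing budget (0.09 per contour point) absorbs the
half-pixel rasterization stair-steps without the shrinkage. Both halves are
sampled at 41 equally spaced parameter values, averaged pairwise, and the
resulting polyline is iteratively refit and resampled until the spacing
coefficient of variation is below 0.01 (at most 20 iterations). The 39
signed angles at interior points, minus the two extremes (noisiest near the
tips), give the 37-value curvature vector; positive means a left turn
traversing head → tail, so mirroring the animal negates the vector. On the
default synthetic renders the midline RMS error is ≈ 0.3–0.6 px and the
curvature RMS error ≈ 0.02 rad.

Frame-quality filters: a frame is omitted if (1) multiple contours were
found, (2) its distance ratio exceeds 0.2, (3) it belongs to a run of ≥ 2
consecutive frames with no computable ratio, or (4) its roundness (interior
area / contour length) has a Z-score above 3 relative to frames within
±5000 frames (window clipped at the recording edges; a zero-SD window
defines Z = 0). Filters (2) and (3) catch end-tracking failures; (4)
catches curled postures whose contour is not worm-like.

## Head identification

Retained frames form segments; each segment is classified independently.
End trajectories are smoothed with a Gaussian of σ = 5 frames, truncated
and renormalized at segment edges (σ is interpreted in frames, matching the
per-frame notation of the speed estimator). Speeds are central differences;
the head is the end with the positive mean natural-log speed ratio, the
confidence is |mean lsr|, and only segments with confidence strictly above
0.05 enter downstream pooling. Frames where either end's estimated speed is
exactly zero are excluded from the mean rather than contributing ±∞.
Segments whose head is "end 2" have their curvature rows reversed and
negated so all vectors run head → tail.

## Developmental time

Speed is s_i = |p_{i+3} − p_i| (px/s at 3 fps). Around each boundary guess
t_k, statistics are collected from a_k = 0.7 t_{k−1} + 0.3 t_k to
b_k = 0.3 t_k + 0.7 t_{k+1} (with t_0 = hatch and t_5 = recording end; the
asymmetric weights are implemented exactly as specified upstream). Speed is
averaged in non-overlapping 300-frame blocks, each block mapped to its ECDF
quantile among the range's blocks (right-continuous, ties counted ≤;
missing blocks get quantile ½ so tracking gaps are neutral), smoothed with
a Gaussian of σ = 10 blocks, and the lethargus is the maximal run of blocks
below quantile 0.2 containing t_k's block; if t_k's own block is at or
above 0.2 the boundary fails. Stage boundaries are the detected interval
midpoints; each stage is divided into 10 equal-time bins (bin membership of
a pooled window is decided by its start frame).

A bias worth knowing: the σ = 10-block smoothing erodes the detected
interval by roughly 4–8 blocks per side, so detected lengths underestimate
the true quiescent period by up to ~1 h and the Jaccard overlap with a 2-h
planted episode averages ≈ 0.83. Dips much shorter than the smoothing scale
(≲ 17 blocks ≈ 0.5 h) retain too little kernel mass to cross the 0.2
threshold and are undetectable by construction; sensitivity is therefore
validated at ≥ 24-block dips, and the generator's default episode length is
2 h, the biologically typical value.

## Behavioral spaces and dimensionality

A behavioral space is the mean-centered PCA of a pool of flattened 10-s
windows (T_w = 30 frames × 37 angles = 1110 features); centering is the
standard PCA contract and makes the variance normalization of the distance
metric meaningful. Loadings are orthonormal, score variances use the n − 1
convention, and their sum over all components equals the pooled variance.

Dimensionality is estimated by bi-cross-validation of the features ×
windows matrix M: every row and column is held out independently with
probability 0.1, M is partitioned as [[A, B], [C, D]] with A the held-out
block, D is factored by SVD into axes and scores, held-out scores (for C)
and axes (for B) are least-squares solutions, and
Â(d) = Û_B(d) V̂_C(d)ᵀ predicts A, giving the relative error
ε_d = Σ(A − Â(d))² / Σ(A − Ā)². Degenerate draws (empty A, kept block
smaller than 2×2, constant A) are redrawn. Errors for all d come from one
SVD per draw via rank-1 updates. The procedure is repeated k times
(defaults: N = 1000 sampled windows, k = 10, d in 1..50); for each of
K = 10,000 bootstrap resamples of the k errors the stopping rule is
applied and the resulting dimensionalities averaged and rounded half away
from zero.

Stopping rule: with ε_0 ≡ 1, find the first d whose log₁₀ error decrease
from d − 1 falls below δ = 0.01 and report the preceding dimension
(floored at 1). Reporting the *preceding* dimension is deliberate: the
first sub-δ step is the first dimension that no longer helps, so the last
useful dimension is d − 1. On noiseless planted-rank data this returns the
planted rank exactly, and on isotropic noise it returns 1. The δ = 0.01
criterion operates on held-out error, so any real-but-small variance
component that still improves prediction by ≥ 2.3% counts as significant —
with few individuals this lets the strongest individual-unique modes into
the *population* space (see the generator section).

Individuals reuse the population dimensionality, capped at the number of
components explaining 99% of their own variance. When a pool holds fewer
than N windows, all are used.

## Space comparison

The relative distance d(V, W) = Σ λᵢ |(I − W Wᵀ) vᵢ|² / Σ λᵢ is the
expected squared residual of a random vector drawn from V's mode
distribution after projection onto span(W), normalized to [0, 1]. It is 0
when W spans V, 1 when the spans are orthogonal, depends on W only through
its projector, and decomposes exactly between a subspace and its orthogonal
complement. Between-bin and between-population comparisons use the
symmetrized average of both directions, each truncated at its own
dimensionality. Temporal structure is summarized by the mean symmetrized
distance at each bin lag; its Pearson correlation with lag is tested
against 1000 random orderings of the bins, with (b + 1)/(n + 1) smoothing
so p is never zero. Missing bins are skipped pairwise. Shared-space
distances use per-PC variance fractions f_k = var(score_k)/total, compared
as Σ_{k≤n_b} |f_ind/f_pop − 1| with n_b from cross-validation (per-bin
spaces) or the smallest n with cumulative population fraction above 0.7
(single shared space). Population dendrograms use complete linkage on the
symmetrized distances (exported as Newick); t-SNE layouts from precomputed
distances (perplexities 20 for bins, 10 for individuals) are seeded but
treated as non-contractual visualization.

## Individuality statistics

Within each experiment and bin, distances are converted to fractional ranks
(ties averaged) and normalized to u = (r − ½)/n ∈ (0, 1); the per-bin mean
is exactly ½ and every statistic downstream depends on the distances only
through their ranks. Consistency is the median Pearson correlation of u
across individuals over all pairs of bins in the consistency range (bins
6–50; earlier bins have too many missing spaces in practice). Significance
is one-sided against 1000 datasets in which u values are permuted
independently within each experiment and bin — one-sided because
consistency and rank-variance are directional alternatives. The same
shuffles serve the per-stage-pair medians (15 unique cells,
Benjamini–Hochberg corrected; within-stage cells exclude self-pairs) and
the variance of per-individual mean ranks. The permutation p-value is
exactly discrete-uniform under the null (verified by simulation), so a
failed calibration indicates a real bug, not tuning.

## Synthetic generators

*Worm frames.* A tapered body (half-width 4.5 · sin(πs)^0.6, length 80 px)
undulates via a traveling curvature wave (amplitude 2 rad, 1.5 spatial
periods, phase speed 0.06 rad/frame) plus a head-concentrated oscillation
(amplitude 6 rad decaying over 25% of the body, period 30 frames ≈ 10 s)
that makes the head tip the faster end; heading is integrated outward from
the body midpoint so neither end accumulates the whole wave. Frames emulate
a tracking crop: the COM random-walks within 8 px of the image center.
These kinematics were chosen so that body-bend curvature stays below tip
curvature (otherwise the detected "end" slides smoothly from the tip onto a
neck bend — a failure mode the distance-ratio filter cannot catch because
it is gradual). Not emulated: self-overlapping coils, grayscale texture,
illumination gradients, or size growth across stages; passing tests
therefore validate the geometry pipeline, not robustness to those real-data
effects. Injected "curl" frames (disks) exercise the roundness filter.

*Window populations.* Windows are drawn as B_b z + η_i U_i z′ + ε: per-bin
population bases B_b follow a Grassmann geodesic between two random
subspaces (so inter-bin distance grows monotonically with lag), mode
variances decay as 0.8^j, η_i ∈ [0, 1] scales each individual's unique
modes (2 per individual; redrawn per bin for inconsistent individuals), and
ε is isotropic with total variance 1/SNR of the signal (default SNR 100).
Defaults are 24 individuals × 50 windows per bin: with fewer individuals
each unique mode is a large enough share of the pooled variance that the
population dimensionality estimate absorbs the strongest individuals'
modes, inverting the uniqueness ordering at the top — an artifact of small
n, not of the method, which disappears at the hundreds-of-individuals scale
the pipeline targets. 24 individuals is the smallest population for which
the estimated population dimensionality stays near the planted rank.

*COM traces.* Stage durations default to (14, 9, 9, 10, 16) h at 3 fps with
2-h lethargus episodes centered on each boundary; active/quiescent speeds
18 / 0.5 px/s with 30% multiplicative noise and a slow heading walk.
Optional tracking gaps write NaN runs.

*Rank-level null.* For p-value calibration, iid distances per bin stand in
for the full pipeline on an η = 0 population: at the rank level the two are
distributionally identical (distances are exchangeable across individuals
within each bin), and the rank-level null is two orders of magnitude
cheaper. The η = 0 full-pipeline null is still exercised once in the
generator tests.

## Problem sizes

Tests and the acceptance checks run the method at desk scale: pools of
300–1200 windows, 5 holdout repeats, 300–1000 bootstrap resamples, 200–1000
shuffles, 50-bin populations of 24 individuals, and 5 full-length COM
traces. These sizes keep every statistic's decision margin wide (e.g.
planted-rank recovery is exact at N = 500, k = 5) while the full paper-scale
constants (N = 1000, k = 10, K = 10,000, 1000 shuffles) remain the library
defaults.

## Known limitations

- No untangling of self-overlapping postures; curled frames are filtered,
  not resolved.
- Head identification is per-segment; a segment misclassified whole stays
  misclassified (no temporal voting across segments).
- Lethargus episodes much shorter than the quantile-smoothing scale are
  undetectable by design, and detected interval edges are eroded by the
  smoothing (see above).
- The bin-shuffle test for the distance-vs-lag correlation treats bins as
  exchangeable; long-range autocorrelation of estimation noise across bins
  is not modeled.
- t-SNE layouts are stochastic and for visualization only.
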