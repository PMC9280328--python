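# Methods

This note documents the models, parameter choices and numerical conventions
behind `seizurepath`, and what the synthetic-data tests do and do not show
about real recordings.

## Preprocessing

Raw seizure clips (channels × samples, with onset/termination markers and a
per-sample missing mask) pass through: cohort-wide downsampling to the lowest
sampling rate (polyphase, anti-aliased); linear interpolation of missing
segments shorter than 0.05 s (longer gaps and edge gaps stay missing);
common average referencing over non-excluded channels; and a 1–150 Hz
band-pass with mains notches (2 Hz-wide band-stops at 50/100/150 or
60/120 Hz). "Fourth-order, zero-phase" is implemented as a 4th-order
Butterworth applied forward-backward (`filtfilt`), i.e. an effective
8th-order magnitude response — the standard reading of that phrase.

Signal dropouts in chronic telemetry are detected by line length
`L = mean |x_{t+1} − x_t|` in 0.1 s windows advancing by 0.05 s: a window
where at least half the montage (⌈n/2⌉, i.e. 8 of 16 channels) has `L ≤ 0.5`
is marked missing together with its immediate neighbours. The half-montage
rule generalises the 16-channel convention to other montage sizes. Windowing
throughout is sample-indexed, 0-based, half-open, with the seizure clock
starting at the onset sample. Noisy channels are an input exclusion list:
identifying them (typically by visual review) is outside the package.

## Connectivity ("pathway") features

Band-averaged coherence sums cross- and auto-spectra over in-band FFT bins
*before* forming the ratio; by Cauchy–Schwarz it lies in [0, 1], reaching 1
for identical signals. Welch spectra use 2 s Hamming-tapered, mean-detrended
subwindows with 1 s overlap and FFT length equal to the subwindow. Band
membership of a bin is half-open (`f1 ≤ f < f2`) so shared band edges are
counted once. FC windows are 10 s long, step 1 s, and must lie wholly inside
the seizure, giving `m = floor(duration) − 9` windows; seizures under 10 s
are rejected. A window tolerates up to 4 missing 2 s subwindows (spectra are
then averaged over the clean ones); at ≥ 5 it is marked missing, and any
seizure with a missing window is excluded from analysis. Each band block of
each window is L1-normalised; an all-zero block is left at zero and the
window flagged rather than divided by zero.

## Stability NMF

Per subject, all FC windows are concatenated into a nonnegative `F × N`
matrix and factorised with multiplicative-update NMF (Frobenius loss) from
random restarts. For each candidate rank the restarts' basis matrices are
matched pairwise by a Hungarian assignment on cosine similarity; the rank's
stability is the mean over restart pairs of the *worst* matched-component
similarity. Using the worst rather than the average component makes the
score discriminative above the true rank: an overcomplete factorisation
still reproduces the true patterns (keeping the average high, ≈ 0.92 on
planted rank-3 data) while the redundant component wanders between restarts
(dragging the minimum to ≈ 0.8). The selected rank is the largest candidate
with stability ≥ 0.9, and the returned model is the lowest-error restart at
that rank. The reconstruction `W·H` replaces the raw windows downstream;
per-band re-normalisation of the reconstruction is off by default, and the
whole stage can be bypassed (identity pass-through) for oracle tests.

## Pairwise measures

**DTW pathway dissimilarity.** Classic dynamic time warping with unit steps
(match/insert/delete), both endpoints anchored, local cost = cityblock (L1)
distance between window feature vectors, no global warping-window
constraint. The dissimilarity is the total optimal path cost divided by the
path length K (the number of aligned window pairs — the warped series
length). Because tied minimal-cost paths can have different lengths, the
implementation maximises K among minimal-cost paths (a lexicographic dynamic
program), which makes the reported average unique and lets an exhaustive
path-enumeration oracle reproduce it exactly. Repeating windows of a
pathway (a pure elastic stretch) therefore costs nothing. The pathway
matrix need not satisfy the triangle inequality (the normalising K differs
between pairs) and this is deliberately not asserted.

**Duration difference.** `|ln l_i − ln l_j|`: a metric on log durations,
invariant to rescaling all durations, equal for any two pairs with the same
duration ratio. The similarity threshold 0.2 corresponds to allowing an
`e^0.2 ≈ 1.22`-fold increase over the shorter seizure.

## Association and multiple comparisons

Spearman correlation (average ranks on ties) between the upper-triangular
entries of the two matrices; undefined (NaN) if either entry set is
constant. Significance via the Mantel test: rows and columns of one matrix
are permuted jointly, preserving its internal structure; the one-sided
p-value uses the add-one convention `p = (#{ρ* ≥ ρ} + 1)/(n_perm + 1)`, so
p ∈ (0, 1] always. When `s!` does not exceed the requested permutation
count the distribution is enumerated exhaustively instead (with a warning).
Calibration under independent random matrices is verified by simulation
(type-I error 0.052 at α = 0.05 over 1000 runs). Across subjects, p-values
are corrected by Benjamini–Hochberg FDR (step-up, α = 0.05).

## Truncation detection

Seizures are grouped by UPGMA (average-linkage) clustering of the pathway
dissimilarity matrix, cutting the dendrogram at height 1 (merges at height
≤ 1 stay merged); each group's centroid is the member with the lowest mean
dissimilarity to the rest. For each ordered group pair (A, B) three criteria
apply: (i) every A-duration strictly below every B-duration; (ii) every
A-pathway-size (maximum cityblock distance between any two windows; zero for
single-window pathways) strictly below every B-size; ties fail both — a
conservative reading; and (iii) the partial-pathway profile — DTW
dissimilarity between centroid A and the first m windows of centroid B,
scanned over m — dips to ≤ 1. Criterion (iii) is evaluated on centroids
only; members inherit the flag, and all |A|·|B| pairs count as truncation
pairs. The subject's truncation proportion is flagged pairs over s(s−1)/2.

## Pair taxonomy

With `d_path ≤ 1` (similar pathway, inclusive) and `d_dur ≤ 0.2` (similar
duration, inclusive), the four categories partition all pairs; *elastic* =
similar pathway + different duration, *semblant* = different pathway +
similar duration. The thresholds are configuration parameters; an optional
helper (`match_similarity_thresholds`) quantile-matches the duration
threshold so the global proportion of duration-similar pairs equals that of
pathway-similar pairs, mirroring how such thresholds can be balanced across
a cohort, but it is not applied by default.

## Duration populations

Log durations are clustered by k-means for k = 1..min(s, 10). Because the
data are 1-D, k-means is a hand-vectorised Lloyd iteration run in batch over
all reference datasets at once (the first initialisation places centres at
evenly spaced quantiles — near-optimal in 1-D — plus random restarts, 10 for
the observed data); this matches sklearn's inertia to within local-optimum
noise and is two orders of magnitude faster for the reference ensemble. The
gap statistic compares `log W_k` (within-cluster sum of squares) against
reference datasets drawn uniformly over the observed range — in 1-D the
principal-component-aligned box reduces to exactly this interval — with
`SE(k) = sd_ref[log W_k*]·sqrt(1 + 1/B)`. The selected k is the smallest
with `gap(k) ≥ gap(k+1) − SE(k+1)` (the one-standard-error "first max"
rule); k = 1 means no distinct duration populations. Identical durations
short-circuit to k = 1.

A known property of this estimator, reproduced independently by R's
`cluster::clusGap` with the same rule: for two equal-weight log-duration
modes separated by 3 within-mode standard deviations, k = 2 is selected in
only ~15–30% of draws (the observed clustering gain at that separation,
ln(Δ²/4σ² + 1) ≈ 1.18, is smaller than the uniform reference's own two-means
gain of ln 4 ≈ 1.39, so the SE rule usually stops at k = 1). Separations of
~6 sd are detected essentially always. Detecting multiple duration
populations therefore requires clearly separated modes; this is a property
of the gap statistic with a uniform reference, not of this implementation.

When k ≥ 2, pathway clusters are obtained by cutting the UPGMA dendrogram of
the pathway dissimilarity matrix into exactly k groups, and the two
partitions are compared with the Rand index and adjusted Rand index;
one-sided permutation p-values permute one membership vector (add-one
convention).

## Embedding

Sammon stress `E = (Σd)⁻¹ Σ (d_ij − δ_ij)²/d_ij` is minimised by gradient
descent with a step-halving line search from a classical-MDS
initialisation (plus a seeded 1e-6-scale jitter to break exact
degeneracies); accepted iterations never increase the stress. Defaults:
max 500 iterations, relative-improvement tolerance 1e-9, epsilon floor 1e-9
on zero target distances. The pipeline embeds at most 400 windows (a seeded
subsample) to keep the O(n²) distance handling modest.

## Synthetic cohort generator

The generator produces the structures the pipeline is designed to detect —
it makes no claim of biophysical realism (no ictal waveform morphology, no
postictal/interictal dynamics). A subject has a dictionary of latent network
**states**: sparse band-specific connectivity templates (mass on a random
quarter of channel pairs per band, L1-normalised, redrawn until pairwise
cityblock distances exceed a margin of 3 so different states are
unambiguous). A **pathway** is an ordered state sequence with dwell
fractions; a seizure renders it at one window per second (the same
`floor(duration) − 9` rule as measured connectivity), linearly cross-fading
between states over one window so pathways are not unrealistically
discontinuous, with clipped-Gaussian feature noise (default sd 5e-4,
i.e. ~6% of the mean feature value 1/n_pairs) followed by per-band
re-normalisation.

Defaults describe one subject: 16 channels, 2 base pathways × 5 seizures,
durations lognormal(μ = ln 60 s, σ = 0.5) (log-transformed durations are
near-normal; a floor of 15 s keeps every seizure analysable), plus 2 planted
elastic pairs (same pathway, log-duration ratio drawn from [0.4, 1.0],
independent dwell warps), 2 semblant pairs (different pathways, durations
matched within |ln ratio| ≤ 0.05) and 2 truncation doublets. Each truncation
doublet lives on its own dedicated pathway: the child realises the leading
40% of the dwell mass at proportionally shorter duration, and the state
order is resampled until the prefix's template spread is strictly below the
full pathway's, so the child is smaller in pathway size as well as shorter —
making the planted relation detectable by construction rather than by luck.
The optional bimodal duration model is a two-component lognormal mixture
with the second log-mode 3 sd above the first. An optional raw-signal
renderer drives channels with per-band narrowband Gaussian sources whose
channel loadings are a rank-1 factorisation of the active state's template
(so estimated coherence correlates with the template), plus white channel
noise; a dropout injector flattens chosen intervals for the line-length
detector to find.

Because durations are sampled independently of pathway identity (except
where pairs are planted), default cohorts show a weak or even negative
pathway–duration correlation; the generator measures the pipeline's
discrimination of planted structure, not any particular association
strength. Passing tests on these cohorts therefore demonstrate that the
measures recover known structure under controlled noise — not that the
generator's geometry matches real iEEG, where noise is correlated across
features, states drift continuously, and pathway variability is not a draw
from a template dictionary.

## Numerical conventions

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical config + seed reproduces cohorts and
  pipeline outputs byte-for-byte.
- DTW ties are resolved toward longer paths among equal-cost paths
  (tolerance 1e-15 in the DP comparison).
- Permutation p-values use the add-one convention and are never 0.
- Degenerate inputs fail loudly: non-positive durations, negative matrices,
  asymmetric matrices on file load, empty pathways, too-short seizures,
  overlapping dropout intervals.

## Problem sizes

Tests and the acceptance script run the pipeline at the default subject size
(14 seizures, ~400 FC windows, 720 features), recovery checks over 5 seeds,
Mantel calibration with 1000 independent runs × 200 permutations, and
gap-statistic simulations over 20 seeds with 100 reference datasets —
sizes chosen so the full suite completes in about a minute on one CPU while
keeping Monte-Carlo error well below the asserted margins.
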