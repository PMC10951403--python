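# Methods

This note documents the models, numerical conventions and design choices
behind `texgeom`, and what the synthetic-data tests do and do not establish.

## Stimulus model and normalization

Stimuli are square grayscale images labelled by texture family, class
(texture / scramble), exemplar and rotation (0° or 90°, implemented as a
lossless transpose-and-flip). Luminance and RMS contrast are equalized by
z-scoring the pixels and mapping to mean µ = 0.5 and standard deviation
σ = 0.15 (population convention, ddof = 0, used throughout the package). The
map is affine and increasing, hence rank-preserving and idempotent.

Scrambles are produced by keeping the 2-D Fourier amplitude spectrum of a
texture and replacing its phases with those of a seeded Gaussian-noise
image. Because the FFT of a real image has Hermitian-symmetric phases, the
recombined spectrum is Hermitian by construction and the output is real with
no truncation bias; the DC term is copied verbatim so the mean is preserved
exactly. Amplitude spectra agree to ~1e-15 relative error.

Spectral band control (`rescale_to_band`) magnifies an image about its
center by exact Fourier interpolation (no resampling replicas) until at
least 95% of the Fourier amplitude lies below 0.5 cycles/degree. Coverage is
measured on the mean-removed, Hann-tapered image: the taper confines the
spectral leakage of the finite crop window, which would otherwise place an
irreducible floor (~50% for broadband images) on out-of-band amplitude no
matter how far the image is magnified. Iteration counts and scale factors
are logged, and a family-mean spectral-overlap diagnostic is recorded.

The raised-cosine vignette has gain 1 over the inner 80% of the radius by
default and falls as ½(1 + cos πt) over the outer 20%; it never increases
|pixel − µ|. Histogram-matched control sets map every image onto a common
seeded Gaussian reference by monotone rank mapping (scikit-image
`match_histograms`), before renormalization, so that skewness and kurtosis
are uninformative of family and class.

## Steerable pyramid

The pyramid is a frequency-domain, polar-separable construction: raised-
cosine (in log₂ radius) high/lowpass pairs split octave annuli recursively,
and each annulus is divided into K = 4 angular lobes ∝ cos^(K−1)(θ − θ_k)
restricted to a half plane, making the oriented bands analytic
(complex-valued). Masks are normalized so the squared two-sided responses
tile the plane exactly; analysis→synthesis round trips and the Parseval
energy partition hold to machine precision (~1e-15, asserted at 1e-6).

The pyramid is **undecimated**: all bands stay at full resolution and the
correlation neighborhood is dilated by 2^(scale−1) instead of subsampling.
With circular boundary handling every statistic is a full-image spatial
average, so circularly shifting the input changes no statistic (verified to
1e-6; measured at ~1e-16). A decimated pyramid would break this bound
through fractional-shift aliasing of the magnitude maps at coarse scales.

## Statistics inventory (740 coefficients at the defaults)

With 4 scales, 4 orientations and a 7-sample neighborhood (M = 7, giving
(M² + 1)/2 = 25 symmetry-deduplicated autocovariance lags):

| group | contents | count |
|---|---|---|
| marginal | pixel skewness, kurtosis (population moments, kurtosis not excess) | 2 |
| spectral | lowpass autocovariances 25 × 5 levels; 18 magnitude means (16 bands, \|highpass\|, \|lowpass\|); highpass variance; lowpass skew/kurt | 146 |
| linear | real cross-orientation covariances 6 × 4 scales; real/imag covariances with the phase-doubled parent 4 × 4 × 2 × 3 | 120 |
| energy | magnitude autocovariances 25 × 16 bands; magnitude cross-orientation 6 × 4; cross-scale 4 × 4 × 3 | 472 |

Covariances are population moments of mean-removed maps. The phase-doubled
parent is b²/|b|, which carries cross-scale phase alignment (the linear
group's only non-spectral information, since covariances of linear filter
outputs are otherwise determined by the power spectrum alone).

## Reduction and statistics-space geometry

Each group is z-scored across images (zero-variance columns dropped with a
warning), PCA-reduced to at most 8 components with the component sign fixed
by making the largest-magnitude loading positive, and the scores re-z-scored
so groups are commensurate. The marginal group (2 dimensions) bypasses PCA.
Groups retaining < 70% variance are flagged, not rejected: on the synthetic
families the spectral and energy groups retain 88–98% at the native 256-px
image size, while the linear group sits at the 70% boundary (0.65–0.77
across seeds) because procedural textures express family identity in only
its 96 phase-doubled-parent columns — a known gap relative to natural
textures. At the 64-px desk-scale used by most tests the linear group is
sampling-noise dominated and exercises the flag path.

Cluster geometry in a 2-D group subspace: radius r = (σₓ + σᵧ)/2, normalized
pair distance ‖µ₁ − µ₂‖ / ((r₁ + r₂)/2) (scale-invariant). Bootstrap CIs
resample within clusters; per-pair confidence levels are Šidák-corrected,
(1 − α)^(1/m) (99.15% for α = 0.05, m = 6). Because a distance statistic is
non-negative, "separation" is declared by comparing the bootstrap lower
bound against the same-level upper quantile of a label-permutation null, so
identical clusters are never flagged.

## Widefield pipeline

The printed trend model is fit per pixel as F(t) ≈ a·t + b and
ΔF/F = (F − (a·t + b))/b — the reading that both detrends and normalizes by
baseline; pixels with near-zero intercept are masked. Hemodynamic correction
low-passes the violet channel (Butterworth, order 6, 5 Hz cutoff, applied
forward–backward for zero phase), regresses it per pixel onto the blue
channel and subtracts c·violet_lp + d. Note that per-channel detrending
forces both channels to zero mean, so d is structurally ≈ 0 after the full
pipeline; the intercept is therefore validated on dF/F-stage synthetic pairs
(`synth.make_hemo_pair`), where both coefficients are recovered within 5%.

Trial tensors span [−500, +1000] ms around onset with frame 0 exactly at the
scheduled onset frame; truncated trials are dropped with a warning. The
pre-stimulus mean used for frame-zero correction excludes the onset frame.
Significance maps pair texture exemplars with a seeded random permutation of
scramble exemplars within family, average post ([200, 400] ms) and pre
([−350, −100] ms) windows, and apply a two-sided paired t-test per pixel
(identical pre/post values report p = 1). Type-I error on null movies
matches α within the binomial interval. Area d′ uses Eq.-style pooled
variance over per-exemplar responses (repeat-, ROI- and window-averaged);
the null band is the 5th–95th percentile of label-permuted pre-stimulus d′
values. Field gradients compare quadrant means with Welch t-tests.

## Two-photon pipeline and encoding model

Neuropil correction F_c = F_s − r·F_n with r = 0.7; baseline F_µ is the mean
of F_c over the first 5 s (cells with F_µ ≤ 0 are masked); F_c is linearly
detrended and ΔF/F = 100·F_d/F_µ. Responsiveness requires max per-exemplar
d′_stim = (µ_stim − µ_blank)/(σ_stim + σ_blank) ≥ 1 and max repeat-averaged
response ≥ 6% in the [250, 500] ms window.

The encoding model is closed-form ridge on column-centered data with an
intercept, fit per cell on the 8-column design (2 PCs per statistics group).
λ is selected per cell from a 13-point grid, 10⁻³…10³, by five-fold
cross-validated explained variance; folds are stratified over stimulus
categories and seeded. EV = 1 − SSE/SST on held-out data (SST about the
held-out mean), reported in percent, negative values kept. The permutation
threshold refits after re-assigning feature rows to random stimuli
(default 1000 shuffles, pooled across cells) and takes the 95th percentile;
the pipeline's inclusion threshold is the conservative max(threshold, 1%).
Weight analysis sums |w| per group; unique EV refits leave-one-group-out
models for cells with full EV ≥ 10% and reports 100·(EV_f − EV_i)/EV_f.
Against sessions with known weights, the median cosine between fitted and
true weight vectors exceeds 0.97 at the default noise level.

## Population geometry and decoding

Embeddings z-score each cell across stimuli (zero-variance cells dropped)
and apply PCA with the fixed sign convention. Binary texture-vs-scramble
decoders are L2 logistic classifiers with stratified, seeded five-fold CV;
the 4-way family decoder is multinomial logistic with an L1 penalty and the
regularization chosen by grid search on CV accuracy. The shared two-area
space concatenates both areas' z-scored cells; per-area projections zero the
other area's centered columns before applying the shared loadings, so the
two projections sum exactly to the full projection.

Cluster radii generalize the printed 2-D rule to the mean of per-component
standard deviations (reducing to (σₓ + σᵧ)/2 at k = 2). Mahalanobis
distances use the pooled within-pair covariance with Ledoit–Wolf shrinkage
by default (40 points in 16 dimensions is ill-conditioned); a fixed
shrinkage intensity may be supplied and the applied value is recorded.
Exact affine invariance holds at zero shrinkage.

## Behavior

d′ = Z(hit rate) − Z(false-alarm rate); rates of exactly 0 or 1 are moved
inward by 1/(2N) before the inverse-normal transform (logged). Aborted
trials are excluded from the denominators when the log flags them. Session
pooling is counts-then-transform by default. The training criterion is the
first run of 10 consecutive sessions with d′ > 1. The link table joins
per-family behavioral d′ (mean ± s.e. over sessions), decoder accuracy and
statistics distance, reporting Spearman rank correlations with bootstrap CIs
over sessions; constant inputs yield NaN correlations by design.

## Synthetic data: what it emulates and what it does not

Texture families are sparse-impulse ("texton") carriers filtered to a
log-Gaussian radial spectrum with optional orientation bias, multiplied by a
shared smooth envelope exp(κ·z): κ sets the strength of family-specific
energy cross-correlations (κ = 0 is exactly Gaussian, statistically
indistinguishable from its own scrambles), and carrier sparsity sets
cross-scale phase alignment. Default families: scales (κ = 0.85, sparsity
0.003, oriented 0°), honeycomb (0.70, 0.01, 60°), plants (0.55, 0.1, 120°),
rocks (0.10, dense, isotropic) — making rocks the family statistically
closest to its scrambles, with the four families' spectra overlapping in the
0.01–0.5 cpd band. Default image size is 256 × 256 px with 100° of visual
angle spanning the image; most tests run at 64 px / 8 exemplars for speed,
and the methods-level properties quoted above state which scale they were
measured at.

Widefield sessions (default 64 × 64 px at 20 Hz; tests use 32 × 32) place
two Gaussian-blob areas with linear retinotopic ramps, a 2:1 LM:V1
texture-gain ratio, an upper-field modulation gradient inside V1, a shared
hemodynamic artifact band-limited below 5 Hz (so the pipeline's low-pass
assumption holds by construction) with c = 0.8, multiplicative slow drift,
and white noise. Two-photon sessions drive per-cell trial amplitudes as
max(0, w·x + baseline) on the reduced statistics, scale a double-exponential
calcium kernel (50 ms rise, 500 ms decay — a generic indicator surrogate),
add shared neuropil with 0.7 mixing (so correction is exact when noiseless),
drift, and a configurable silent-cell fraction. `within_family_scale`
shrinks exemplar feature scatter toward family centroids and trial noise by
the same factor — the dial for programming a more compact ("LM"-like)
representation with unchanged cells and centroids. Behavioral observers are
equal-variance signal-detection agents with an unbiased criterion.

None of this emulates optics, eye movements, photobleaching, cell
segmentation, spike-to-fluorescence nonlinearity beyond rectification, or
natural-image phase structure richer than sparse impulses; passing tests
demonstrate that the analysis chain recovers what was programmed, not that
real recordings satisfy the generators' assumptions.

## Numerical conventions

Population (ddof = 0) moments everywhere; FFTs with origin-at-corner layout
and explicit shifts for radial coordinates; seeded `numpy.random.default_rng`
for every stochastic step; PCA signs fixed by the largest-loading rule;
logistic solvers at tol ≤ 1e-4 with capped iterations and seeded folds; ties
and degenerate inputs (constant images, zero-variance clusters or
denominators, empty ROIs, rank-deficient designs) raise or mask with
explicit diagnostics rather than propagating silently.
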