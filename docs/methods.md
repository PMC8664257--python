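# Methods

This note documents the models and numerical choices behind `spherotime`:
what each stage assumes, which parameters matter, what the synthetic data
do and do not emulate, and where the design was genuinely open.

## Oscillation quantification

**Model.** Osmotic water influx inflates the spheroid lumen at a rate that
falls linearly with medium osmolarity, reaching zero at the isotonic point
(70 mM sucrose equivalent).  When the normalized radius reaches a rupture
threshold the epithelium tears and the lumen collapses to a floor value;
the radius trace is a sawtooth.  Phase II repeats the pattern with both
amplitude and period shrunk by fixed factors.

**Rupture falls between frames.** At a 10-minute frame interval the exact
rupture peak is essentially never sampled: the camera sees a rising limb
and then, one frame later, the collapsed floor.  Both the trace generator
and the cycle detector adopt this convention consistently.  `detect_cycles`
therefore estimates each cycle's peak by extrapolating the least-squares
fit of the rising limb to the collapse time.  On noise-free sawtooths this
makes slope, amplitude *and* period simultaneously exact to machine
precision — which no convention based on the observed maximum can achieve
on a discrete grid.  `phase1_area` re-inserts the reconstructed peak as a
polyline vertex before integrating `max(radius − 1, 0)`, so a triangular
cycle integrates to its closed-form area exactly; negative excursions are
clipped by exact piecewise-linear integration, not by clipping samples.

**Rupture detection.** A rupture is a drop, within 3 frames of the running
cycle maximum, of at least `min_drop_fraction` (default 0.3) of the current
peak-to-trough span *and* at least `min_amplitude` (default 0.1 normalized
radius units).  The absolute floor is what separates ruptures from noise:
early in a cycle the running span is small and a purely fractional rule
would fire on ordinary fluctuations.  Cycles with amplitude below
`min_amplitude` are discarded.

**Phase I → II transition.** The criterion — amplitude down by at least
30% *and* frequency at least doubled — is applied automatically against
the *median* of all preceding cycles (robust to one noisy cycle).  Both
halves of the conjunction are required: amplitude decay alone never
triggers a transition.

**Image segmentation.** The chain is: coarse median filter (radius 60 px),
Phansalkar local threshold (window radius 50 px) with the r and k terms of
the full formula zeroed — leaving `t = m·(1 + 2·exp(−10·m))`, a threshold
sitting just above the local mean — another median filter (radius 20 px),
hole filling, and a 5000 µm² minimum object area (holes included).  The
radius assumes a spherical object, `r = √(area/π)`.

Median filtering erodes convex boundaries: on a binary disk the output
boundary is the locus where the filter window is half-covered, which for a
window of radius ρ on a disk of radius R sits inward by roughly ρ²/(3R)
(−30% radius at R = 50 px, −7% at R = 100 px for the 60 px window).  Since
the object is assumed spherical throughout, this response is invertible in
closed geometric form; `segment_spheroid_image` applies that inversion by
default (`curvature_correction=True`), bringing the radius error on
synthetic disks of 50–300 px below 0.6%.  Relative (normalized) radius
traces are insensitive to the correction for large objects; absolute areas
are not.

**Tissue thickness.** Whole-section and lumen areas are converted to
equivalent-disk radii and differenced.  A single global (Otsu) threshold
separates a fluorescent ring from a dark background; when the lumen is
brighter than the background (bright-field-like sections) the single
threshold merges lumen and ring, so the function falls back to a
three-class multi-Otsu split and takes the brightest class as tissue.

**Group tests.** Mood's median test dichotomizes at the grand median
(`≤ median` vs `> median`), with Yates continuity correction only in the
2×2 case.  The Wilcoxon rank-sum test uses midranks, the exact permutation
distribution for total n ≤ 20, and a tie-corrected normal approximation
with continuity correction otherwise; two-sided p-values are
`2·min(P≤, P≥)` capped at 1.  Both match brute-force enumeration oracles on
small inputs and hold their nominal α = 0.05 within binomial error over
1000 null replicates.

## GAM engine

Smooth fits `y ~ s(t, k)` use a cubic B-spline basis of dimension k with
knots at quantiles of t and an exact curvature penalty (the Gram matrix of
second derivatives, integrated by Gauss–Legendre, exact for cubics).  The
penalty weight is selected by generalized cross-validation,
`n·RSS/(n − γ·tr(A))²`, on a descending 50-point log grid; γ > 1 inflates
the complexity term and yields smoother fits.  The GCV score is floored at
a small multiple of the response scale so that responses fitted exactly at
every penalty (constants, straight lines) tie and resolve to the smoothest
fit, and the grid's upper end is kept moderate so the penalty null space
stays numerically exact.

**Smooth-term significance.** The p-value is the exact F test of the
*unpenalized* k-dimensional spline regression against the constant model.
An F test that plugs the GCV-selected effective degrees of freedom into the
reference distribution is strongly anti-conservative (measured 16%
rejection at α = 0.05 under the null — a selection effect: wiggly fits are
chosen precisely when noise looks wiggly), which would poison every FDR
threshold downstream.  The exact test is uniform under a Gaussian null by
construction (verified by KS); the penalized fit still provides fitted
values and edf for reporting.  Consequence: the test's resolution is fixed
at k − 1 numerator degrees of freedom rather than adapting to the fitted
complexity — an acceptable trade for honest calibration at the stringent
thresholds used here.

## Preprocessing

Samples under 5 million reads are dropped.  Size factors are sums over a
single global inclusion set — genes below the 95th percentile of mean
expression — scaled to mean 1; a handful of hugely expressed genes
therefore cannot distort the factors, and rescaling any excluded gene
leaves them unchanged.  Normalized values are put on a CPM-like scale
(mean sample total 1e6) and transformed as `log2(x + 8)`; the pseudocount 8
shrinks fold changes of lowly expressed genes.

**Size-factor identifiability.** When a large fraction of the transcriptome
genuinely changes over time, the included-gene total drifts with
composition and the estimated factors absorb that drift; recovered
expression then matches the truth up to one scale per sample (exactly one —
tested to 1e-9) rather than absolutely.  This is inherent to sum-based
normalization, not an implementation artifact.

**Batch correction.** The two collection sessions (hours 1–11 and 12–22)
introduce an additive log2 shift per gene.  Because spheroids develop
asynchronously, first-session samples collected at 10–11 h overlap
developmentally with second-session samples collected at 12–13 h.  All
cross-session pairs among these bridge samples are ranked by Spearman
correlation; pairs that are mutually within each other's top 3 are MNN
pairs, and the per-gene shift is the mean of their value differences,
subtracted from every second-session sample (one-sided, keeping session A
as the reference; a symmetric half-and-half split is available via
`symmetric=True`).  The estimator is exact when the shift is gene-wise
constant and the bridge samples are biologically identical; otherwise its
error floor is the sampling noise of ~30–40 shared-sample pair differences
— about 0.12 log2 units at a per-sample log2 noise of 0.45 (NB dispersion
0.1), irrespective of sequencing depth.

## Pseudotime ordering

The method assumes a single one-dimensional progression (no branching) and
that informative genes are smooth functionals of developmental time.

1. **Variable-gene filter**: quadratic trend of log-variance on log-mean
   across genes; top 50% by positive residual.
2. **Time-component denoising**: PCA of the filtered matrix; each of the
   first 50 component scores is GAM-fitted against collection time
   (k = 10, γ = 1.0); components with BH-adjusted smooth p < 0.05 are kept
   and the matrix is rebuilt from them.  Keeping α at 0.05 means ~5% of
   pure-noise runs still retain one borderline component — the error path
   ("no time-associated components") fires in the large majority, not all,
   of label-permutation runs.
3. **Windowed gene selection**: sixteen half-open 7-hour windows starting
   at hours 1..16.  Half-open intervals (`[s, s+7)`) are what give each
   sample between 1 and 7 covering windows on a 1-hour grid; closed
   intervals would give up to 8.  Within each window every gene is fitted
   with `s(t, k=4)`, γ = 1.25, and genes with BH-adjusted p < 0.05 are
   selected.  Windows with fewer than 8 samples, or fewer than 2 selected
   genes, are skipped with a warning.  Selection runs on the denoised
   matrix by default (`use_denoised_windows=False` reverts to the raw
   filtered one).
4. **Isomap ensemble**: per window, 100 one-dimensional isomap embeddings
   of the samples on random halves of the selected genes (gene profiles
   standardized first, making the stage equivariant to gene-wise affine
   transforms).  Each axis is oriented by non-negative Spearman correlation
   with collection time — the only available anchor — with ties inheriting
   the previous iteration's orientation, then min-max scaled to [0, 7
   hours].  The neighbour count defaults to `max(5, ⌈n/10⌉)` and is raised
   until the neighbourhood graph connects (logged in the diagnostics).
   The window coordinate is the per-sample mean over iterations.
5. **Consensus**: each window's weight is Σ over its selected genes of
   −log10(adjusted p), capped at 300 per gene — increasing in both the
   number and the significance of supporting genes (an
   `n × median(−log10 p)` variant is available).  A sample's consensus
   pseudotime is the weighted mean of `window_start + coordinate` over its
   covering windows.  Samples whose windows were all skipped fall back to
   their collection time with zero weight, with a warning; a fit with no
   usable window at all is an error.

Asynchrony is summarized as the per-collection-hour range of the central
50% of consensus pseudotimes (singleton hours excluded) and its median.

On the default synthetic conditions (150 samples, 400 genes, 60 dynamic,
asynchrony sd 1.5 h, NB dispersion 0.1) the consensus reaches Spearman
ρ ≈ 0.99 against the hidden latent time; the test suite asserts ρ ≥ 0.9
noisy and ≥ 0.99 in the count-noise-free limit.

## Positional-identity projection

PCA (mean-centred, unscaled) on segment transcriptome replicates — not
centroids, preserving the within-group variance the confidence ellipses
display — restricted to genes with a log2 range ≥ 1 (twofold) in both the
segment and the spheroid data, computed on raw (unsmoothed) series.
Pseudotime-ordered spheroid data are smoothed with a centred moving average
(window 16 samples ≈ 2 h of pseudotime; truncated windows at the ends — no
data are invented beyond the course) and projected as
`(x − center)·eigenvectors`; unordered data (regenerated animals) skip the
smoothing.  Two components are reported; the full score matrix is retained.
Eigenvector signs follow a fixed largest-loading-positive convention.
Confidence ellipses are `{x : (x−μ)ᵀΣ⁻¹(x−μ) ≤ χ²₂(level)}` at levels 0.70,
0.80, 0.90; collinear score sets are flagged degenerate.

## Differential dynamics

Both conditions are linearly interpolated to 150 points spanning the
*intersection* of their pseudotime ranges (no extrapolation).  Per gene,
the delta is standardized to unit variance and tested with `s(t, k=8)`,
γ = 1.0; p-values are BH-adjusted across genes.  The effect size is the
summed absolute difference of the two mean-centred signals over grid points
4..150 — mean-centring ("mean-normalized" read as subtraction, the natural
choice on a log scale; divide-by-mean available) makes it translation
invariant per condition, and dropping the first three points removes the
highly variable course start.  The smooth test sees shape, the effect size
sees scale; selection requires FDR < 1e-6 *and* effect > 40.  Among the
significant pool the top 10% by effect size are flagged, ties broken by
gene id for determinism.

**Interpolation-aware testing.** Linear interpolation correlates adjacent
grid points, and a naive F test on the 150-point delta is badly
anti-conservative (several of 500 null genes at adjusted p < 1e-6).  The
interpolation operators are known matrices, so under independent
homoskedastic sample noise the delta's covariance is
`σ²(L_A L_Aᵀ + L_B L_Bᵀ)` exactly; the test transforms into that matrix's
eigenspace (near-null directions dropped) and applies the exact F test
there.  Null calibration is restored (no adjusted p below 1e-4 in 10
replicates of 500 null genes) while a late 2-log2-unit divergence over the
last third of the course is detected with sensitivity ≈ 1.

Profiles of genes changing ≥ twofold along the reference course are
k-means clustered (k = 5, 25 k-means++ restarts, fixed seed; cluster ids
relabelled by size for stability).

**Intron/exon trajectories.** Both pseudotime-ordered series are smoothed
(window 36 points).  Each point is classified: *transcription* while the
intronic signal is above the midpoint of its dynamic range (10th–90th
percentile) or still rising; *degradation* when the intronic signal sits at
baseline while the exonic signal falls; *quiescent* otherwise.  The
transcription shutoff point is where the smoothed intronic signal crosses
that midpoint after its maximum — with a symmetric smoothing window this
recovers a step-like shutoff to within a few grid points.  The pointwise
classification is an extension beyond the smoothing itself, added to make
the transcription-versus-degradation reading testable.

**qPCR.** Fold changes are `2^−ΔΔCt` with `ΔCt = Ct(target) − Ct(reference)`
per sample and `ΔΔCt` taken against a calibrator sample (each condition's
initial time point in the intended use).

## Synthetic data: what it emulates, and what it does not

The expression generator reproduces the study design: samples spread evenly
over a 1..22 h collection grid; latent developmental time = collection time
plus Gaussian asynchrony (sd 1.5 h, clipped to the span) — so zero
asynchrony makes latent and collection time coincide exactly; smooth
per-gene log2 trajectories (logistic sigmoids and Gaussian bumps with
randomized midpoints and widths, amplitudes 1.5–3 log2 either sign);
condition-divergent genes with independent alternative trajectories;
expected CPM renormalized per sample (compositional, as real CPM is);
negative-binomial counts (`var = μ + φμ²`, φ = 0.1 default; φ = 0 means
deterministic expected counts, the noise-free limit used by exactness
tests); library sizes uniform on 6–25 million reads; sessions split at hour
11/12 with per-gene log2 shifts (sd 0.5) on 20% of genes.  Latent times are
drawn per sample around a uniform grid, making the marginal distribution
near-uniform over the span.

Not emulated: read-level artifacts (mapping, duplication, gene length),
gene–gene correlation beyond the shared trajectories, dropout, cell-type
composition shifts within a spheroid, and any real *Hydra* gene identity.
Passing recovery tests therefore demonstrates the algorithmic chain under
the stated noise model, not performance on a particular organism's data.

Oscillation traces are ideal sawtooths plus white Gaussian noise: no
drift, bleaching, or tracking loss.  Spheroid images are hard-edged
annuli with a dimmer lumen on a bright background plus white noise; real
bright-field texture, illumination gradients and neighbouring debris are
not modelled (the 5000 µm² filter and the median chain are exercised, but
their robustness margins on real images will differ).

## Determinism and problem sizes

Every stochastic component takes a seed; the pipeline derives per-stage
seeds deterministically from one global seed, and identical configuration
plus seed reproduces result tables byte-for-byte.  The benchmark drivers
use the study-scale configuration for pseudotime (150 samples × 400 genes),
20 replicates of 500 null genes for differential calibration, 50 seeded
traces for cycle-count recovery, 200 replicates for GAM null uniformity,
and 1000 replicates for the α calibration of the rank tests; these sizes
keep every driver's runtime in seconds-to-a-minute on one core while
leaving the binomial error bars far tighter than the asserted margins.

## Known limitations

- The MNN shift estimator cannot beat the sampling-noise floor of its
  bridge pairs (~0.12 log2 units under the default noise model); shifts
  smaller than that are effectively absorbed rather than estimated.
- The smooth-term test's fixed numerator df trades adaptive power for
  exact calibration (see above).
- The curvature-bias inversion in segmentation assumes one convex,
  approximately circular object; it is approximate for irregular shapes.
- Pseudotime assumes a single 1-D trajectory; branching dynamics would
  need a different embedding stage.
- `select_affected_genes` counts and flags are deterministic, but k-means
  cluster *identities* are arbitrary up to relabelling (stabilized here by
  ordering clusters by size).
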