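# spherotime

Quantitative analysis of regenerating *Hydra* tissue spheroids: osmotic
inflation/deflation oscillations, pseudotime ordering of asynchronous bulk
RNA-seq time courses, positional-identity projection, and differential
expression dynamics between mechanical-stimulation conditions.

## The problem

A small fragment of *Hydra* body column folds into a hollow bilayered
spheroid that re-patterns itself into a whole animal.  Osmotic water influx
inflates the lumen until the epithelium ruptures; the radius trace is a
sawtooth.  Early regeneration shows high-amplitude, low-frequency cycles
(phase I) that switch to low-amplitude, high-frequency cycles (phase II) at
symmetry breaking, and raising medium osmolarity with sucrose slows
inflation down to a standstill at the isotonic point (70 mM).  Spheroids
collected at the same clock hour sit at different points of the
developmental program, so bulk RNA-seq time courses must be reordered along
a latent *pseudotime* before their dynamics can be compared.

`spherotime` implements that full computational chain as a tested library
with a thin CLI, exercisable end-to-end on synthetic data with known ground
truth:

- **oscillation** — segmentation of bright-field images (median filter,
  Phansalkar local threshold with the r and k terms zeroed, median filter,
  hole filling, 5000 µm² size filter, with a curvature-bias inversion for
  spherical objects), cycle slope/amplitude/period extraction, the
  phase I→II criterion (≥30% amplitude decrease *and* frequency doubling),
  phase-I area under the curve, ectoderm thickness, Mood's median and
  Wilcoxon rank-sum tests.
- **preprocessing** — 5-million-read library filter, size factors excluding
  the top 5 percentiles of genes, CPM scaling, `log2(x + 8)`, and a mutual
  nearest-neighbour (top-3 Spearman) batch correction anchored on samples
  collected at 10–11 h vs 12–13 h of the two sessions.
- **pseudotime** — `PseudotimeModel(matrix).fit(seed)`: top-50% variable
  genes, reconstruction from GAM-significant principal components, sixteen
  overlapping 7-hour windows with per-window GAM gene selection
  (`s(t, k=4)`, GCV with γ=1.25), 100 one-dimensional isomap embeddings per
  window on random gene half-subsets, and a significance-weighted consensus.
- **projection** — PCA basis on body-segment transcriptomes (head, body1–4,
  budding zone, foot), restricted to genes changing ≥2-fold in both segment
  and spheroid data; pseudotime-ordered spheroid data are smoothed (window
  16) and projected onto that basis, with Gaussian confidence ellipses for
  the reference groups.
- **dynamics** — `DifferentialDynamics(...).fit(seed)`: interpolation of
  both conditions to 150 shared pseudotime points, a GAM smooth test on the
  standardized delta (`s(t, k=8)`), effect sizes (summed |difference| of the
  mean-centred signals, first three points excluded), FDR < 1e-6 and
  effect > 40 selection, top-10% ranking, k-means (k=5) profile clustering,
  intron/exon trajectory smoothing (window 36), and 2^−ΔΔCt qPCR
  quantification.
- **synthetic** — generators for all of the above with recorded ground
  truth: sawtooth traces whose inflation slope falls linearly to zero at
  70 mM, spheroid images, asynchronous two-condition/two-batch
  negative-binomial count time courses, and axial segment profiles.

The GAM engine (`spherotime.gam`) is a penalized cubic regression spline
with a curvature penalty, GCV smoothing selection with an inflatable
penalty (γ), and an exactly calibrated smooth-vs-constant F test.

## Worked example

```python
import warnings
from scipy import stats
from spherotime import (ExpressionSimConfig, generate_expression_timecourse,
                        preprocess, PseudotimeModel, DifferentialDynamics)

# a 22-hour two-condition time course: 150 spheroids per condition,
# 400 genes (60 dynamic, 20 condition-divergent), NB dispersion 0.1
counts, truth = generate_expression_timecourse(ExpressionSimConfig(seed=1))
log2, report = preprocess(counts)          # filter, CPM, log2, MNN correction

ctrl = log2.subset_samples(log2.sample_ids[log2.samples.condition == "control"])
result = PseudotimeModel(ctrl).fit(seed=1)
print(result.summary())
```

```
Consensus pseudotime
====================
samples:                 150
variable genes kept:     200
time components kept:    4
windows used:            16 / 16
windows per sample:      1-7
median spread per point: 0.63 h
```

Each spheroid gets between 1 and 7 window estimates; the consensus tracks
the hidden developmental clock closely
(`spearmanr(result.pseudotime, truth.latent_time)` → ρ = 0.996).  The
median pseudotime spread per collection point (0.63 h here) quantifies how
asynchronously the simulated spheroids develop.

Comparing the two media conditions along their pseudotimes:

```python
iso = log2.subset_samples(log2.sample_ids[log2.samples.condition == "isotonic"])
iso_result = PseudotimeModel(iso).fit(seed=1)
dd = DifferentialDynamics(ctrl.values, result.pseudotime.to_numpy(),
                          iso.values, iso_result.pseudotime.to_numpy()).fit(seed=1)
print(dd.summary())
```

```
Differential expression dynamics
================================
genes tested:             400
grid points:              150
FDR < 1e-06:              17
effect > 40:              400
significant & effect:     17
top 10% flagged:          2
genes clustered (>=2x):   400
```

The 17 genes passing both filters are all truly condition-divergent (17 of
the 20 planted divergent genes; none of the 380 others is flagged).  Note
that under counting noise the effect-size cut alone is permissive — the
stringent FDR cut carries the specificity, exactly the interplay the
selection rule is designed around.

The same stages are scriptable:

```bash
spherotime pipeline --seed 1 --out run1     # simulate → … → diffdyn
spherotime simulate traces --n 5 --out traces/
spherotime oscillation analyze traces/*.csv --min-drop 0.3
```

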