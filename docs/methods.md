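# Methods

This document records the statistical model, the phantom generator, the
default parameters and why they were chosen, and the numerical choices
made in the implementation.

## 1. Phantom model (`synthgen`)

### Geometry

A square pixel grid (default 60×60) contains a short-axis heart-section
analogue: an annulus of tissue between an outer radius (0.42 of the grid
diagonal scale) and an inner "ventricular cavity" radius (0.15). The
ischemic territory is an angular sector of the annulus (default −60° to
+60°), mimicking the perfusion bed of one coronary branch. Two analysis
regions are derived from the geometry: **ROI1** (the ischemic sector)
and **ROI2** (a remote septum-analogue sector on the opposite side),
used respectively for effect estimation and for negative-control
analyses.

### Feature panel and planted effects

`build_model` draws `n_features` (default 800) theoretical m/z values
uniformly over the acquisition range (100–2000), enforcing a minimum
spacing so consensus grouping is well-posed. A subset can be pinned to
exact metabolite masses (`metabolite_mz`) so annotation is exercised
end-to-end. Differential features (default 40 up + 40 down) get planted
log2 fold changes drawn from ±[1.0, 2.0]; at each nominal ischemia
duration the planted value is scaled by a severity multiplier
(15 min: 0.5, 30 min: 0.65, 1 h: 0.8, 2 h: 0.9, 4 h: 1.0), reflecting
progressive metabolic derangement. The effect is applied only inside the
ischemic sector of ischemic samples; control samples and remote tissue
are unaffected.

### Intensity model

Log-scale additive model per pixel and feature:

```
log Y = baseline(feature) + sample_effect + sector_effect + pixel_noise
```

- `baseline` ~ N(11.5, 1.0) per feature (log2-scale abundance, giving
  raw intensities spanning roughly 10³–10⁵ so the 20,000 abundance
  filter is meaningful), with a per-sample wobble of SD 0.2
  (`baseline_log_sd`).
- `sample_effect` ~ N(0, 0.2) per sample — biological replicate
  variation; this is the variance component that the moderated t on ROI
  means actually tests against.
- `pixel_noise` ~ N(0, 0.5) — independent shot/heterogeneity noise per
  pixel.
- A per-sample TIC drift (log-normal, SD 0.3) multiplies whole pixels,
  and a smooth spatial gain field simulates matrix-deposition
  inhomogeneity; both are what MSTUS normalization must remove.
- Dropout: each tissue intensity is zeroed with probability 0.05,
  modelling detection failure of weak ions.
- m/z jitter: observed centroids deviate from theoretical masses by a
  per-pixel Gaussian of 3 ppm, the scale of a calibrated TOF instrument;
  this is what the 0.001 Da consensus grouping and ±20 ppm merge/extract
  windows must absorb.

### Matrix background

Off-tissue pixels are not empty in real MALDI data: they carry **matrix
cluster ions** at a fixed set of m/z channels. The generator reserves a
random 10% of channels (`matrix_feature_frac`, disjoint from the
differential and pinned features) and gives every pixel — on and off
tissue — an exp(N(6, 0.5)) matrix contribution there; all other channels
are zero off tissue. This matches the physics (matrix chemical noise is
chemically specific, not uniform across the spectrum) and gives
segmentation a realistic background class: low-intensity, low-diversity
spectra clearly distinct from tissue.

## 2. Pipeline stages and numerical choices

### Peak picking (`peakflow.pick_peaks`)

Noise is estimated per spectrum as 1.4826 × median absolute deviation of
the intensities; peaks are local maxima above `snr_min` × noise.
`snr_min` defaults to 0 because the phantom (like exported processed
imzML) is already centroided — every stored point is a real peak — so
the SNR gate exists for profile-like data and is off by default.

### Consensus feature list

Peaks from **tissue pixels only** are grouped by single-linkage within
0.001 Da; a group is kept when it appears in at least `min_frequency`
(0.5) of the non-empty tissue peak lists, and its consensus m/z is the
intensity-weighted mean. Neighbouring consensus features within ±20 ppm
are then merged (split-peak repair); the merge is idempotent and the
resulting list has all pairwise gaps > 20 ppm. Intensities are
re-extracted per pixel as the nearest peak within ±20 ppm.

Using only tissue pixels for the consensus is deliberate: off-tissue
spectra contain only matrix ions, so including them would dilute the
frequency of genuine tissue features below the 50% threshold whenever
tissue covers less than half the scanned area.

### Feature filter

Three criteria, all required: detected in more than 10% of tissue
pixels; detected in at least 3 samples of at least one treatment group;
maximum raw abundance above 20,000 counts.

### Normalization

MSTUS: each tissue pixel is scaled so its total signal over the retained
features equals the median total across tissue pixels; then
log2(x + 1). For the **clustering** input only, zeros are first imputed
to one fifth of the per-feature minimum positive value over tissue
pixels (`impute_zeros`, the convention used by MetaboAnalyst): a dropout
zero is a censored low value, and leaving it at 0 puts a ~10–15 log2
unit outlier in the pixel vector that k-means would chase. The
differential-expression chain does not impute — ROI means over dozens of
pixels are insensitive to sporadic zeros, and imputation would bias low
abundances.

### Moderated differential expression

For each timepoint, per-sample ROI1 means are compared between ischemic
and control with a limma-style moderated t: the prior (d0, s0²) is
estimated by moment matching of log sample variances (closed-form
digamma/trigamma relations with Newton refinement; trigamma inversion by
the standard asymptotic-start Newton scheme), the posterior variance is
`(d0·s0² + df·s²)/(d0 + df)`, and t is referred to d0 + df degrees of
freedom. d0 is capped at 1e6 to keep the arithmetic finite when the
variances are essentially homogeneous. The implementation is verified in
the test suite against the reference R implementation (limma 3.58) to
4 significant digits. Benjamini–Hochberg adjustment is the exact
step-up procedure (cumulative minimum from the largest p-value down).
Volcano classification uses q < 0.05 and |fold change| > 1.5.

### Spatially-aware segmentation

Before k-means, every feature image is smoothed over a Chebyshev
neighbourhood of radius r (default 1) with Gaussian weights
exp(−d²/2σ²), σ = max(r, 1)/2, renormalized per pixel over the valid
neighbours. Smoothing is **class-preserving**: tissue pixels only
average over tissue neighbours and background over background, so the
tissue boundary is never blurred. k-means uses k-means++ initialization,
Lloyd iterations, and 20 restarts; labels are reported 1-based. With
r = 0 the path is bitwise identical to scikit-learn's `KMeans` on the
raw matrix, which the tests check exactly. Segmentation quality against
the planted mask is the best single-cluster Jaccard index (and adjusted
Rand over tissue pixels).

### Annotation and enrichment

Monoisotopic masses are summed from a frozen table (C 12 exact,
H 1.00782503, N 14.00307401, O 15.99491462, P 30.97376200,
S 31.97207117); the [M−H]⁻ ion mass subtracts one proton
(1.00727646 Da). Features annotate to database entries within ±10 ppm;
equal-formula isobars are flagged ambiguous. Pathway
over-representation is the one-sided Fisher exact test (hypergeometric
upper tail, `P(X ≥ k)`), pathways with fewer than 2 differential hits
excluded **before** testing, and BH applied across the tested pathways.

## 3. Default parameters

| Parameter | Default | Rationale |
|---|---|---|
| `consensus_tolerance_da` | 0.001 | grouping width for centroid jitter |
| `min_frequency` | 0.5 | consensus support across tissue pixel lists |
| `merge_ppm`, `extract_ppm` | 20 | split-peak repair / extraction window |
| `pixel_frac_min` | 0.10 | filter: present in >10% of pixels |
| `min_samples_per_group` | 3 | filter: group support |
| `min_abundance` | 20000 | filter: intensity floor |
| `de_fdr` | 0.05 | BH significance threshold |
| `volcano_fc` | 1.5 | fold-change cut for volcano status |
| `annotate_ppm` | 10 | metabolite identification window |
| `k`, `r` | 6, 1 | clusters / smoothing radius for segmentation |
| `enrich_min_hits`, `enrich_q` | 2, 0.05 | pathway testing conventions |

## 4. Realism and limitations of the generator

- **No isotope envelopes or adduct series.** Each metabolite is one
  channel; deisotoping and adduct resolution are out of scope.
- **MSTUS compositional bias.** MSTUS assumes most of the signal is
  unchanged. When many high-abundance features change in one direction
  (strong effects at 4 h), normalization transfers a small opposite
  shift to null features, which can produce a handful of false
  discoveries in the effect-bearing ROI. This is a property of the
  normalization itself, shared with real studies; the null-cohort FDR
  and the remote-ROI analyses are unaffected and are the calibrated
  guarantees.
- **Fixed-width consensus grouping.** The 0.001 Da tolerance is narrower
  than 3 ppm jitter above ≈ 330 m/z, so sparse high-mass groups can
  fragment into multiple consensus features; the ±20 ppm merge repairs
  most but not all of this. Consensus accuracy is therefore stated as
  all features within 5 ppm (90% within 1 ppm) of a planted mass rather
  than an exact count.
- **Independent pixel noise.** Apart from the smooth gain field, pixel
  noise is spatially white; real data show correlated texture. The
  smoothing radius r = 1 is therefore, if anything, conservative.
- **Single-section samples.** Each simulated sample is one section; no
  serial-section or inter-animal spatial registration is modelled.
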