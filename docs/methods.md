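# Methods

`strokewmh` implements and evaluates automated segmentation of white-matter
hyperintensities (WMH) in brains that also contain a stroke lesion. This
note records the models, the synthetic data they are exercised on, the
numerical choices, and what the tests do and do not demonstrate.

## The segmentation problem

WMHs are FLAIR-hyperintense lesions of presumed vascular origin. In stroke
cohorts two complications arise: (1) the infarct itself can share the WMH
intensity profile, so a supervised classifier can be poisoned by stroke
voxels labelled "non-WMH" in its training set; and (2) multi-site studies
mix scanners and sequences, shifting intensity distributions between the
training and test data of any supervised method.

## Supervised k-NN voxel classification

Each voxel inside the effective brain mask becomes a feature vector:

- **Intensities** per modality (FLAIR required; T1, T2 optional),
  normalized within the brain mask. Default: clip to the within-brain
  [q1, q99] percentile range and map to [0, 1]. Z-scoring and "none"
  are available; note that both percentile and z-score normalization are
  invariant to affine intensity shifts, which matters for the cross-site
  experiment below.
- **Patch means**: the mean intensity over a cubic p-voxel neighbourhood
  intersected with the effective brain, p in {0, 3, 6, 9}. Buffers the
  classifier against misregistration. For even p the window is shifted
  one voxel toward the origin side (the convention of
  `scipy.ndimage.uniform_filter`).
- **Spatially weighted coordinates**: world mm coordinates divided by
  100 mm, multiplied by the spatial weighting sw in {0, 1, 5, 10}. The
  100 mm scale makes sw a graded location prior against unit-normalized
  intensities: at sw = 1 a 10 mm displacement costs as much as a 0.1
  intensity difference; at sw = 10 location dominates. Raw mm coordinates
  would dwarf the intensity columns at any sw > 0 and collapse the sw
  grid to a single regime.

Training points are sampled per subject: lesion points uniformly without
replacement from the gold mask ("all" = every voxel), non-lesion points
from a pool controlled by the location policy (anywhere outside the gold
mask; excluding its 1-voxel 26-neighbourhood border; or only that
border). The per-subject sampling seed is the configured seed plus the
subject's position, so cohorts are reproducible.

A query voxel's WMH probability is the fraction of its k nearest training
vectors (Euclidean distance; default k = 40, not part of the optimization
grid) labelled WMH — always an exact multiple of 1/k. Neighbour search
uses scikit-learn's kd-tree; equal-distance ties at the k boundary are
re-resolved by a stable (distance, training-index) sort so results are
platform- and permutation-independent. A fixed threshold tau (comparison
is >=; default 0.85) binarizes the map.

**Stroke handling.** `mask_input` removes the stroke from the brain mask
before feature extraction and sampling: infarct voxels can neither enter
the non-WMH training class nor be segmented. `mask_output` classifies the
full brain, then deletes the (optionally mm-dilated) stroke mask from the
output. Both modes guarantee a stroke-free final mask; they differ in
training contamination, which is exactly what the stroke-masking
experiment measures.

## Distance-band adaptive thresholding

A deliberately simple surrogate for locally adaptive threshold
estimation: the brain is split into bands by Euclidean distance from the
ventricle mask (default two bands at 10 mm, the usual periventricular /
deep cutoff) and a per-band threshold is grid-searched to maximize mean
within-band Dice on training subjects (ties take the larger, more
conservative threshold). With one band this is exactly a global
fixed-threshold search. It is *not* a reimplementation of any published
locally-adaptive tool; it reduces that idea to its distance-band core so
fixed-vs-adaptive comparisons can be run on phantoms.

## Unsupervised Gaussian-mixture baseline

A per-subject K-component Gaussian mixture (default K = 4) over
within-brain intensity vectors, fitted by EM: seeded k-means
initialization, diagonal covariances, variances floored at 1e-6 of the
per-feature data variance (flagged, never fatal), convergence when the
mean log-likelihood changes by less than 1e-6 (relative) or after 200
iterations. The lesion class is the component with the highest FLAIR
mean — transparent and inspectable. Its responsibility map is
thresholded (grid {0.1, 0.3, 0.5, 0.7, 0.9}; 0.1 default) and the stroke
mask is removed from the output only, since an unsupervised method has no
training input to protect. Because the mixture refits each subject's own
intensities, the method is inherently robust to between-site gain/offset
changes. EM is implemented in the package (the per-iteration
log-likelihood trace is part of the tested contract); an independent
scikit-learn mixture fit cross-checks the estimates in the tests. This
is a plain mixture baseline: no atlas deformation, no shape priors, and
no claim of numerical correspondence with any whole-brain segmenter.

## Scoring

With gold mask G and automated mask A: SI = 2|G∩A|/(|G|+|A|),
FDR = |A\G|/|A|, FNR = |G\A|/|G|; at cluster level (26-connected
components, overlap = at least one shared voxel) FDRc and FNRc are the
fractions of unmatched A- and G-clusters, and with MTA = (|G|+|A|)/2,
DER sums the voxels of all unmatched clusters over MTA while OER sums
matched-cluster voxels outside the intersection over MTA. Volumetric
agreement is ICC(A,1) — two-way random effects, absolute agreement,
single measure — over per-subject volume pairs (via `pingouin`; a
hand-coded ANOVA decomposition serves as the test oracle). Undefined
metrics (empty G or A) are NaN-flagged and excluded from cohort means
with counts reported; scoring them as zero would bias means. Whether a
cohort cell should be the mean of per-subject metrics or a pooled-voxel
metric is a genuine convention choice; per-subject means are used here.

## Optimization and validation experiments

`loo_score` evaluates one configuration by leave-one-out cross-validation
(fit on n−1, segment the held-out subject), reporting mean SI, FNRc and
the ICC over the LOO volume pairs. `select_best` applies the 2-of-3 rule
on (SI up, ICC up, FNRc down): a configuration wins if, against every
rival, it takes at least two strict wins or one strict win plus two ties.
Dominance cycles are possible; the fallback is highest SI, flagged in the
phase log. `phased_optimize` varies one settings dimension at a time
around the incumbent (modalities, spatial weighting, patch, point
location, point counts, threshold), adopting per-dimension winners until
a full phase changes nothing. LOO results are cached by settings
fingerprint; features are cached per subject and feature configuration.

`cross_site_experiment` scores, with identical settings: same-site arms
(80/20 split within each site), the cross-site arm (site-A model applied
to site-B's test set), a mixed arm (equal halves of both training sets),
and the unsupervised GMM arm on both test sets.

## The phantom generator

Real multi-site stroke MRI cannot ship with a toolkit, so every
experiment runs on generated phantoms: a 64³ grid at 1 mm isotropic
(world origin at the volume centre), an ellipsoidal brain (semi-axes
26×30×22 mm), two ellipsoidal lateral ventricles, spherical WMH blobs
(default 12±4 clusters, radii 2–4.5 mm) seeded periventricular (within
10 mm of the ventricles) with probability 0.7, a spherical stroke lesion
(9 mm) whose intensity defaults to the WMH profile on *every* modality —
maximal confusability, so stroke-masking experiments have signal — and
optional deep "mimic" blobs (default 0): WMH-intensity tissue far from
the ventricles, standing in for the bright non-lesion structures (e.g.
midline white matter) that attract false positives in real pipelines and
making lesion *location* genuinely informative where a test plants it.

Default tissue means (arbitrary units, FLAIR/T1/T2): parenchyma
120/120/110, CSF 60/50/200, WMH 170/100/160, noise sd 8 per modality.
Per-site acquisition differences are an affine intensity map plus noise
rescaling: value = gain·mean + offset + N(0, noise_scale·sd), optionally
after Gaussian smoothing of the class-mean image. One subject is fully
determined by one integer seed; cohorts fan a base seed out by addition.

What the phantoms deliberately omit: gyral anatomy, partial-volume
mixing, bias fields beyond the linear site map, irregular lesion shapes,
and non-affine site effects. Consequently, passing experiments show that
the *mechanisms* behave as designed (training contamination hurts,
affine domain shift breaks a supervised model, a per-subject unsupervised
fit does not, location priors help when location is informative) — they
do not certify accuracy levels on clinical MRI.

## The cross-site experiment and intensity normalization

The percentile and z-score normalizations are exactly invariant to an
affine intensity map, so under the phantom's site model they would undo
the site effect and no supervised cross-site degradation could occur.
In real multi-site studies the sites' scans are *not* jointly
harmonized — each dataset arrives through its own preprocessing — so the
canonical cross-site experiment here runs with
`intensity_normalization="none"`, letting the raw site shift reach the
classifier. Within-site optimization keeps the percentile default.

## Experiment scales

Unit tests run on 32³ phantoms. The experiment-scale suite uses the 64³
default geometry: 20 subjects for the stroke-masking contrast, 20+20 for
the cross-site experiment (site B: gain 1.4, offset +20, noise ×1.5),
and a 6-subject LOO cohort for the optimizer with a reduced grid
(sw {0,1,5,10}, patch {0,3}, tau {0.8,0.85,0.9}, other dimensions fixed)
on the planted-structure phantom. `scripts/acceptance.py` re-runs the
three experiments at 12, 12+12 and 5 subjects respectively and writes
the summary numbers as JSON.

## Known limitations

- The k-NN feature scaling (intensity normalization, 100 mm coordinate
  scale) is this package's own; outputs are method-faithful to k-NN WMH
  classification, not numerically identical to any external tool.
- The adaptive-threshold module is a distance-band reduction, not a
  learned local-threshold regression.
- Cluster connectivity (26), the 1-voxel border width for the sampling
  policies, and the >= threshold convention are documented choices where
  the method description leaves them open; all are configurable.
- Registration is application-only: given affines are applied; estimation
  is out of scope.
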