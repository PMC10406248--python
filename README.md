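# strokewmh

Stroke-aware segmentation of white-matter hyperintensities (WMH):
a supervised k-nearest-neighbour voxel classifier with explicit
stroke-lesion handling, an unsupervised Gaussian-mixture baseline, a
complete lesion-overlap scoring suite, and the optimization and
multi-site validation experiments that compare them — all runnable on
generated synthetic brain phantoms.

## Who this is for

WMHs are FLAIR-bright lesions of presumed vascular origin, common in
aging and a risk factor for stroke. Stroke researchers segmenting WMHs
face two specific problems this package addresses head-on:

1. **The infarct mimics the lesion.** A chronic stroke lesion can share
   the WMH intensity profile. If stroke voxels enter a supervised
   classifier's training set labelled "non-WMH", they poison the model.
   The segmenter therefore supports masking the stroke on *input*
   (removed from the brain mask before feature extraction and training)
   or on *output* (classified, then deleted — optionally after
   millimetre dilation), and the experiments quantify the difference.
2. **Multi-site data breaks supervised models.** A k-NN model trained on
   one scanner's intensity distribution can fail completely on another's.
   The cross-site experiment measures same-site, cross-site and
   mixed-sample training, alongside an unsupervised per-subject
   mixture-model baseline that has no training set to mismatch.

## The methods in brief

**Supervised:** each brain voxel becomes a feature vector — normalized
modality intensities (FLAIR; optionally T1, T2), optional cubic patch
means, optional spatially weighted template coordinates. The WMH
probability of a query voxel is the fraction of its k nearest labelled
training vectors (Euclidean; k = 40) carrying the WMH label:

    p(voxel) = #{WMH among k nearest training points} / k

A fixed threshold tau (default 0.85, comparison >=) yields the mask;
a distance-band adaptive alternative fits per-band thresholds by
ventricle distance. Scoring: Dice SI, FDR, FNR; cluster-level FDRc,
FNRc; detection/outline error rates DER and OER; ICC(A,1) over lesion
volumes. A phased one-factor-at-a-time grid search with leave-one-out
cross-validation and a 2-of-3 metric rule (SI, ICC, FNRc) selects the
settings.

**Unsupervised:** a per-subject K-class Gaussian mixture over intensity
vectors (EM, diagonal covariances); the class with the highest FLAIR
mean is the lesion class, its posterior is thresholded (default 0.1) and
the stroke mask is removed from the output.

Because real multi-site stroke MRI cannot ship with a toolkit, a phantom
module generates multi-modal subjects with ground-truth WMH, stroke,
brain and ventricle masks, periventricular lesion clustering, a
WMH-mimicking stroke, and per-site intensity gain/offset/noise effects.
See `docs/methods.md` for the full model description.

## Worked example

```python
import strokewmh as sw
from strokewmh import knn_segmenter as knn

# two cohorts from different "scanners"
site_b = sw.SiteEffect(gain=1.4, offset=20.0, noise_scale=1.5, site_id="site-B")
cohort_a = sw.generate_cohort(10, base_seed=100)
cohort_b = sw.generate_cohort(10, site=site_b, base_seed=200)

settings = sw.SegmentationSettings(
    feature_config=sw.FeatureConfig(("FLAIR", "T1"), spatial_weighting=0.0,
                                    intensity_normalization="none"),
    sampling_config=sw.SamplingConfig("any", "all", "equal"),
    tau=0.85, stroke_mode="mask_input",
)
res = sw.cross_site_experiment(cohort_a, cohort_b, settings, seed=7)
print({k: round(v, 3) for k, v in res["mean_si"].items()})
```

prints

```
{'same_site_A': 0.996, 'same_site_B': 0.988, 'cross_site_A_to_B': 0.065,
 'mixed': 0.992, 'gmm_A': 0.993, 'gmm_B': 0.98}
```

Reading: trained and tested within one site the k-NN segmenter is nearly
perfect on these phantoms (mean Dice 0.99+); applied across the site
shift it collapses to 0.065 because site B's parenchyma lands exactly on
site A's WMH intensity range; training on a mixed sample restores
performance; and the unsupervised mixture baseline, refitted to each
subject, is indifferent to the site shift.

The same workflow is available from the shell:

```bash
strokewmh make-phantoms --n 10 --seed 1 --out cohort/
strokewmh train --manifest cohort/manifest.csv --out model.bin --n-lesion all
strokewmh segment --model model.bin --manifest cohort/manifest.csv \
    --out-dir seg/ --n-lesion all
strokewmh score --manifest cohort/manifest.csv --auto-dir seg/ --out report.csv
```

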