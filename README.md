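# eegfusion

Multi-brain-region multispectral EEG imaging, weighted image fusion,
population-graph construction, and cross-validated classification.

## The problem

Resting EEG differs between patients with neurodegenerative and retinal
degenerative disease (e.g. age-related macular degeneration, Alzheimer's
disease) and healthy controls, and the differences are band- and
region-specific: elevated frontal theta power, altered parietal alpha/beta.
`eegfusion` implements a feature-extraction and evaluation pipeline that
turns a multichannel recording into a single color image summarizing the
spatial distribution of band power across five scalp regions — frontal,
parietal, left temporal, right temporal, occipital — so that an image
classifier can exploit those regional differences, and so that subjects can
be related in a population similarity graph.

## The method

For each subject and each region *i*:

1. **Band power.** Each electrode's signal is Fourier transformed and
   reduced to three features — the sum of squared one-sided DFT magnitudes
   over theta [4, 8), alpha [8, 13) and beta [13, 30) Hz.
2. **Projection.** Electrode positions on the unit sphere are mapped to the
   plane by the azimuthal equidistant projection: an electrode at polar
   angle φ from the vertex and azimuth ψ goes to (φ cos ψ, φ sin ψ).
3. **Imaging.** Per band, features are min–max normalized over the region's
   electrodes and interpolated with the piecewise-cubic Clough–Tocher
   scheme onto a shared 40×40 grid; the three band maps are stacked as the
   R (theta), G (alpha), B (beta) channels of a multispectral image *D_i*.
4. **Fusion.** The five regional images are combined pixelwise as
   *D* = Σᵢ Aᵢ·Dᵢ with non-negative weights summing to 1 (uniform by
   default).

On a cohort, fused images feed two products:

- a **population graph** with edge weights
  `W(v,w) = exp(−ρ²/2σ²) · Σ_h γ(M_h(v), M_h(w))`, where ρ is the
  correlation distance between the subjects' fused images and γ scores
  phenotype agreement (Kronecker delta for gender; |Δage| < θ for age);
- a **classification protocol**: a compact softmax head (flatten →
  dense(64, ReLU) → dropout 0.1 → dense(e) → softmax) trained with
  cross-entropy and RMSprop (lr 10⁻⁴) under stratified 5-fold
  cross-validation, reporting accuracy, recall, F1 and AUC.

A seeded synthetic-cohort generator produces two-class cohorts whose
classes differ in regional band power, so the whole pipeline is testable
without clinical recordings.

## Worked example

```python
import numpy as np
from eegfusion import (ClassifierConfig, CohortSpec, PipelineConfig,
                       default_montage, generate_cohort, kfold_evaluate,
                       subject_images)

recordings, phenotypes, labels = generate_cohort(CohortSpec(n_per_class=15, seed=2))
montage = default_montage()
X = np.stack([subject_images(r, montage, PipelineConfig())[1].pixels
              for r in recordings])
report = kfold_evaluate(X, labels, ClassifierConfig(seed=2))
print(report.mean_accuracy, report.mean_auc)
```

Run as `python examples/06_crossvalidated_classification.py`, this prints

```
per-fold accuracy: [1.0, 1.0, 1.0, 1.0, 1.0]
mean accuracy 1.000  recall 1.000  F1 1.000  AUC 1.000
mean validation loss 0.131
validation accuracy epoch 10: 0.867 -> epoch 400: 1.000
```

The cohort's patient class carries a focal frontal-theta power elevation
(3×) and a milder parietal-alpha one (1.5×); perfect separation of this
small 30-subject cohort means the fused images preserved those
class-specific spatial patterns through projection, interpolation,
normalization and fusion. The other scripts under `examples/` walk through
each stage — simulation, band features, topographic imaging, fusion, and
the population graph — each printing the quantities it computes.

There is also a CLI mirroring the pipeline stages:

```bash
eegfusion simulate --n-per-class 10 --seed 1 --out cohort/
eegfusion image cohort/sub-000.csv --out images/
eegfusion evaluate images/ cohort/labels.csv --out results
eegfusion run-all --seed 1 --out run/
```

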