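# Methods

This note documents the models, numerical choices and known limitations of
`eegfusion`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Electrode geometry and projection

The packaged default montage is an idealized 36-channel extended 10-20
layout on the unit sphere (head-centered: x toward the right ear, y toward
the nasion, z toward the vertex). Ring electrodes follow the standard
fractional-arc construction (the 10% ring at polar angle 72°, the 20% ring
at 36°, the low-temporal FT9/FT10/TP9/TP10 row on the equator); remaining
intermediate electrodes are spherical midpoints of their 10-20 neighbors.
The low-temporal row matters: without it each temporal region has only
three nearly co-circular electrodes whose convex hull is a sliver
containing no pixel of a 40×40 grid, leaving temporal images blank and
reducing five-region fusion to three informative regions in practice.

Electrodes map to regions by prefix, longest match first: Fp/AF/F/FC →
frontal, C/CP/P → parietal, O/PO → occipital, and T/FT/TP split by the
odd/even (left/right) numbering convention; midline "z" electrodes follow
their prefix. An explicit label→region table overrides the rule per
electrode. Every one of the five regions must keep at least three
electrodes, the minimum for triangulated interpolation.

The azimuthal equidistant projection is centered on the vertex (0, 0, 1):
(u, v) = (φ cos ψ, φ sin ψ) with φ the polar angle and ψ = atan2(y, x).
Azimuths are preserved exactly and the planar radius is the great-circle
distance from the vertex, so the projection is injective on any hemisphere
montage and radially monotone. An electrode antipodal to the vertex has no
defined azimuth and is rejected.

## Band-power features

Per channel, the feature for band *b* = [low, high) is the sum of squared
one-sided DFT magnitudes over bins k·fs/n ∈ [low, high). Band edges
default to theta [4, 8), alpha [8, 13), beta [13, 30) Hz; edges are
configurable but must be non-overlapping, increasing, and below Nyquist. A
band that contains no DFT bin at the given fs and n is a configuration
error, reported with both values. Half-open binning prevents double
counting at shared edges. No window, detrending or epoching is applied by
default — the transform is taken over the whole recording — but mean
removal and fixed-length epoch averaging are available as options. Units
are squared spectral magnitude; downstream min–max normalization makes the
pipeline insensitive to the overall scale.

## Multispectral imaging

Per region and band, features are min–max normalized to [0, 1] **within
the region's electrodes** and interpolated with the Clough–Tocher
piecewise-cubic scheme (`scipy.interpolate.CloughTocher2DInterpolator`)
onto a regular 40×40 grid. Channels stack as R = theta, G = alpha,
B = beta. Numerical conventions:

- **Shared window.** All regions use one grid window — the bounding square
  of the full-montage projection padded by 5% — so regional images are
  spatially commensurable before fusion.
- **Outside the hull.** Triangulated interpolation cannot extrapolate;
  pixels outside the electrodes' convex hull are set to 0.
- **Degenerate band.** If a band is constant across the region
  (max = min), the channel renders as 0.5 inside the hull, keeping the
  image a valid color map.
- **Overshoot.** Cubic interpolation can overshoot the data range by a few
  ulps to a few percent between sites; pixels are clipped to [0, 1].
- **Orientation.** Row 0 is maximal v (nose up), column 0 minimal u (left
  ear left). Exact float pixels are archived as `.npy` with a JSON sidecar
  (region, bounds, conventions); PNGs are 8-bit quantizations for
  inspection only.

Min–max normalization deliberately removes per-region, per-band scale:
images encode the *spatial pattern* of band power, not its absolute level.
The interpolant reproduces electrode values exactly (≤ 1e-9) at
grid-coincident sites, and the image is invariant to positive affine
rescaling of a band's feature vector.

## Fusion

The fused image is the pixelwise, channelwise convex combination
Y = Σₙ Aₙ Xₙ with Aₙ ≥ 0, Σ Aₙ = 1 (validated to 1e-9 at the boundary).
Because weights are constant across pixels, pixel-level and image-level
weighted averaging coincide; the operation is implemented once. Default
weights are uniform (1/5 per region). Fusion is linear, permutation
consistent, and bounded by the per-pixel envelope of its inputs.

## Population graph

Edge weights combine imaging similarity and phenotype agreement:
W(v, w) = exp(−ρ²/2σ²) · Σ_h γ_h, with the diagonal zeroed. The feature
distance ρ is the correlation distance 1 − Pearson r between flattened
fused images, clipped to [0, 1]; identical images give ρ = 0 and kernel
value 1, and a zero-variance image (undefined correlation) is treated as
maximally dissimilar (ρ = 1) and logged. This choice keeps ρ in the (0, 1)
range the kernel expects while giving the kernel its usual semantics —
similar subjects get weights near 1. Phenotype terms are binary: gender
agreement is a Kronecker delta; ages agree when |Δ| < θ. Defaults σ = 1,
θ = 2 years. Edge weights therefore lie in [0, H] for H phenotypes, and a
pair disagreeing on every phenotype has weight 0 regardless of imaging
similarity.

## Classifier and evaluation protocol

The classification head is deliberately compact — flatten 40×40×3 →
dense(64, ReLU) → dropout(0.1) → dense(e) → softmax — small enough to
train on a CPU in seconds while exercising the full protocol: softmax
probabilities, cross-entropy loss (binary form for two classes,
categorical beyond), and RMSprop updates
(s ← γs + (1−γ)g², θ ← θ − lr·g/√(s+ε), γ = 0.9, ε = 1e-8, lr = 10⁻⁴).
Inputs are centered on the training-set per-feature mean before the first
layer (mean-intensity subtraction): raw pixels are all-positive, which
confines first-layer gradient directions to one orthant and slows
optimization. Softmax is computed with max subtraction; probabilities are
clamped at 1e-12 in the loss. Training is deterministic for a fixed seed —
initialization, shuffling and dropout masks all derive from one seeded
generator.

The epoch budget defaults to 400. The governing criterion is that
validation accuracy/loss curves must have stabilized; with 64 training
subjects there is exactly one 64-sample batch per epoch, and on default
synthetic cohorts the 5-fold validation curves plateau around epochs
350–500. The budget is configurable, and per-epoch validation curves are
part of every report so stabilization can be checked rather than assumed.

Evaluation uses stratified 5-fold cross-validation (every subject in
exactly one validation fold, both classes in every fold), reporting
per-fold and mean accuracy, recall, F1 and AUC (macro one-vs-rest beyond
two classes), mean validation loss, fold assignments and the validation
curves. Folds and metrics come from scikit-learn; the AUC implementation
is cross-checked in the tests against brute-force Wilcoxon pair counting.

## Synthetic cohorts

The generator emulates the study premise — two classes whose EEG differs
in regional band power — under a simple, analytically checkable model.
Each channel is a sum of one sinusoid per band (center frequency uniform
within the band, phase uniform) plus white Gaussian noise, 4 s at 128 Hz.
Amplitudes have three factors:

- a **baseline topography** per band (Gaussian bumps of width 0.8 rad):
  theta dominant at the frontal midline, alpha at the occipital pole, beta
  at the vertex — the canonical resting-EEG pattern, scaling base
  amplitudes (theta 10, alpha 10, beta 5 µV) by 1 to 1.5;
- **subject jitter**: per-subject, per-electrode lognormal variation
  (sd 0.15), so individual topographies vary around the group pattern;
- **class effects**: a (region, band, class, multiplier) effect applies
  gain 1 + (m−1)·exp(−d²/2w²), w = 0.6 rad, with d measured from the
  region's most lateral-left electrode. Defaults: frontal theta ×3 and
  parietal alpha ×1.5 in the patient class.

The effect is focal and lateralized by design. Because images are min–max
normalized per region and band, a *uniform* regional amplitude change is
invisible in the image (only raw features retain it); and a focal change
concentric with the band's baseline peak largely rescales the existing
pattern, which normalization also removes. A laterally displaced focus
changes the shape of the normalized topography — the quantity the imaging
method actually encodes. Phenotypes are drawn independently of the EEG:
gender Bernoulli(1/2); age normal with sd 5, mean 70 (control) vs 75
(patient), the shift giving the population graph phenotypic signal.
Noise sd defaults to 5 µV, a signal-to-noise ratio at which per-band
features are signal-dominated but single-subject topographies remain
visibly noisy.

What the generator does **not** emulate: 1/f background spectra, artifacts
(blinks, muscle), volume conduction and inter-channel correlation,
non-stationarity, and realistic inter-subject anatomical variability.
Passing tests therefore show that the pipeline recovers class-dependent
spatial band-power structure under this generative model — not that it
attains any particular performance on clinical EEG.

## Pipeline scale and determinism

Default experiment size: 40 subjects per class, 36 channels, 512 samples,
40×40×3 images — a full cohort images in under a second, and a 5-fold
evaluation takes tens of seconds on one CPU. The end-to-end pipeline
writes every artifact with provenance (config hash over the scientific
parameters, seed, library versions); rerunning with the same config and
seed reproduces byte-identical float archives, graph files and reports
(archives are plain `.npy` + JSON sidecars specifically because zip-based
containers embed timestamps). A failing run leaves a `.failed` marker
rather than silently partial output.

## Known limitations

- The five-region prefix rule is a convention, not anatomy; region
  membership is fully configurable, and no attempt is made to model the
  18-region parcellations used in some related work.
- The Clough–Tocher interpolant is undefined outside the electrode hull;
  regions with few, tightly clustered electrodes (e.g. occipital here)
  produce small informative areas.
- The correlation-distance kernel treats images holistically; it does not
  localize which region drives similarity.
- The classification head is a protocol vehicle, not a tuned architecture;
  no convolutional structure, augmentation or transfer learning is
  included.
- EDF files can be read (via mne) but not written; the simulator exports
  long-format CSV.
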