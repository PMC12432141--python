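# Methods

## Screening model

`caescreen` detects artifact-laden fluorescence microscopy images by
reconstruction error. A convolutional autoencoder is trained exclusively on
artifact-free images, with the input as its own target, so it learns to
compress and reproduce the one structure class authentic images contain:
sparse, point-like emitters of varying brightness. Structures it never saw
— extended blobs, lines, streaks, dense clusters — pass poorly through the
125 × 125 × 256 bottleneck (32 × 32 × 32 at desk scale), leaving a large
localized reconstruction error.

The per-image score is the **image reproduction error**,

    IRE = Percentile({(I_xy − O_xy)^2 | all pixels}, 99.99),

the 99.99th percentile of the squared pixel errors between input `I` and
reconstruction `O`. For a 500 × 500 input this is (after interpolation)
roughly the 26th-largest squared error, so ~25 deviating pixels suffice to
move the score while the mean over 250,000 pixels would barely change —
that is what makes small artifacts detectable. Scores are compared against
a dataset-adaptive threshold

    t = q50 + 3 · (q50 − q25)

over the IREs of all images in the dataset. Using the lower half-spread
q50 − q25 (instead of the full IQR, with the 1.5 multiplier doubled in
compensation) makes the threshold immune to any inflation of values above
the median, i.e. robust up to a 50% artifact load. Images with `IRE > t`
(strictly) are flagged artifact-laden.

## Model and training choices

* Architecture: Conv(f1, k1=2) → MaxPool(2) → Conv(f2, k2=5) → MaxPool(2)
  → ConvT(f2, k2, stride 2) → ConvT(f1, k1, stride 2) → Conv(1, k1), all
  ReLU, all "same"-padded (the printed feature-map sizes force same
  padding and stride 1 everywhere except the transposed convolutions).
  Defaults f1=126, f2=256, input 500 × 500; a single `scale` factor shrinks
  input side and filter counts together for small machines.
* Loss is mean squared error — the same quantity used for validation
  monitoring, keeping training and evaluation coherent. Optimizer Adam
  (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-7), batch size 2, 8 epochs. The small
  batch matters: with only 8 epochs over a few hundred images, larger
  batches leave too few optimizer steps and training can settle in a
  degenerate basin that reproduces bright point signals at roughly half
  their amplitude (the MSE-optimal "spread the mass" solution when the
  network has not yet learned to encode sub-block peak positions through
  the pooling layers). Batch 2 quadruples the step count within the same
  epoch budget and, together with the initialization below, escapes that
  basin reliably. The per-epoch
  validation record carries the clean-image MSE and the percent excess of
  the artifact-laden MSE; an optional `select_best` mode keeps the epoch
  with the largest percent excess, because the lowest clean MSE does not
  necessarily separate the classes best.
* Weight initialization is seeded Glorot-uniform (He-normal available as an
  option); biases start at zero. On this sparse-target reconstruction task
  Glorot's smaller early weights converge markedly more reliably within few
  epochs than He-normal, judged on training loss across seeds. Training is
  deterministic for a fixed config seed (pure numpy, no backend
  nondeterminism).
* The engine is written directly in numpy (float32, NHWC): convolutions
  accumulate one GEMM per kernel tap over shifted input slices, transposed
  convolution is convolution of the zero-dilated input with the flipped
  kernel, and its data gradient is the matching strided convolution.
  Gradients are verified against finite differences and layer outputs
  against scatter/scipy oracles in the test suite.

## Preprocessing conventions

* Gaussian blur: 5 × 5 kernel. Only the kernel size is fundamental; the
  sigma uses the size-derived convention `0.3·((k−1)/2 − 1) + 0.8` (1.1 for
  k=5), the default of mainstream image libraries, and is overridable.
  Border handling is mirror (reflect-101) padding, which avoids a dark rim
  that zero padding would leave to survive thresholding as a fake edge.
* Background zeroing: threshold `mean + 5·SD`, both computed over all
  pixels of the *blurred* image (the blur exists precisely to shrink the
  background variance before this step). SD is the population standard
  deviation (divisor n) — immaterial at 10⁶ pixels but fixed for
  reproducibility. Pixels strictly below the threshold become zero; values
  equal to it are kept, so a constant image (SD 0) passes unchanged.
* Block reduction: non-overlapping 2 × 2 means (scikit-image
  `block_reduce`), halving the side.
* Normalization divides by the fixed sensor full scale `2^14 − 1`, not the
  per-image maximum, so intensities remain comparable across images and a
  single model and a single IRE threshold apply dataset-wide.

## Quantile conventions

All percentiles/quantiles (the IRE's 99.99th percentile, q25/q50 of the
threshold rule) use linear interpolation between order statistics at rank
`(n − 1)·q` — numpy's default. The choice matters: the 99.99th percentile
of 250,000 values lands between the 25th- and 26th-largest, so a
nearest-rank convention would shift every score. The convention is fixed
here and checked against a full-sort + hand-interpolation oracle.

## Statistical evaluation

* **t-test**: two-tailed Welch (unequal variances) by default, since group
  sizes and spreads differ wildly in practice (hundreds of clean vs dozens
  of laden images); Student's variant by flag.
* **Bootstrap AUC**: 10,000 subsets by default, each drawing
  m = min(n_clean, n_laden) images per class with replacement (balanced to
  avoid class-imbalance bias). Per subset an unregularized single-feature
  logistic regression of label on IRE is fitted and the AUC of its scores
  computed on that subset; the reported value is the mean over subsets.
  Because the logistic score is monotone in its only feature, each
  subset's AUC equals the Mann–Whitney rank AUC whenever the fitted slope
  is positive (asserted in tests). AUC is computed in-subset; for a single
  monotone feature a held-out variant would differ only through resampling
  noise. Positive class is artifact-laden throughout.
* **Confusion metrics**: sensitivity = TP/(TP+FN), specificity =
  TN/(TN+FP), accuracy = (TP+TN)/n, in percent, artifact-laden positive.
  With no positives (or negatives) in the truth, the undefined rate is
  reported as NaN, never as 0.

## Synthetic scenes

The generator emulates the assay's raw data so the pipeline is fully
testable without microscope files. Everything is a pure function of the
scene spec, including its seed.

* **Clean scenes**: i.i.d. Gaussian background per pixel (default mean 500,
  SD 50 counts, matching a camera characterized only by mean/SD; a Poisson
  variant is a flag), plus point emitters — each a delta of random
  integrated intensity convolved with an isotropic Gaussian PSF (sigma
  1 px, truncated at 4σ so footprints are exact). Default 300 emitters per
  1000 × 1000 frame (area-scaled at other sides). Intensities are drawn
  log-uniform over 2000–90,000 integrated counts, i.e. peak intensities
  from ~300 counts (just above background) to ~14,300 of the 16,383 full
  scale — the "large variability" regime the method targets; a 14-bit
  sensor whose signals stayed below 10% of full scale would not be operated
  that way. Intensities are rounded and clipped to the 14-bit range.
* **Artifacts** (rendered additively on the noiseless scene, so the mask of
  altered pixels is exact): *blob* — Gaussian disc, peak 8000 counts,
  extent 6% of the side; *scratch* — straight band, peak 5000, length half
  the side, width 3 px; *streak* — like a scratch but wider (8 px), dimmer
  (3000) and fading toward its ends; *agglomerate* — round(density·extent²)
  extra emitters (default 0.05 px⁻² over a box 10% of the side) drawn from
  the scene's own amplitude distribution, i.e. individually authentic
  signals at pathological density. Sizes scale with the image side so the
  same classes exist at any simulated resolution. These defaults span the
  qualitative range seen in practice (small conspicuous defects to large
  bright contaminations) and are all configurable.

What the simulator does **not** model: optics-accurate TIRF physics,
camera-specific noise (read/shot-noise mixtures, hot pixels), illumination
gradients, multi-channel data, or focus drift. Passing tests therefore show
that the implementation is correct and that the method separates these
artifact classes from point-emitter scenes — not that any particular
accuracy carries over to a given real instrument.

## Reference experiment and problem sizes

The package's reference experiment (`desk_scale_experiment`, also run by
`scripts/acceptance.py` and the end-to-end test) uses raw scenes of 256 px
(autoencoder input 128 × 128), filters 16/32, 200 clean training images,
8 epochs, and 50 clean + 50 artifact-laden held-out images — sizes chosen
so a full run finishes in about two minutes on one CPU core while keeping
every pipeline stage at realistic sparsity and dynamic range. The Welch
test and bootstrap AUC (1000 subsets at this scale) are computed on the
full 50/50 held-out set. The adaptive threshold, by construction, assumes
an artifact load below 50%, so the confusion metrics are measured on a
realistically mixed subset of the same scored images (all 50 clean plus 17
laden, ~25% load — comparable to heavily loaded real datasets). Master
seeds fan out into named substreams (simulate / train / bootstrap), so
e.g. changing the number of bootstrap subsets never changes the simulated
images.

## Known limitations

* Artifacts dimmer than the background-zeroing threshold are removed by
  preprocessing and cannot be detected downstream.
* Agglomerates of well-separated authentic signals may reconstruct almost
  as well as clean scenes and can fall below the threshold; dense or
  overlapping clusters are detected reliably.
* The adaptive threshold breaks down when half or more of a dataset is
  artifact-laden; a precomputed assay-specific threshold can be supplied
  instead (`fixed_threshold` / `--threshold`).
* The numpy engine is single-core and intended for the scaled
  configuration; training the full 500 × 500 / 126 × 256-filter model is
  supported but slow without further optimization.
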