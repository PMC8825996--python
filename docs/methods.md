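# Methods

## The inferential problem

Given two cohorts of single-channel immunofluorescence micrographs of one
neuropil, decide whether the cohorts' image distributions differ. Classical
pixel statistics (mean relative fluorescence + ANOVA/Tukey) capture global
intensity shifts but can miss textural or spatially localized differences;
a classifier two-sample test captures any difference a convolutional network
can exploit. The package implements both, plus the synthetic data needed to
validate them.

## Classifier two-sample test

**Datasets.** For cohorts X and Y, the pairwise dataset labels X's images 0
and Y's images 1. For each cohort, a *control* dataset halves the cohort's
images at random (larger half gets label 0 when n is odd) and relabels them:
its labels carry no information, so its accuracy distribution is the
procedure's null. Three pairwise + three control datasets make up the full
three-cohort protocol (six datasets per neuropil).

**Protocol.** Each dataset is split into train/validation parts `n_splits`
times (stratified random splits; default 10, validation fraction 0.2). Per
split, a freshly initialized network is trained `runs_per_split` times
(default 10 — 100 runs per dataset) and its final-epoch validation accuracy
recorded. The test statistic is the mean of the per-split mean accuracies;
a 95% t-interval over the `n_splits` split means (df = n_splits − 1; a
normal-approximation option exists) yields the decision: *differentiable*
iff the CI lower bound strictly exceeds 0.5. The strict inequality makes a
degenerate all-0.5 run (zero-width CI at 0.5) non-significant.

Splits are image-level by default; an animal-grouped mode keeps the one or
two neuropils of an animal on the same side of the split, guarding against
identity leakage. For the synthetic generator the two modes behave alike
(per-animal images share no identity signature beyond cohort), but grouped
splitting is the safer default for real data with repeated measures.

**Network.** Three convolution blocks (32/64/128 filters, 3×3 kernels, ReLU,
2×2 max-pool), dropout 0.25, flatten, dense 128 + ReLU, dropout 0.5, dense 2
with softmax; cross-entropy loss, Adam (lr 10⁻³, β₁ 0.9, β₂ 0.999), batch
size 16, 50 epochs. All of it is configurable (`ModelConfig`). The network
is written directly on numpy (`neuroseason.nn`): convolutions are lowered to
matrix products via im2col, max-pool backward routes gradients through the
recorded argmax, dropout is inverted (identity at inference), and the
softmax/cross-entropy pair is fused. Weights use Glorot-uniform
initialization so that initial logits are near zero and no optimizer budget
is spent unwinding confidently wrong random predictions. All parameter
gradients are validated against central finite differences in the tests.

**Augmentation.** Training images (never validation images) are rotated by an
angle uniform in ±5° (bilinear, nearest-border fill) and flipped horizontally
with probability 1/2. Augmentation *enlarges* the training set: each epoch
iterates over `expansion` independently deformed copies of every training
image (default 4). Besides regularizing, the expansion sets the number of
optimizer updates per epoch, which is what determines whether a 15-epoch
scaled-down run converges at all: with ~48 training images and batch 16, a
1× pass gives 3 updates/epoch, and the dropout-regularized network
demonstrably cannot escape the symmetric initialization within 45 updates,
while 4× (12 updates/epoch) converges reliably. Both dropout-free training
and 50–60-epoch schedules converge at 1×, so this is an optimization-budget
choice, not a correctness one.

**Divergence.** A non-finite training loss raises `TrainingDivergedError`
instead of contaminating the accuracy aggregate.

**Grad-CAM.** For a trained network, image and target class, the channel
weights are the spatial means of ∂(class logit)/∂(feature map) at the last
convolution block (post-ReLU, configurable); the map is the rectified
weighted sum of feature maps, bilinearly upsampled to the image grid and
divided by its maximum. All-zero maps (constant class score) are returned
unnormalized with a logged notice. Overlays blend a colormapped heatmap over
the grayscale image with per-pixel weight `alpha * heat`, so cold regions
show the unaltered micrograph.

## Classical quantification

Images are cropped to the tight bounding box of their mask, bilinearly
resized to the neuropil's standard resolution — lamina (500, 100), medulla
(800, 400), lobula (250, 400) in (rows, cols) — and summarized by the
arithmetic mean intensity over all pixels. The mean is taken *after*
crop + resize so that all images are commensurate. Cohorts are compared per
neuropil with one-way ANOVA followed by Tukey's HSD computed from the
studentized range distribution with the Tukey–Kramer unequal-n correction
(α = 0.05 default); the q statistic is exposed per contrast, and the
p-values are cross-checked against statsmodels in the tests. A two-way
(cohort × neuropil, type-II) ANOVA mode is provided for pooled tables.
Zero within-group variance with identical means is reported as an explicitly
undefined F (NaN plus a note) rather than an arbitrary number. Head width vs
neuropil area uses the Pearson product-moment correlation with its two-sided
p-value.

## Synthetic micrograph generator

Each image is rendered at the kind's standard resolution as a two-level
field: background `b` and foreground SI "profiles" `f` covering an exact
fraction `d` (texture_density) of the mask, plus additive Gaussian pixel
noise (sd default 10 intensity units; a Poisson option exists) clipped to
[0, 255]. Profiles are the top-`d` quantile of Gaussian-smoothed white noise
(smoothing sigma = texture_scale), which gives blob/filament shapes whose
scale is controllable; only the intensity/texture statistics matter
downstream, so no biophysical neuron model is attempted. Geometry follows
the qualitative anatomy: lamina profiles cover the whole mask (dense
meshwork), medulla profiles are confined to the central 60% of the
distal–proximal (row) axis, lobula profiles are sparse blobs. With
`b = background_fraction · m` the foreground level solves
`d·f + (1−d)·b = m`, so the expected within-mask mean equals
`mean_intensity` exactly (noise clipping adds a negligible bias away from
the 0/255 rails); the generator refuses parameter combinations that would
push `f` beyond 255.

Per animal, head width is Normal(mean, sd) in µm and neuropil area is
`0.25 · width² · area_scale` with lognormal jitter (σ = 0.04) — area scales
with the square of linear size, and the jitter is kept below the squared
head-width spread so the size–width correlation stays clearly positive even
within low-variance laboratory cohorts.

Cohort presets encode the *direction* (not magnitude) of the observed
seasonal contrasts: hibernating lamina intensity 25% below active (100 → 75
units), outside medulla 10% above the laboratory cohorts (80 → 88), outside
head width ~40% above the laboratory cohorts (946 vs 685 µm, sd 40 vs 15),
lamina density 0.5, medulla 0.4, lobula 0.15 (sparse, higher background
fraction so the foreground stays within 8 bits). `plant_effect` scales mean
intensity and/or density by (1 + δ) to create controlled effect sizes.

**What the generator does not emulate:** optical blur and shading, animal-level
intensity variability beyond texture-layout randomness, staining-batch
effects, anatomical landmarks, or multi-channel context. Passing tests
therefore demonstrate that the *procedure* is calibrated and powerful under
a faithful null and a known effect — not that any particular biological
magnitude is recoverable from real micrographs.

## Reproducibility and problem sizes

Every stochastic stage takes a seed; one master seed derives all stage seeds
via `numpy.random.SeedSequence` spawning in a fixed, documented order, so any
sub-stage reruns in isolation and a rerun of a whole experiment is
bit-identical. Experiments checkpoint per-dataset JSON and resume from it.

The full protocol (10 splits × 10 runs × 50 epochs at native resolution) is
expensive on one CPU, so routine validation uses the scaled-down protocol:
3 splits × 2 runs, 15 epochs, images downscaled 4× (lamina 125 × 25), with
15 animals × 2 neuropils per cohort — the cohort sizes of the motivating
study. The acceptance script runs the null calibration over 5 replicate
control experiments and one planted-effect (δ = 0.25) decision in a few
minutes; the power sweep in the test suite uses 10 animals × 2 neuropils per
cohort with the 3 × 2 scaled-down protocol and a dimmed base intensity
(80 units) so that the largest planted effect still renders within 8 bits.
With only 2–3 splits and 1 run each, the t-interval can collapse to zero
width when split means tie, which turns any mean above 0.5 into a spurious
detection — the sweep therefore keeps 2 runs per split.

## Known limitations

* The two-level texture makes planted intensity effects easier for the CNN
  than subtle real-world differences; scaled-down accuracies near 1.0 on a
  25% effect should not be read as a statement about real micrographs.
* The t-interval over few split means is conservative at 3 splits
  (df = 2); the full protocol's 10 splits is the intended operating point.
* Accuracy is evaluated at the final epoch (a best-epoch option exists but
  is off by default), so under-trained runs bias the statistic toward
  chance — conservative for detection, but a reason to keep the update
  budget per run roughly constant when scaling the protocol down.
* Max-pool gradient routing is exact for distinct window values; ties (all
  zeros after ReLU) send the gradient to the first maximum, which matches
  common framework behaviour.
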