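# neuroseason

Tools for asking whether two cohorts of animals differ in the serotonin
immunofluorescence (SI) of a brain region, when the images are too few and
too textured for conventional pixel statistics to be trusted. The package
was built around seasonal comparisons in the optic-lobe neuropils (lamina,
medulla, lobula) of ant workers — hibernating (H), active laboratory (A)
and outside-foraging (O) cohorts — but the machinery is generic.

It implements two complementary analyses:

1. **Classical quantification** — crop each neuropil micrograph to its mask,
   resize to the standard per-neuropil resolution (lamina 100 × 500,
   medulla 400 × 800, lobula 400 × 250 pixels, width × height), take the
   mean relative fluorescence, then compare cohorts with one-way ANOVA and
   Tukey's HSD (studentized range, Tukey–Kramer correction), and correlate
   neuropil size with head width.

2. **A classifier two-sample test** — infer that two image sets differ if a
   small convolutional network can classify held-out images better than
   chance. For cohorts X, Y with images split into train/validation parts
   \(k = 10\) times and the network retrained \(r = 10\) times per split,
   the test statistic is the per-split mean final-epoch validation accuracy
   \(\bar a_1,\dots,\bar a_k\); with
   \(\bar a = \tfrac1k\sum \bar a_i\) and
   \(\mathrm{CI}_{95} = \bar a \pm t_{0.975,\,k-1}\, s/\sqrt{k}\),
   the cohorts are declared *differentiable* iff the CI lower bound
   strictly exceeds 0.5. Matched control datasets (one cohort halved
   arbitrarily and relabelled) calibrate the procedure's null behaviour.
   Grad-CAM heatmaps localize the image regions driving the classification.

Because such micrograph collections are rarely public, the package ships a
seeded synthetic generator (`neuroseason.synthgen`) that emulates the
statistical structure of the real data — per-neuropil texture geometry,
cohort-dependent mean intensity, per-animal covariates — with *plantable*
effect sizes, so every inferential claim can be validated against a known
ground truth.

The CNN itself (convolution, ReLU, max-pooling, dropout, dense, softmax;
cross-entropy loss; Adam) is implemented in numpy in `neuroseason.nn`, with
gradients verified against finite differences in the test suite.

## Worked example

```python
import numpy as np
from neuroseason import (
    cohort_presets, generate_cohort, plant_effect,
    build_pairwise_dataset, build_control_dataset, DifferentiabilityTest,
)
from neuroseason.pipeline import downscale_images

base = cohort_presets("lamina")["A"]              # active-cohort lamina spec
dim  = plant_effect(base, delta_intensity=-0.25)  # hibernating-like: 25% dimmer

imgs_a, _ = generate_cohort(15, "lamina", base, neuropils_per_animal=2, seed=11)
imgs_h, _ = generate_cohort(15, "lamina", dim,  neuropils_per_animal=2, seed=12)
small_a, small_h = downscale_images(imgs_a, 4), downscale_images(imgs_h, 4)

from neuroseason.cnn_infer import ModelConfig
protocol = dict(n_splits=3, runs_per_split=2, config=ModelConfig(epochs=15))

pair = DifferentiabilityTest(**protocol, random_state=42).fit(
    build_pairwise_dataset(small_a, small_h, "AH"))
ctrl = DifferentiabilityTest(**protocol, random_state=43).fit(
    build_control_dataset(small_a, "AA", seed=5))

for t in (pair, ctrl):
    s = t.summary_
    print(f"{s.dataset_tag}: mean={s.grand_mean:.2f} "
          f"CI=[{s.ci_low:.2f}, {s.ci_high:.2f}] "
          f"significant={t.decision_.significant}")
```

prints

```
AH: mean=1.00 CI=[1.00, 1.00] significant=True
AA: mean=0.50 CI=[0.50, 0.50] significant=False
```

The planted 25% intensity difference is detected with perfect held-out
accuracy (the CI lower bound 1.00 > 0.50), while the signal-free control —
the same cohort halved arbitrarily — stays at chance and is correctly not
declared differentiable.

The same protocol is available end to end from the shell:

```bash
neuroseason run --scaled-down --out results/demo --seed 0
neuroseason generate --kind lamina --n-animals 15 --out data/ --seed 0
neuroseason quantify --manifest data/manifest.csv --out results/stats
neuroseason infer --manifest data/manifest.csv --downscale 4 --out results/ml --seed 0
neuroseason gradcam --manifest data/manifest.csv --pair AH --out results/cam --seed 0
```

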