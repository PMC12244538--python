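# mitodet

Mitosis detection in H&E histopathology tiles: stain normalization, a
150-slot handcrafted feature bank, hybrid jellyfish/walrus wrapper feature
selection, a skip-connected fully convolutional detector trained with
focal loss, and an 11-metric evaluation suite — with seeded synthetic
generators so every stage runs end to end without external data.

## Who this is for

Counting mitotic figures is a core step in tumor grading, and automating
it is hard: mitoses are rare (heavy class imbalance), morphologically
diverse, and easily confused with apoptotic nuclei, while staining varies
across labs and scanners. `mitodet` packages one complete detection recipe
for that problem so each stage can be studied, tested and reused:

1. **Stain normalization** — optical-density color deconvolution with a
   robust data-driven stain-matrix estimate, remapping tiles through a
   reference stain profile.
2. **Feature bank** — a versioned 150-slot descriptor per tile: local
   directional pattern (Kirsch top-3) and Gabor-bank frequency-pattern
   texture histograms, per-component shape statistics, RGB/HSV color
   statistics.
3. **Feature selection** — a hybrid of the Jellyfish Search Optimizer
   (global exploration, time-control-gated moves) and the Walrus
   Optimization Algorithm (feeding/migration/escape phases), recombined
   with crossover 0.8 / mutation 0.2, maximizing the cross-validated F1
   of candidate feature subsets.
4. **CDL detector** — a VGG-16-style backbone (13 conv + 3 FC layers)
   converted to a fully convolutional network, with three 1×1-conv skip
   connections fused into a transposed-convolution upsampling path,
   trained with focal loss, two-rate Adam, plateau LR decay and early
   stopping. Implemented as a compact CPU NumPy layer library with
   hand-written backprop, structurally identical at any channel width
   (`width_scale`) so the full architecture trains at desk scale.
5. **Evaluation** — sensitivity, specificity, accuracy, F-measure, CSI,
   balanced accuracy, Fowlkes–Mallows, markedness, negative likelihood
   ratio, FPR and FNR from one confusion tally, plus object-level
   detection F1 with centroid-within-mask matching.

The fitness the selector maximizes is `F1 = 2PR/(P+R)`; the detector's
loss is the focal loss `−α(1−p_t)^γ log p_t` (α = 0.25, γ = 2). See
`docs/methods.md` for the full model descriptions and design rationale.

## Worked example

```python
import numpy as np
from mitodet import (
    TileGenParams, gen_stain_pair, estimate_stain_profile,
    normalize_to_reference, extract_feature_vector,
    TableGenParams, gen_feature_table, HJWOAConfig, hjwoa_run,
)

# Two renderings of one scene under different stain jitter ...
params = TileGenParams(side=96, n_nuclei=15, n_mitotic=2,
                       stain_perturbation=0.15, seed=100)
a, b = gen_stain_pair(params)
pre = np.abs(a.pixels.astype(float) - b.pixels.astype(float)).mean()

# ... normalized through one estimated stain profile
profile = estimate_stain_profile(a)
an, bn = (normalize_to_reference(t, profile) for t in (a, b))
post = np.abs(an.pixels.astype(float) - bn.pixels.astype(float)).mean()
print(f"mean pixel distance: {pre:.2f} -> {post:.2f}")

# Wrapper selection on a table with 5 known informative columns
X, y, informative = gen_feature_table(
    TableGenParams(n_samples=300, d=150, n_informative=5,
                   effect_size=2.0, seed=1000))
result = hjwoa_run(X, y, config=HJWOAConfig(population=30, iterations=50,
                                            seed=0))
hits = int(result.mask.astype(bool)[informative].sum())
print(f"selected {result.n_selected}/150 features, F1={result.fitness:.4f}, "
      f"recovered {hits}/5 informative")
```

Output:

```
mean pixel distance: 6.34 -> 2.75
selected 14/150 features, F1=0.9967, recovered 4/5 informative
```

The first line shows stain normalization removing most of the staining
difference between two renderings of the same tissue. The second shows
the hybrid selector recovering four of the five genuinely
class-separating columns among 150 while discarding nearly all noise
columns.

Short narrative scripts for each capability live in `examples/`; the
end-to-end pipeline (`simulate → normalize → extract-features →
select-features → train → evaluate`) is available both as
`mitodet.pipeline.run_pipeline` and as the `mitodet run` CLI with a YAML
config.

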