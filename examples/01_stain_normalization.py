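"""Stain normalization: remove staining variation between paired tiles.

Renders the same synthetic tissue scene twice under independent stain
jitter, estimates a stain profile from the first rendering, and maps both
through it. The printed distances show how much of the inter-tile pixel
difference was staining rather than tissue.
"""

import numpy as np

from mitodet import (
    TileGenParams, estimate_stain_profile, gen_stain_pair,
    normalize_to_reference,
)

params = TileGenParams(side=128, n_nuclei=18, n_mitotic=3,
                       stain_perturbation=0.15, seed=42)
a, b = gen_stain_pair(params)

profile = estimate_stain_profile(a)
print("estimated stain matrix (rows: hematoxylin, eosin):")
print(np.round(profile.stain_matrix, 3))

pre = np.abs(a.pixels.astype(float) - b.pixels.astype(float)).mean()
an = normalize_to_reference(a, profile)
bn = normalize_to_reference(b, profile)
post = np.abs(an.pixels.astype(float) - bn.pixels.astype(float)).mean()

print(f"mean pixel distance before normalization: {pre:.2f} intensity levels")
print(f"mean pixel distance after normalization:  {post:.2f} intensity levels")
print("-> the residual is tissue noise; the staining difference is gone")
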