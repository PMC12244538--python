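"""Train the quarter-width CDL detector on synthetic tiles (CPU, ~2 min).

Trains from scratch on 40 easy 96-px tiles, then scores object-level
detection F1 on 20 held-out tiles using centroid-within-mask matching.
"""

import numpy as np

from mitodet import CDLConfig, TileGenParams, build_cdl, gen_he_tile, train
from mitodet.cdl import (
    detection_f1, postprocess_detections, predict_segmentation,
)


def make_tiles(n, seed0, rng):
    return [
        gen_he_tile(TileGenParams(
            side=96, n_nuclei=12, n_mitotic=int(rng.integers(0, 4)),
            seed=seed0 + i, difficulty="easy",
        ))
        for i in range(n)
    ]


rng = np.random.default_rng(7)
train_tiles = make_tiles(40, 10_000, rng)
val_tiles = make_tiles(8, 20_000, rng)
test_tiles = make_tiles(20, 30_000, rng)

config = CDLConfig(input_side=96, width_scale=0.25, batch_size=8,
                   max_epochs=25, patience=10, plateau_patience=10,
                   seed=11, pretrained_source="none")
net = build_cdl(config)
print("architecture:", {k: v for k, v in net.describe().items()
                        if k in ("n_conv_layers", "n_fc_equivalent")})

state = train(net, train_tiles, val_tiles, config)
print(f"trained {state.epoch} epochs ({state.stop_reason}); "
      f"val loss {state.history[0]['val_loss']:.4f} -> "
      f"{state.history[-1]['val_loss']:.4f}")

pairs = []
for tile in test_tiles:
    prob = predict_segmentation(net, tile)
    pairs.append((postprocess_detections(prob), tile.mask))
print(f"held-out object-level detection F1: {detection_f1(pairs):.4f}")
print("-> 1.0 means every mitotic figure found with no false alarms")
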