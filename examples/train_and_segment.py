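"""Train the segmentation network on synthetic scenes and segment a held-out one.

Uses the CPU-sized conditions: the scaled camera (same field of view as the
default camera at 1/8 the resolution), a reduced channel plan and a 96 px
working resolution.  Takes a minute or two on one CPU.  The final lines show
the held-out dice — overlap between the predicted and true wound mask —
and the wound pixel count the area step would consume.
"""

import numpy as np

from woundseg import NetworkConfig, TrainConfig, build_network, train, predict_mask
from woundseg.metrics import confusion, dice
from woundseg.synthetic import SCALED_CAMERA, generate_scenes

scenes = generate_scenes(24, seed=11, camera=SCALED_CAMERA,
                         area_range_cm2=(10, 35), height_range_mm=(120, 300))
net = build_network(NetworkConfig(variant=813, input_side=96,
                                  stage_channels=(8, 16, 32, 64, 128),
                                  ca_reduction=4, seed=1))
result = train(scenes, net, TrainConfig(epochs=50, max_steps=100, batch_size=8,
                                        val_fraction=0.2, seed=3))
print(result.history.tail(3).to_string(index=False))
print(f"best validation dice {result.best_val_dice:.3f}")

held_out = generate_scenes(1, seed=77, camera=SCALED_CAMERA,
                           area_range_cm2=(10, 35), height_range_mm=(120, 300))[0]
pred = predict_mask(net, held_out.image)
d = dice(confusion(pred, held_out.mask))
print(f"held-out scene: dice {d:.3f}, predicted wound pixels {int(pred.sum())} "
      f"(ground truth {held_out.lambda_true})")
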