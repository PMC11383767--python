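"""Bicubic resizing and the six-transform augmentation set.

Renders one synthetic leaf image at capture-like resolution, resizes it to
the network input size with the Keys bicubic kernel (a = -0.5), and applies
each of the six augmentation transforms.
"""

import numpy as np

from resswin import (DEFAULT_AUGMENTS, cubic_kernel_weight, resize_bicubic)
from resswin.imaging import apply_augment
from resswin.synthgen import SynthConfig, generate_leaf_image

# kernel sanity: 1 at the origin, 0 at the knots, weights sum to 1
print("W(0)   =", cubic_kernel_weight(0.0))
print("W(1)   =", cubic_kernel_weight(1.0))
print("W(0.5) =", cubic_kernel_weight(0.5))
u = 0.37
print("partition of unity at u=0.37:",
      sum(cubic_kernel_weight(k - u) for k in (-1, 0, 1, 2)))

cfg = SynthConfig(image_size=448, seed=3)
img = generate_leaf_image("mite", np.random.default_rng(3), cfg)
small = resize_bicubic(img, 224, 224)
print(f"\nresized {img.shape} -> {small.shape}")

for op in DEFAULT_AUGMENTS:
    out = apply_augment(small, op)
    print(f"{op.name:>9}: shape {out.shape}, mean intensity "
          f"{out.mean():6.1f} (input {small.mean():6.1f})")
# rot90 swaps H and W; dim/brighten scale the mean by ~0.9/~1.5 (clamped);
# the blur leaves the mean nearly unchanged while smoothing detail.
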