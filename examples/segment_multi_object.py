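"""Extract three objects with different intensity levels from one contour.

Builds a 128x128 phantom with three objects (levels 0.95, 0.60, 0.30 on a
0.05 background, two of them with interior holes), initializes a single
rectangle enclosing everything, and runs both the localized patch model
and the global FEAC baseline.  The localized model recovers all three
objects; the global two-prototype fit drops the dimmest one.
"""

import numpy as np
from scipy import ndimage

from lofac import (
    FeacParams,
    ModelParams,
    count_recovered_components,
    default_seed_box,
    dice_coefficient,
    feac_segment,
    segment,
    three_object_phantom,
)

image, truth = three_object_phantom(seed=0)
box = default_seed_box(128)

res = segment(image, box, ModelParams(radius=20, m=2.0))
n_comp = ndimage.label(res.binary_mask, np.ones((3, 3), bool))[1]
print(f"localized: Dice={dice_coefficient(res.binary_mask, truth):.4f} "
      f"components={n_comp} sweeps={res.iterations_run} converged={res.converged}")

res_f = feac_segment(image, box, FeacParams(m=2.0))
print(f"global FEAC: Dice={dice_coefficient(res_f.binary_mask, truth):.4f} "
      f"objects recovered={count_recovered_components(res_f.binary_mask, truth)}/3")

print("\nA Dice of 1 is a perfect overlap with the ground truth; the")
print("localized model finds all 3 objects because each patch only has to")
print("separate one object level from its local background, while the")
print("global baseline fits one foreground prototype to all three levels")
print("and sacrifices the object closest to the background.")
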