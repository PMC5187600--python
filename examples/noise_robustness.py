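"""Segmentation under additive Gaussian noise of increasing variance.

Renders the circle+rectangle phantom at noise variances 0.01, 0.10 and
0.20 (on the [0,1] intensity scale) and segments it with the localized
model and the FEAC baseline, starting from one seed box per shape.
"""

from lofac import FeacParams, ModelParams, dice_coefficient, feac_segment, segment
from lofac.phantoms import circle_rectangle_spec, generate_phantom, seed_boxes_for

print("variance  localized-Dice  FEAC-Dice")
for variance in (0.01, 0.10, 0.20):
    spec = circle_rectangle_spec(noise_variance=variance, seed=0)
    image, truth = generate_phantom(spec)
    boxes = seed_boxes_for(spec)
    res = segment(image, boxes, ModelParams())
    res_f = feac_segment(image, boxes, FeacParams())
    print(f"  {variance:4.2f}      {dice_coefficient(res.binary_mask, truth):8.4f}"
          f"      {dice_coefficient(res_f.binary_mask, truth):8.4f}")

print("\nAt variance 0.20 the noise standard deviation (~0.45) is half the")
print("object/background contrast, and any per-pixel global classifier is")
print("capped near Dice 0.7.  The narrow-band evolution stays above 0.9")
print("because only contour-adjacent pixels are ever updated, while the")
print("full-image FEAC sweeps label noisy pixels everywhere (speckle).")
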