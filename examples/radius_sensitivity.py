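"""Effect of the localization radius on an inhomogeneous scene.

The phantom has two bars whose intensity ramps along their axis and
overlaps the background's range (no global threshold separates them),
plus bright border clutter that is not part of the target.  The radius
must be large enough to carry boundary information across the wide gap
between the bars, yet small enough to keep the clutter out of the local
statistics.
"""

from lofac import ModelParams, dice_coefficient, segment
from lofac.phantoms import inhomogeneous_phantom, inhomogeneous_seed_box

image, truth = inhomogeneous_phantom(seed=0)
box = inhomogeneous_seed_box(128)

print("radius  Dice")
for radius in (10, 15, 20, 25, 30):
    res = segment(image, box, ModelParams(radius=radius, max_iterations=200))
    print(f"  {radius:3d}   {dice_coefficient(res.binary_mask, truth):.4f}")

print("\nThe best Dice sits at an intermediate radius: the smallest radius")
print("is too local (the contour stalls inside the wide inter-bar gap,")
print("where no patch reaches a boundary), the largest is too global (the")
print("patches absorb the border clutter into the local background")
print("prototype and erode the ramped bars).")
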