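# lofac — localized patch-based fuzzy active contours

`lofac` segments 2-D grayscale images — synthetic phantoms, photographs,
medical scans — into a foreground and a background by evolving a *fuzzy
active contour*: a membership field `u(x) ∈ [0, 1]` whose 0.5-level plays
the role of the zero level set of a classical signed function. It is aimed
at images where the object and background are **not** globally homogeneous
(intensity inhomogeneity, multiple objects at different gray levels,
strong noise), the regime where classical global two-phase region models
fail.

## The model

Around every pixel `x` a disc patch `Ω_x = {y : |y − x| ≤ r}` (selected by
the mask `W(x, y)`) is split by the contour into a local interior and a
local exterior, each summarized by a membership-weighted mean intensity
(prototype):

    c1(x) = Σ_y W(x,y) u(y)^m I(y) / Σ_y W(x,y) u(y)^m
    c2(x) = Σ_y W(x,y) (1−u(y))^m I(y) / Σ_y W(x,y) (1−u(y))^m

The segmentation minimizes the sum of patch-local two-class fitting
energies (no curve-length regularization term):

    F(u, c1, c2) = Σ_x Σ_y W(x,y) [ u(y)^m (I(y) − c1(x))²
                                  + (1−u(y))^m (I(y) − c2(x))² ]

with fuzzifier `m > 1` (default 2) and localization radius `r` (default
20 px). Instead of solving the Euler–Lagrange PDE, the optimizer sweeps a
narrow band around the current contour and, for each pixel, evaluates a
candidate membership

    u_n = 1 / (1 + (A/B)^(1/(m−1))),   A = Σ_x W(x,P) (I0 − c1(x))²,
                                       B = Σ_x W(x,P) (I0 − c2(x))²

and the **exact closed-form energy change** ΔF of adopting it — two O(1)
update identities make both the prototype updates and ΔF computable
without re-evaluating the energy:

    ĉ1 = c1 + (u_n^m − u0^m) / (s1 + u_n^m − u0^m) · (I0 − c1),  s1 = Σ W u^m
    ΔF = Σ_x [ s1 Δ1/(s1+Δ1) (I0−c1(x))² + s2 Δ2/(s2+Δ2) (I0−c2(x))² ]

The candidate is accepted iff ΔF < 0, so the energy decreases
monotonically and the evolution needs no reinitialization. A global fuzzy
energy-based active contour (FEAC) baseline — one prototype pair for the
whole image, optional `μ·Length(C)` penalty — is included for comparison,
and a seedable phantom generator provides ground-truthed test scenes.

## Worked example

```python
from lofac import ModelParams, default_seed_box, dice_coefficient, segment, three_object_phantom

image, truth = three_object_phantom(seed=0)          # 128x128, 3 objects + holes
result = segment(image, default_seed_box(128), ModelParams(radius=20))
print(result.iterations_run, result.converged)
print(dice_coefficient(result.binary_mask, truth))
```

Running `python examples/segment_multi_object.py` (which adds the global
baseline for contrast) prints:

```
localized: Dice=0.9848 components=3 sweeps=53 converged=True
global FEAC: Dice=0.6571 objects recovered=2/3
```

i.e. the localized model recovers all three objects (Dice 0.98 against
the ground truth; the small deficit is the interior holes, which a
shrinking outer contour cannot reach), while the global baseline drops
the dimmest object entirely. The other scripts in `examples/` demonstrate
noise robustness (`noise_robustness.py`), the localization-radius
trade-off (`radius_sensitivity.py`) and file-based I/O
(`files_and_masks.py`); each prints the numbers it computes and a short
interpretation.

A thin CLI wraps the same library calls:

```sh
lofac generate --preset three-object --out-image phantom.png --out-truth truth.png
lofac segment --input phantom.png --seed 14,14,100,100 --radius 20 --out-mask mask.png
lofac evaluate --pred mask.png --truth truth.png
lofac benchmark --experiment noise --seeds 0,1,2 --out-csv report.csv
```

## Layout

- `src/lofac/image.py` — domain types, image/mask I/O, disc patch masks,
  membership initialization
- `src/lofac/energy.py` — local statistics, total energy, membership
  closed forms, incremental update identities, Dice
- `src/lofac/solver.py` — narrow-band sweep optimizer
- `src/lofac/feac.py` — global FEAC baseline
- `src/lofac/phantoms.py` — seedable phantom generator and presets
- `src/lofac/evaluate.py` — experiment protocols and CSV reports
- `docs/methods.md` — modelling assumptions, parameter guidance, design
  choices and known limitations
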