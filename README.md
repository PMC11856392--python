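# grapeyield

Grape-cluster segmentation and occlusion-corrected yield estimation from
indoor RGB imagery, with a synthetic scene generator that provides exact
ground truth for every stage.

## The problem

Counting berries from photographs underestimates yield because most berries
are hidden — behind foliage or behind each other; in heavily occluded field
imagery only about a fifth of a bunch may be visible.  Writing `V` and `O`
for the visible and occluded berries of an image, the quantity a grower
cares about is the total count `C = |V| + |O|` (and the bunch weight in
grams), not `|V|`.

`grapeyield` implements a three-stage pipeline for controlled indoor
imagery:

1. **Segment** — a U-Net maps the RGB image to a two-channel grape/background
   output and produces a cluster mask;
2. **Overlay** — the mask suppresses background pixels so the counting stage
   sees grape evidence only;
3. **Count** — a convolutional regression network with two scalar heads
   predicts total count and weight from the masked image.

Occlusion is corrected two ways: *implicitly*, because the regression
targets are the total (visible + occluded) count and the measured weight,
so the network learns the visible-evidence-to-total mapping; and
*explicitly*, through a stratified correction factor — the per-stratum
training mean of `total/visible`, which inflates a visible-count estimate
(e.g. from the distance-transform blob counter) to a total:

    C_hat = round(V_hat x r_stratum),   r_stratum = mean(C / |V|)

Count accuracy is reported as MAE and `R^2 = 1 - SS_res/SS_tot`;
segmentation accuracy as per-pixel IoU, F1, precision and recall with grape
foreground as the positive class.

Because the real dataset this design emulates is an external download, the
package ships a scene simulator: three grape clusters per image, blue /
green / purple varieties, low / medium / high foliage, white or green-bokeh
backgrounds, four view angles per bunch arrangement (sharing a `group_id`
so train/test splits never leak views of one bunch), three 3:4 resolution
tiers, and exact masks, counts and weights.  Occlusion severity is
calibratable to a target visible fraction.

## Worked example

```python
import numpy as np
from grapeyield import (SceneParams, render_scene, UNetSegmenter, overlay,
                        CNNYieldRegressor, iou)
from grapeyield.simulate import derive_seed

params = SceneParams(rows=48, cols=64, color_variety="blue",
                     foliage_level="low", background="white")
scenes = [render_scene(params, derive_seed(1, i)) for i in range(100)]
X = np.stack([s.image for s in scenes])
M = np.stack([s.mask for s in scenes])
Y = np.array([[s.total_count, s.weight_g] for s in scenes])

seg = UNetSegmenter(depth=3, base_channels=8, epochs=10,
                    learning_rate=2e-3, seed=0).fit(X[:80], M[:80])
pred_masks = seg.predict(X[80:])
print("held-out IoU:", np.mean([iou(p, t) for p, t in zip(pred_masks, M[80:])]))

masked = np.stack([overlay(x, m).image for x, m in zip(X, M)])
counter = CNNYieldRegressor(epochs=15, seed=0).fit(masked[:80], Y[:80])
pred = counter.predict(masked[80:])
print("count MAE:", np.mean(np.abs(pred[:, 0] - Y[80:, 0])))
print("one scene:", pred[0], "truth:", Y[80])
```

Output:

```
held-out IoU: 0.9380533476166125
count MAE: 3.012854929016421
one scene: [54.09142547 81.31473464] truth: [53.         80.50818657]
```

The IoU near 0.94 says the predicted masks overlap the exact ground-truth
masks almost completely on this high-contrast preset; the count MAE of
about 3 berries on scenes averaging ~55 berries corresponds to roughly 5%
deviation, and the weight head tracks the 1.5 g-per-berry generative law
(81.3 g predicted vs 80.5 g true for the scene shown).

A command-line interface wraps the same stages
(`grapeyield simulate | train-seg | segment | overlay | train-count |
predict | evaluate | ablation | seg-study`); each subcommand consumes the
previous one's files.

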