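# cervseg

Semantic segmentation of acetowhite lesions in colposcopic images of the
cervix, for computer-aided cervical-cancer screening. The toolkit covers the
full workflow around a supervised encoder–decoder model: converting expert
LabelMe polygon annotations into binary masks, preparing and augmenting
CIN-graded image/mask datasets, building and training an attention-enhanced
dual-encoder network, scoring predictions with the standard segmentation
metric suite, and explaining model decisions with Grad-CAM++ heatmaps.

Because clinical colposcopy datasets are private, the package ships a phantom
generator that emulates their structure — a bright elliptical cervix field
containing irregular bright lesion blobs with exact ground-truth masks and
polygon annotations, plus texture noise and specular highlights — so every
component is exercisable end to end with no data download.

## The model

Two convolutional encoders run side by side on a 256×256×3 input:

- a deep **resnet50-style** branch (bottleneck residual blocks,
  y = G(x, {Wᵢ}) + x) tapped at strides 2/4/8/16 and projected to
  64/128/256/512 channels;
- a lightweight **mobilenetv2-style** branch (inverted residuals built from
  depthwise-separable convolutions, y = (X ∗ W_depthwise) ∗ W_pointwise)
  tapped at the same strides and projected to 16/24/32/96 channels.

Matching levels are concatenated (deepest fused map: 512 + 96 = 608 channels
at 16×16). The fused bottleneck feeds a **lightweight ASPP** block,

    ASPP(X) = Concat(Conv_rate=1, Conv_rate=6, Conv_rate=12, GlobalAvgPool),

with depthwise-separable dilated branches of 256 channels each (→ 1024
channels). A four-stage decoder of 2× transposed convolutions restores
resolution; each skip connection passes through a **squeeze-and-excitation**
gate, σ(W₂ ReLU(W₁ GAP(X))) · X, before concatenation. A 1×1 convolution with
sigmoid emits the per-pixel lesion probability map.

Training minimizes the hybrid loss

    L = L_Dice + L_Tversky,
    L_Dice    = 1 − (2Σyŷ + ε) / (Σy + Σŷ + ε),
    L_Tversky = 1 − (Σyŷ + ε) / (Σyŷ + αΣy(1−ŷ) + βΣ(1−y)ŷ + ε),

with α = 0.7, β = 0.3 by default so false negatives (missed lesion pixels)
are penalized more heavily than false positives. Evaluation reports PA, MPA,
MIoU, FW-IoU, Dice, the boundary Hausdorff distance, and Cohen's
κ = (p_o − p_e)/(1 − p_e) between Grad-CAM++ heatmaps and reference masks.

The network and its training loop run on a compact numpy reverse-mode
autodiff engine bundled with the package (`cervseg.nn`), so no deep-learning
framework is required.

## Worked example

```python
import numpy as np
from cervseg.synthetic import load_phantom_arrays
from cervseg.runner import TrainConfig, train_arrays, evaluate_arrays

xtr, ytr, _ = load_phantom_arrays((50, 50, 50), size=64, seed=101)
xva, yva, _ = load_phantom_arrays((10, 10, 10), size=64, seed=102)
xte, yte, _ = load_phantom_arrays((10, 10, 10), size=64, seed=103)

model, log = train_arrays(xtr, ytr, xva, yva, TrainConfig.desk(seed=1),
                          checkpoint_path="desk.npz")
report = evaluate_arrays(model, xte, yte)
print(round(report.dice, 3), round(report.miou, 3))
```

This trains the 64×64 desk-scale configuration (150 training phantoms, 30
epochs, batch 8) in a few minutes on one CPU and prints

```
0.987 0.986
```

— the held-out Dice coefficient and mean IoU. A Dice of 0.987 means predicted
and true lesion masks overlap almost completely on the phantom task; the
printed training log (`log.val_dice`) shows validation Dice climbing from
roughly 0.1 to 0.98 across the 30 epochs.

The same workflow is available from the shell:

```sh
cervseg synth --n 30,30,30 --out data --seed 7     # phantom dataset
cervseg convert-masks --annotations data/annotations --out masks
cervseg build --summary                            # layer/shape table
cervseg train --train-manifest train.csv --val-manifest val.csv --desk
cervseg evaluate --test-manifest test.csv --checkpoint checkpoint.npz
cervseg explain --checkpoint checkpoint.npz --image img.png --out heat.png
```

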