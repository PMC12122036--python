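# defifnet

A lightweight **dual-encoding feature interaction fusion network** for
medical image segmentation — skin-lesion photographs and cell-nucleus
micrographs — implemented from scratch on a small numpy reverse-mode
autodiff engine, with a scikit-learn style estimator, a CLI, and a synthetic
fixture generator so every code path runs without downloading any dataset.

## The problem and the model

Dense binary segmentation of pathological regions needs both *local* texture
cues and *long-range* spatial context, ideally from a network small enough
for resource-constrained deployment. The architecture here addresses this
with an asymmetric encoder–decoder:

- **Dual encoder.** At each of L = 4 levels a U-Net branch (two 3×3
  conv-BN-ReLU units) captures neighbouring dependencies while a
  global-dependency-fusion (GDF) branch applies a single 7×7 convolution
  over a wide receptive field. The branches are summed and refined by a
  **feature interaction fusion convolution (FIFConv)**: tear the channels
  into halves, lift each half with a 1×1 convolution, transform the left
  half with a 2-group 3×3 convolution plus a 1×1 shortcut and the right with
  an identity residual plus 1×1, concatenate, gate per channel with
  σ(global average), tear again and sum.
- **Skip connections** pass through a **channel feature reconstruction
  module (CFRM)**: one channel half gated by σ(w·AvgPool(X₁) + b), the other
  by a grouped 3×3 convolution times σ(w·GroupNorm(X₂) + b) — the learnable
  scales start at 0 and shifts at 1 — followed by a 2-group channel shuffle.
- **Bottleneck**: two 3×3 conv-BN-ReLU units and a **multi-branch ghost
  module (MBGM)** — entry 3×3, a ghost pair of 1×1 convolutions, an extra
  3×3 branch fused residually, and an exit 3×3, each with BN+ReLU.
- **RFE decoder**: bilinear ×2 upsampling, 1×1 channel adjustment, skip
  concatenation, two 3×3 convolutions producing F₁, and the residual output
  FIFConv(F₁) + F₁; a 1×1 head with a sigmoid yields per-pixel foreground
  probabilities.

Training minimizes the combined objective

```
L = α · [1 − 2Σpᵢgᵢ / (Σpᵢ² + Σgᵢ² + ε)] + β · BCE(p, g),   α = 0.7, β = 0.3
```

and evaluation reports IoU, DSC, accuracy, recall and the symmetric average
Hausdorff distance. The default channel schedule (4, 4, 8, 44) with
bottleneck width 44 was fixed by `scripts/calibrate_channels.py` so that the
assembled network meets the published budget of **0.24 M parameters** and
**0.33 G MACs** for a 3×256×256 input.

## Worked example

```python
from defifnet import DEFIFNetSegmenter, SyntheticSpec
from defifnet.synth import generate_arrays
from defifnet.metrics import segmentation_metrics

spec = SyntheticSpec(mode="lesion", image_size=(64, 64), count=16, seed=123)
X, y = generate_arrays(spec)                      # (16,64,64,3) uint8, (16,64,64) {0,1}
est = DEFIFNetSegmenter(epochs=40, batch_size=16, lr=3e-3, seed=0).fit(X, y)
print(segmentation_metrics(est.predict(X), y).format_summary())
```

prints

```
iou: 95.01 ± 2.24 %; dsc: 97.43 ± 1.19 %; acc: 98.69 ± 0.63 %; rec: 98.39 ± 0.61 %; avg HD: 0.04 ± 0.05 px
```

i.e. after 40 epochs the default network reproduces the 16 synthetic lesion
masks it was fitted on almost exactly (mean per-image overlap 95 % IoU,
boundary error 0.04 px) — the memorization probe used by the learning smoke
test. The same functionality is available from the shell:

```bash
defifnet synth --mode lesion --count 16 --size 64 --out data/lesions
defifnet train config.yaml          # checkpoint + per-epoch loss history
defifnet eval run/checkpoint.npz config.yaml --out report.csv
defifnet predict run/checkpoint.npz data/lesions/images --out pred/
defifnet summary                    # parameter / MAC budget report
```

`defifnet summary` on the default configuration reports
`total parameters: 243085 (0.24 M)` and
`forward MACs: 332020042 (0.33 G)` with a per-layer breakdown.

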