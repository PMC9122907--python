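# fazseg

Lightweight attention U-Nets for segmenting the foveal avascular zone
(FAZ) in en-face OCTA images, with automatic FAZ morphometry and the
statistics used to validate it.

## What this is for

The FAZ — the capillary-free region at the centre of the retina — is a
biomarker whose area, perimeter and circularity change in glaucoma,
diabetic retinopathy and other disease. Measuring it from optical
coherence tomography angiography (OCTA) en-face projections requires a
precise segmentation that tolerates salt-and-pepper noise, scan-line
artifacts, capillary dropout and blurred boundaries. This package is
for researchers who want to

* build and train the **LWBNA_Unet** family of segmentation networks —
  U-Nets made lightweight by fixing the filter count (128 or 64),
  replacing transposed convolutions with parameter-free upsampling,
  replacing concatenating skips with additive ones, and adding
  **bottleneck channel narrowing with attention** — plus the
  conventional U-Net baselines for comparison;
* turn predicted probability maps into physical FAZ measurements
  (area in mm², perimeter in mm, circularity CI = 4πA/P²);
* quantify agreement between measurement methods (Bland–Altman bias
  and limits of agreement, Pearson's r) and disease discrimination
  from a single FAZ parameter (logistic-regression ROC/AUC);
* generate synthetic OCTA-like images with known ground truth to test
  all of the above end to end.

The whole stack is NumPy — the network engine (convolutions, batch
normalization, channel attention, Adam, backprop) is implemented in the
package and verified against adjoint identities and numeric gradients.

## The model in brief

Each network is an encoder–decoder with two conv blocks (3×3 conv + BN
+ ReLU) per resolution level and 2×2 max pooling. The channel-attention
block computes per-channel weights `w = σ(relu(W·gap(x) + b))`, which
confines every weight to **[0.5, 1)**: weak channels are damped, never
deleted. In `LWBNA_Unet` the bottleneck additionally narrows its 128
channels stepwise to 16 (conv + attention at each halving), restores
them, and fuses with a skip connection — only the high-level features
needed for reconstruction squeeze through. All seven presets reproduce
the published total parameter counts of the family exactly, e.g.

| preset | parameters |
|---|---|
| Unet | 28,340,931 |
| Unet_AB | 29,830,275 |
| Unet_AB_128_Upsampling_Add | 2,673,795 |
| LWBNA_Unet | 2,958,819 |

Training follows the published protocol: Adam (α = 1e-4, β₁ = 0.9,
β₂ = 0.99, ε = 1e-7), batch size 5, shuffling, soft dice loss, He-normal
initialization, early stopping on validation loss (min_delta 1e-8,
patience 40), fully seeded.

## Worked example

```python
import numpy as np
from fazseg import (SynthConfig, make_dataset, build_model, TrainConfig,
                    train, evaluate_testset, analyze_mask, bland_altman)
from fazseg.synthetic import dataset_arrays

cfg = SynthConfig.clear(height=96, width=96)        # visually clear stratum
train_set, _ = make_dataset(60, cfg, base_seed=1000)
val_set, _   = make_dataset(20, cfg, base_seed=5000)
test_set, _  = make_dataset(20, cfg, base_seed=9000)

model = build_model("LWBNA_Unet", seed=1, input_size=(96, 96))
model, hist = train(model, dataset_arrays(train_set), dataset_arrays(val_set),
                    TrainConfig(seed=1, max_epochs=15, early_stopping=False))

report = evaluate_testset(model, dataset_arrays(test_set))
print(f"mean test dice = {report.mean_dice_raw:.4f} "
      f"(largest-region: {report.mean_dice_largest:.4f})")

pred, true = [], []
for img3, sample in zip(dataset_arrays(test_set)[0], test_set):
    prob = model.predict(img3[None])[0, ..., 0]
    meas = analyze_mask((prob >= 0.5).astype(np.uint8),
                        cfg.mm_per_pixel, area="pixel")
    pred.append(meas.area_mm2); true.append(sample.true_area_mm2)
ba = bland_altman(np.array(pred), np.array(true))
print(f"area bias = {ba.bias:+.5f} mm^2, "
      f"LoA = [{ba.loa_low:+.5f}, {ba.loa_high:+.5f}] mm^2")
```

Output (about 12 minutes on one CPU core):

```
mean test dice = 0.9831 (largest-region: 0.9831)
area bias = +0.00666 mm^2, LoA = [-0.00100, +0.01431] mm^2
```

The mean dice says the predicted FAZ masks overlap the ground truth by
~98% on held-out clear images after only 15 epochs on 60 training
images; the Bland–Altman bias says the automatic areas run ~0.007 mm²
above the analytic truth — under 3% of a typical 0.25 mm² FAZ — with
individual disagreements inside about ±0.014 mm² of the bias.

The same workflow runs from the shell: `fazseg simulate | train |
predict | analyze | agree | roc` (see `fazseg --help`); every command
writes a JSON record of its resolved configuration next to its outputs.

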