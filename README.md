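# diagnext

Two-stage deep-learning analysis of kidney pathologies in 3D contrast-CT:
a segmentation stage that delineates background, kidney parenchyma, cysts,
tumors and stones voxel-by-voxel, followed by a classification stage that
assigns each detected lesion to one of four diagnostic classes (normal,
cyst, tumor, stone) with calibrated uncertainty. The package is aimed at
medical-image-analysis researchers who want a fully inspectable, CPU-scale
implementation of this cascade: every component — including the neural
network layers and their gradients — is plain numpy/scipy, and a synthetic
CT-phantom generator makes the entire pipeline trainable and testable
without downloading any clinical data.

## The model

**Stage 1 — segmentation.** A U-shaped 3D encoder–decoder whose blocks
follow the modern large-kernel depthwise design: each Enhanced
Convolutional Block computes

```
ECB(x) = x + γ ⊙ PW(GELU(PW(GN(DW₇ₓ₇ₓ₃(x)))))
```

with a 7×7×3 depthwise convolution, GroupNorm, an inverted 1×1×1
bottleneck, and a per-channel LayerScale γ initialized at 1e-6. The
bottleneck applies 3D atrous spatial pyramid pooling (dilated 3×3×3
branches at rates 1/3/6 plus a pooled branch); decoder skip connections
pass through additive spatial attention gates
`α = σ(ψᵀ ReLU(W_g g + W_x x + b))`. Training minimizes the compound
objective

```
L_seg = 0.4·L_CE + 0.3·L_Dice + 0.2·L_Boundary + 0.1·L_Focal
```

where the boundary term weights predicted class probability by the signed
Euclidean distance transform of the ground-truth region and the focal term
uses focusing exponent 2.

**ROI extraction.** Predicted masks are decomposed into 26-connected
components (minimum volume 27 voxels), boxed with a 15% contextual margin,
resized to 96×96×32 (aspect-preserving for extreme boxes), z-scored and
clipped to [−3, 3]. Each region carries a confidence score S combining
prediction certainty, boundary sharpness and spatial consistency.

**Stage 2 — classification.** Each ROI is processed at three resolutions
(96×96×32, 72×72×24, 48×48×16) by pathways with scale-matched kernels,
fused by context-aware attention weights conditioned on S, scaled by
`κ + (1−κ)·S`, and mapped to Dirichlet concentrations `α = softplus(z) + 1`
over the four classes. The predictive probability is `α/Σα` and the
evidential uncertainty `u = K/Σα`; training balances cross-entropy,
evidential expected cross-entropy, a KL regularizer toward the uniform
Dirichlet and an uncertainty-alignment term under temperature-softmax
adaptive weights `λᵢ = exp(zᵢ/τ)/Σⱼ exp(zⱼ/τ)` with τ = 2.

## Worked example

```python
import numpy as np
from diagnext import PhantomSpec, generate_phantom, split_patients, roi_pipeline
from diagnext.clsnet import DirichletPrediction

split = split_patients([f"patient-{i:04d}" for i in range(3847)], seed=42)
print(f"train/val/test patients: {len(split.train_ids)}/{len(split.val_ids)}/{len(split.test_ids)}")

spec = PhantomSpec(seed=7)
vol = generate_phantom(spec, "demo-001", lesion_class="cyst")
lesion = vol.lesions[0]
print(f"phantom {vol.patient_id}: shape {vol.image.shape}, spacing {vol.spacing_mm} mm")
print(f"implanted cyst: radius {lesion.radius_mm:.1f} mm, {lesion.voxel_count} voxels")

probs = np.moveaxis(np.eye(5)[vol.mask.astype(int)], -1, 0)
(roi,) = roi_pipeline(vol.image, probs, vol.patient_id)
print(f"ROI: class={roi.predicted_class}, bbox={roi.source_bbox}, "
      f"patch={roi.patch.shape}, S={roi.confidence_S:.3f}")

pred = DirichletPrediction(np.array([14.2, 1.0, 1.3, 1.1]))
print(f"evidential prediction: {pred.predicted_class}, "
      f"p={np.round(pred.expected_probs, 3)}, uncertainty u={pred.uncertainty_u:.3f}")
```

prints

```
train/val/test patients: 2693/577/577
phantom demo-001: shape (64, 64, 16), spacing (1.0, 1.0, 2.5) mm
implanted cyst: radius 7.0 mm, 584 voxels
ROI: class=cyst, bbox=(13, 20, 4, 33, 40, 12), patch=(96, 96, 32), S=1.000
evidential prediction: normal, p=[0.807 0.057 0.074 0.062], uncertainty u=0.227
```

The split reproduces the 70/15/15 patient-level partition of a
3847-patient cohort; the phantom carries a hypodense 7 mm cyst whose 584
voxels the ROI pipeline recovers as a single standardized patch with full
segmentation confidence; the final lines show how Dirichlet
concentrations translate into class probabilities and a scalar
uncertainty (here, strong evidence for "normal" with u ≈ 0.23).

A command-line interface mirrors the pipeline stages:

```bash
diagnext generate --n 120 --seed 42 --out data/
diagnext train-seg --data data/ --out ckpt/seg.npz
diagnext extract-roi --data data/ --out rois/
diagnext train-cls --rois rois/ --out ckpt/cls.npz
diagnext infer --data data/ --seg-ckpt ckpt/seg.npz --cls-ckpt ckpt/cls.npz --out preds.json
diagnext evaluate --data data/ --predictions preds.json --out report.json
```

## Layout

- `diagnext.phantom` — synthetic CT kidney phantoms with ground truth
- `diagnext.preprocess` — windowing, resampling, normalization, padding
- `diagnext.segnet` / `diagnext.seg_losses` — segmentation network and loss
- `diagnext.roi` — confidence scoring and ROI extraction
- `diagnext.clsnet` / `diagnext.cls_losses` — evidential classifier and loss
- `diagnext.train` / `diagnext.experiments` — training loops, cascade, studies
- `diagnext.metrics` — Dice, HD95, boundary IoU, classification reports
- `diagnext.nn` — the numpy autodiff engine and 3D layers
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
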