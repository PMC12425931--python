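# mdwcnet

Segmentation of the spinal column in frontal X-ray radiographs with
**MDWC-Net**, a lightweight multi-scale dynamic-weighting context network —
implemented end to end on NumPy (hand-derived backward passes, numba-JITed
inner loops), with a seeded synthetic spine-phantom generator so the whole
pipeline trains, evaluates and reproduces with no external data.

Intended users: researchers in medical image analysis who want a compact,
fully inspectable reference implementation of this architecture family —
every gradient is written out and checked against finite differences — and
a ready-made harness for ablating its blocks.

## The model

MDWC-Net is a five-level U-Net-shaped encoder-decoder for two-class
pixel labelling with three bespoke blocks:

* **MSCAW** — each level block splits into four parallel
  depthwise-separable convolutions (kernels 1×1, 3×3, 5×5, 7×7), each
  followed by BN, ReLU and a learnable per-channel scaling δ (initialised
  at 1, trained by SGD), concatenated:
  `F_out = Concat(δ(ReLU(BN(k_i * X))), i = 1..4)`.
* **DFCB** — skip fusion that gates both the encoder map (C channels,
  reduced C→C/2) and the reduced decoder map (2C→C/2) by a channel softmax
  of the decoder map, then concatenates the two gated halves back to C.
* **BIEB** — bottleneck enhancement: channel attention
  `ζ = σ(γ(P_avg(F)) + γ(P_max(F)))` with a shared two-layer perceptron γ,
  summed with a residual double-convolution branch carrying adaptive
  weighting.

Training recipe: pixel cross-entropy, SGD (momentum 0.9), batch 8, lr
1e-3 ÷ 10 every 20 epochs, random horizontal flips, best-validation-Dice
checkpointing. Metrics: global pixel accuracy, Dice, mean IoU and
sensitivity, reported per dataset as mean ± sample std in percent, plus a
paired t-test for model comparison. See `docs/methods.md` for every
design choice and numerical convention.

## Worked example

Generate 96 phantoms at 96×96 (64 train / 16 val / 16 test), train the
default network for 20 epochs, and evaluate the held-out split:

```sh
mdwcnet generate --n 96 --image-size 96 --seed 11 --out ds
mdwcnet train --data ds --out run --seed 1 --epochs 20
mdwcnet evaluate --checkpoint run/checkpoint.npz --data ds --split test --out report
```

Training logs one line per epoch (learning rate, train/val cross-entropy,
validation Dice); the last epochs of the run above:

```
epoch 19/20 lr 1.00e-03 train 0.0920 val 0.0915 dice 0.9666 (28.5s)
epoch 20/20 lr 1.00e-03 train 0.0871 val 0.0865 dice 0.9686 (25.6s)
```

and the evaluation report on the 16 held-out phantoms:

```
gpa          99.31 ± 0.096
dice         97.00 ± 0.387
miou         96.70 ± 0.417
sensitivity  97.48 ± 1.382
```

i.e. 99.3% of pixels are labelled correctly, the predicted and true
vertebral columns overlap with Dice 97%, and 97.5% of true foreground
pixels are recovered; the ± figures are the spread across test images.
An untrained network scores Dice ≈ 0.21 on the same split, so essentially
all of this is learned signal.

Parameter accounting and the ablation variants:

```sh
$ mdwcnet params
3990934 (3.99M)

$ mdwcnet ablate
baseline_unet            28,946,626  (28.95M)
multiscale_conv_only      2,337,046  (2.34M)
mscaw_only                2,339,990  (2.34M)
mscaw_bieb_upper          2,472,150  (2.47M)
mscaw_bieb_lower          4,460,694  (4.46M)
mscaw_bieb_full           4,592,854  (4.59M)
mscaw_dfcb                1,738,070  (1.74M)
full                      3,990,934  (3.99M)
with_aspp                10,093,890  (10.09M)
with_cbam                 1,870,329  (1.87M)
```

The full network is ~7× lighter than the U-Net baseline under identical
counting conventions. `docs/methods.md` discusses how this count relates
to the published figure for the architecture.

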