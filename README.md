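# acns — in-plane MRI super-resolution with a compact deconvolutional network

`acns` estimates a high-resolution (HR) 2-D MRI slice from a low-resolution
(LR) one by a small convolutional network that ends in a transposed
("deconvolution") layer, so the upscaling itself is learned rather than
interpolated.  It is aimed at MRI-guided radiotherapy imaging, where cine and
4-D acquisitions trade in-plane resolution for temporal resolution and any
resolution recovery must be cheap enough to run in near real time.  Because
volunteer MRI and licensed digital-phantom data cannot be redistributed, the
package ships a synthetic moving torso phantom so that every stage — training,
inference, evaluation — runs from scratch with no downloads.

## The model

The LR observation is modelled as anti-aliased bicubic decimation of the HR
image,

    Y = D_f X,

with scale factor `f ∈ {2,3,4}`.  The network `F(Y; f, Θ)` has three parts:

1. **Feature extraction** — one `w1 × w1` convolution to `N_feature` channels,
   followed by a per-channel PReLU, `max(0,z) + α·min(0,z)`.
2. **Nonlinear mapping** — `n` recursions of 3×3 convolutions (1-pixel zero
   padding, stride 1) at a reduced width `N_map`, each with PReLU, then one
   3×3 "expansion" back to `N_feature` channels.  The narrow middle is the
   autoencoder-style bottleneck that keeps the parameter count small.
3. **Reconstruction** — a single transposed convolution with kernel `w_out`,
   stride `f` and crop `p` per side, whose output size obeys
   `f·(in − 1) + w_out − 2p`.

A network is written `ACNS(N_feature, N_map, w1, w_out, p, n)`; the selected
configuration is `ACNS(16,8,5,9,5,4)`, which has 5,728 kernel weights —
against 8,032 for SRCNN, 12,464 for FSRCNN and 1,774,080 for DRCN, the three
standard comparators whose weight plans the package also builds.

A candidate `(w1, w_out, p)` is admissible for a given LR training-patch size
only if four geometric conditions hold (kernel fits the patch, the
reconstruction output lands between the LR and `f×` LR patch sizes, …);
`validate_spec` evaluates them and `enumerate_valid_specs` enumerates the
admissible triples.

Training minimizes `L(Θ) = (1/2N) Σ ||F(Y_i) − X_i||²` over aligned 11×11 LR /
`f·(11−w1)+w_out−2p` HR patch pairs with momentum SGD
(`Δ ← 0.9Δ − η·∇L`, `η = 10⁻³`, `10⁻⁴` for the reconstruction stage), Xavier
initialization, and hand-written backprop — verified against central finite
differences.  Quality is reported as PSNR, SSIM (Gaussian 11×11 window,
`K1 = 0.1`, `K2 = 0.3`) and the information fidelity criterion (IFC) computed
from a Gaussian-scale-mixture model of steerable-pyramid-style subbands.

## Worked example

```sh
acns validate --spec "ACNS(16,8,5,9,5,4)" --scale 2 --patch 11
```

prints the four design conditions with their numbers and the implied HR patch
size:

```
Condition1: PASS  (w1=5 < lr_patch=11)
Condition2: PASS  (2p=10 < f*(lr_patch-w1)=12)
Condition3: PASS  (p=5 < w_out=9)
Condition4: PASS  (11 <= f*(lr_patch-w1)+w_out-2p=11 <= 23)
overall: PASS
implied HR patch size: 11
```

so an 11-pixel LR patch maps to an 11-pixel HR target at `f = 2` (17 at
`f = 3`, 23 at `f = 4`).  A miniature end-to-end run:

```sh
acns simulate --n 60 --size 200 --seed 1 --out data/train
acns train --spec "ACNS(16,8,5,9,5,4)" --scale 2 --data data/train \
           --iters 50000 --seed 1 --out model.npz
acns simulate --n 10 --size 200 --seed 1 --role test --out data/test
acns degrade --scale 2 --in data/test/phantom_test_0000.png --out lr.png
acns enhance --ckpt model.npz --in lr.png --out sr.png
acns evaluate --truth data/test --test data/sr \
              --baseline bicubic,nearest --scale 2 --out report.csv
```

`evaluate` writes per-image PSNR (dB), SSIM and IFC columns for the network
and each baseline and prints the means; trained this way the network exceeds
the bicubic baseline by more than 0.5 dB mean PSNR on held-out phantom slices
(the acceptance suite asserts exactly this property).

```sh
acns count-params --ref SRCNN     # prints the plan and "total kernel weights: 8032"
```

## Layout

```
src/acns/architecture.py  network spec, validity conditions, plans, forward pass
src/acns/observation.py   bicubic degradation model and baseline upsamplers
src/acns/patches.py       aligned LR/HR training patch extraction
src/acns/training.py      MSE loss, momentum SGD, Xavier init, backprop loop
src/acns/metrics.py       PSNR, SSIM, IFC
src/acns/phantom.py       synthetic moving torso phantom
src/acns/io.py            PNG/NIfTI input, checkpoint archive
src/acns/cli.py           the `acns` command
docs/methods.md           modelling choices, defaults and limitations
```
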