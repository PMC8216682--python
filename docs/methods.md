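# Methods

This note records the modelling assumptions, the defaults and why they were
chosen, and what the synthetic data can and cannot show.  Nothing here states
an empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## Observation model

The LR image is modelled as anti-aliased bicubic decimation of the HR image.
The bicubic kernel is the 4-tap Keys kernel with `a = −0.5`; on downscale the
kernel support is stretched by the scale factor (anti-aliasing) and boundary
taps are clamped with weights renormalized to sum to one, so constants are
reproduced exactly.  This is the convention of the common imaging-toolbox
`imresize`, and the package's implementation is cross-checked in the tests
against Pillow's anti-aliased bicubic resize (agreement well under one 8-bit
level on smooth images).  Whether to anti-alias is a genuine open choice for
a bicubic observation model; it is adopted here because the documented
closeness of bicubic decimation to "3×3 mean blur + nearest decimation" —
which the test suite verifies at a 3-of-255-levels mean tolerance — only
holds for the anti-aliased form.  Degraded images are kept in float64;
quantization to the declared bit depth happens only on PNG export
(round-half-away-from-zero).  Images whose sides are not divisible by the
scale factor are centre-cropped to the nearest multiple before degradation.

## Network and geometry

Stages: `w1×w1` feature extraction (no padding) → `n` 3×3 mapping recursions
(padding 1, width `N_map`) → 3×3 expansion back to `N_feature` → transposed
convolution (kernel `w_out`, stride `f`, crop `p` per side).  All stages but
the last carry a per-channel PReLU with trainable slope, initialized at 0.25;
per-channel (rather than a single scalar) slopes follow the original PReLU
formulation.  The expansion stage is written with the same 3×3/padding-1
geometry as the mapping recursions and trains at the main learning rate; only
the transposed convolution is treated as "the reconstruction layer" with its
own, smaller rate.

Transposed-convolution semantics are fixed by the output-size rule
`f·(in − 1) + w_out − 2p`: zero-interleaved scatter of the input against the
kernel followed by a symmetric crop of `p` pixels per side.  The four
admissibility conditions on `(w1, w_out, p)` for an LR patch size `s` are

1. `w1 < s`
2. `2p < f·(s − w1)`
3. `p < w_out`
4. `s ≤ f·(s − w1) + w_out − 2p ≤ f·s + (s mod 2)`

and on success the HR patch size is `f·(s − w1) + w_out − 2p`.  With the
candidate sets `w1 ∈ {1,3,5,7,9}`, odd `w_out ≤ 21`, `p ≤ 9` at `s = 11`,
`f = 2`, the package enumerates 166 admissible triples (lexicographically
ordered for reproducibility); the count is reported, not asserted, since it
is sensitive to boundary conventions in condition 4.

Weight counts use kernel weights only (biases and PReLU slopes excluded) —
the only convention under which the selected network counts 5,728 and the
comparator plans count 8,032 / 12,464 / 1,774,080.  The comparator layer
shapes are fixed in `reference_plan`; DRCN's recursive stage unrolls at run
time but its shared kernel enters the count once.  These comparators exist
for complexity analysis only and are never trained here.

Whole-image inference ("full-size" border mode) replicate-pads the input by
`(w1−1)/2` so feature extraction preserves size, then centre-crops or
edge-pads the reconstruction output to exactly `f·S`.  The alternative
"valid" mode applies no padding and returns the natural output size; on an
11-pixel input it produces exactly the 11/17/23 HR patch sizes.

## Patch pairs

LR patches (11×11, stride 4) are tiled over the degraded image — degrading
the whole image rather than each patch avoids border inconsistencies — and
the patch count per axis is `floor((size − patch)/stride) + 1` (the standard
sliding-window rule; 196 patches on a 64×64 LR image).  Each HR target is
the centre crop of the implied HR-patch size from the `f·11` region at the
scaled LR origin; centre alignment is chosen because the valid-mode network
has a symmetric receptive field, and it is what makes the interior of a
re-degraded HR region match the LR patch in the tests.

## Training

Loss `(1/2N) Σ ||F(Y_i) − X_i||²`; momentum SGD `Δ ← 0.9Δ − η g`, `W ← W + Δ`
with `η = 10⁻³` for all stages except the reconstruction stage's `10⁻⁴`;
PReLU slopes train at the main rate.  No learning-rate decay and no weight
decay.  Xavier initialization in its uniform fan-in form,
`U(±sqrt(3/fan_in))` with `fan_in = in_channels·k²`, biases zero — at this
depth (seven weight-bearing stages) the PReLU-specific initialization caveat
for very deep networks does not apply.  Mini-batches of 64 patches are drawn
with replacement; the batch at iteration `t` is derived from `(seed, t)`, so
a run checkpointed at any iteration resumes with a bit-identical loss trace
(the checkpoint stores parameters, optimizer velocities and the iteration).

Patch intensities are divided by MAX inside the training loop: with raw
0–255 values the per-patch squared-error gradients are ~10⁴ larger and the
default learning rate diverges immediately.  The inference wrapper
(`upscale`) applies the same normalization and clips the output to
`[0, MAX]`.

Gradients are hand-written backprop through the conv / PReLU /
transposed-conv stages; the contract is the finite-difference test (central
differences over every parameter of a <200-weight network, ≤10⁻⁴ relative
error per array), which the suite runs in float64.  The update loop itself
defaults to float32 working precision — on the 5,728-weight network the loop
is memory-bound and float32 roughly halves the time per iteration; float64
is available via `TrainingConfig(dtype="float64")`.  Runs are deterministic
in either precision.

## Metrics

PSNR is `10·log10(MAX²/MSE)` (identical pairs report +inf).  SSIM uses the
standard Gaussian 11×11, σ = 1.5 sliding window with `C1 = (K1·MAX)²`,
`C2 = (K2·MAX)²`; the defaults `K1 = 0.1`, `K2 = 0.3` reproduce the
evaluation convention this package follows, and images smaller than the
window fall back to a single global window.  The windowed computation is
delegated to scikit-image.

IFC: both images are decomposed by a Fourier-domain steerable-pyramid-style
tight frame — radial raised-cosine annuli between cutoffs `π/2^(s−1)` and
`π/2^s` for scales `s = 1..4`, times angular windows `|cos(θ − πk/K)|^(K−1)`
for `K = 6` orientations; the high/low-pass residuals and the coarsest scale
are excluded.  Per subband the reference coefficients follow a Gaussian
scale mixture `C = s·U` with `s²` estimated as the local 3×3 variance, and
the distortion channel `D = gC + V` is fit per non-overlapping 3×3 block by
least squares (`g = cov/var`, `σ_v² = var_D − g·cov`, floored at
`ε = 10⁻¹⁰·MAX²`).  The score sums `0.5·log2(1 + g²s²/σ_v²)` over blocks and
subbands.  This reproduces the defining properties — self-fidelity bound,
invariance to a positive gain on the test image, strict decrease with noise —
but absolute values are not comparable across different subband
configurations, so only relative comparisons are meaningful.

## Synthetic phantom

The generator emulates a thoracic cine: an elliptical body, two lungs whose
diaphragm edge moves with the respiratory phase (amplitude 4% of the frame,
top edge pinned), a heart ellipse dilating ±5% with the cardiac phase, and
bright vessel segments, all anti-aliased, on an exactly-zero background —
the zero background is deliberate, since background preservation is one of
the published failure modes the metrics are sensitive to.  Default
intensities (tissue 120, lung 35, heart 170, vessels 220 of 255) are ordered
like a balanced-SSFP thoracic contrast.  Defaults: 200×200 pixels,
respiratory period 20 frames, cardiac period 7 frames, per-slice geometric
jitter of ±0.5% of the frame, optional Rician noise (off by default so the
training pairs follow the bicubic observation model exactly).  Train and
test datasets draw from disjoint seed streams.

What this does *not* emulate: MRI physics (k-space truncation, bias fields,
distortion), anatomical texture, through-plane structure.  Passing the
end-to-end test therefore shows that the pipeline learns to invert the
stated degradation on images with edges, smooth regions and a zero
background — not that it reaches any particular quality on clinical MRI.

## Problem sizes in the acceptance suite

The architecture and metric identities are exact and instantaneous.  The
end-to-end property uses the package's stated study conditions — 150
training slices at 200×200, scale factor 2, 50,000 iterations of batch 64 —
and checks a ≥0.5 dB mean PSNR gain over bicubic upsampling on 20 held-out
slices, plus finiteness and a decreasing trend of the loss trace.  The
published clinical-data tables are not reproducible without the original
volunteer MRI and licensed phantom data, which is why the acceptance
property is defined on the synthetic phantom instead.

## Known limitations

- The degradation is fixed to bicubic decimation; no noise or blur mismatch
  between train and test is modelled (beyond optional Rician noise in the
  generator).
- The IFC subband configuration is a package choice; published IFC numbers
  computed with the original steerable-pyramid code are not directly
  comparable.
- Only integer scale factors are supported, applied identically to both axes.
- NIfTI support is read-side (slice extraction with recorded min-max
  rescale); outputs are written as 8-bit PNG.
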