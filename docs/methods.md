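# Methods

## PCNN impulse filtering

Each pixel (i, j) is a spiking unit with stimulus S = the gray value.
Per iteration n (1-based), with the 3×3 coupling kernel m (weights
1/distance, center 0) applied to the previous firing map Y[n−1] under
edge replication:

    F[n] = e^(−α_F)·F[n−1] + V_F·(m ∗ Y[n−1]) + S
    L[n] = e^(−α_L)·L[n−1] + V_L·(m ∗ Y[n−1])
    U[n] = F[n]·(1 + β·L[n])
    E[n] = e^(−α_E)·E[n−1] + V_E·Y[n−1]
    Y[n] = 1  iff  U[n] > E[n]      (strict; ties do not fire)

Initial state F = L = Y = 0.  The threshold decays once before the first
comparison, so at iteration 1 exactly the pixels above e^(−α_E)·E₀ fire.
Defaults: β = 0.5, V_E = 2.0, α_E = 0.3 (the constants that govern the
filter); α_F = 0.1, V_F = 0.5, α_L = 1.0, V_L = 0.2 (conventional values
— the dynamics are insensitive to them for ranking bright pixels),
n_iter = 30.  A `stimulus_only` feedback mode (F = S, no accumulation) is
selectable; the full recurrence is the default.  PCNN arithmetic is
float64; images are uint8 throughout.

**Threshold initialization.** `pcnn_iterate` starts E at the stimulus
maximum — the contract used by the firing-order analyses and oracles.
The *denoising pipeline* instead starts E at the grayscale ceiling 255
(`threshold_init="range_max"`).  With an image-relative start, removing
the salt lowers the next pass's detection band and a second pass begins
flagging bright anatomy; with the fixed ceiling the detection band is
stable, repeated application is essentially idempotent (a second pass
changes at most a couple of pixels), and a clean image passes through
unchanged unless it contains near-saturated isolated points.

**Detection and repair.**  Bright-impulse candidates are the pixels whose
first firing falls within the first `window` iterations (default 1).  An
optional `isolated` criterion restricts flags to early firers with ≤ 2
early-firing 8-neighbours — impulses fire ahead of their surroundings,
structure fires together — but the default pipeline does not use it,
because on the inverted (pepper) pass the background itself fires early
and would mask the impulses.  Repair replaces *only flagged pixels* by the
3×3 grayscale opening (erosion then dilation, edge-replicated); opening
removes maxima smaller than the element, so solid structure ≥ 3×3
survives even when flagged.  Dark impulses are handled by running the
same bright pass on 255 − I and inverting back.

PSNR = 10·log₁₀(255²/MSE) in dB; identical images report infinity rather
than a numeric overflow.  The comparison baseline is a k×k median filter
(edge-replicated, k odd ≥ 3).

## Phantom model

Real liver CT/MRI is modelled as three piecewise-constant tissue classes
— background 40, liver 160, tumor 210 gray levels (pairwise contrast
≥ 20 enforced) — with the liver an ellipse of semi-axes (0.35, 0.27) of
the frame, the tumor a disk sampled to lie strictly inside it, and
band-limited Gaussian texture (σ = 6 gray levels, spatial scale size/32)
inside the organ.  Tumor radii default to size/32…size/12 pixels, the
scale of small hepatic lesions on a 512-pixel slice.  Degradations:
salt-and-pepper at a given density (exactly round(density·N) pixels set)
and/or additive Gaussian noise.  One integer seed drives a dedicated
generator stream; no global state is touched.

What the phantoms do **not** model: anatomy other than one organ + one
lesion, partial-volume effects, scanner-specific noise spectra, contrast
phases, inter-slice context.  Passing tests demonstrate that the
algorithms are implemented correctly and learnable signal is recovered;
they say nothing about clinical segmentation accuracy.

## SE-ResUnet

Stage widths 32·2^k (k = 0…3 at the default depth 4).  Each stage is an
SE-residual block

    Y = body(SE(X)) + shortcut(X) + attn(SE(X))

* SE gate: global average pool → FC C→C/r → ReLU → FC C/r→C → sigmoid,
  r = 8 (clipped to the channel count at the 3-channel input block);
  weights in (0, 1), output shape equals input shape.
* body: conv3×3–BN–ReLU–conv3×3–BN (basic) or 1×1/3×3/1×1 bottleneck
  with reduction 4; shortcut: identity, or 1×1 conv + BN when widths
  change; attn: an additive 1×1 conv + BN branch on the gated input.
* `se_heads` (default 1) builds parallel SE branches whose recalibrated
  outputs are averaged before the body — the closest channel-attention
  analogue of a "number of attention heads" parameter; the depth of such
  a mechanism has no referent in an SE gate and is not exposed.
* The block output is the raw sum — no post-sum normalization or
  activation — so zeroing every branch parameter leaves an exact identity
  on same-width features, and forcing all SE gates to 1 (or building with
  `se_enabled=False`) yields a plain Res-Unet bit-exactly.  Branch-level
  BN keeps stacked raw sums O(1), which keeps the sigmoid head out of
  saturation at initialization.

Encoder: block then 2×2 max pool, four times.  Decoder: bilinear 2×
upsampling (exact separable linear operator), channel concatenation with
the matching encoder feature (addition selectable), then a block, four
times.  Head: 1×1 conv + sigmoid.  Inputs must be divisible by 2^depth.
Initialization is He-uniform from a single seeded generator, so build is
bit-reproducible.  All tensor math is float32 on a hand-written numpy
reverse-mode autodiff engine (`hepaseg.nn`) whose gradients are verified
against central finite differences; single-threaded execution makes
training trajectories bit-reproducible.

## Training and evaluation

Reference regime: 100 epochs, Adam with decoupled weight decay
(lr 1e-4, decay 1e-4), gradient accumulation over 5 mini-batches per
update (each mini-batch loss is scaled by 1/5 so the applied update is
the window mean; a trailing partial window is never flushed early), a
checkpoint every 5 epochs (floor(epochs/interval) files), batch size 4,
soft Dice loss (optionally + BCE).  History records per-epoch mean loss,
validation Dice and pixel accuracy.  Checkpoints are single .npz archives
holding weights plus the JSON-encoded model config.

After the last update the batch-norm running statistics are recalibrated:
one pass over the training set with cumulative-average momentum replaces
the exponential estimates — which lag the rapidly moving weights on short
runs — with the exact mean batch statistics under the final weights, so
eval-mode inference matches what the network learned.

Metrics operate on binary masks at threshold 0.5 (configurable):
Dice, per-image foreground IoU (dataset value = mean over images),
precision, recall; ROC/AUC pools all pixels and sweeps every distinct
probability (trapezoid area, which equals the normalized Mann–Whitney
statistic).  Degenerate conventions, warned not raised: both masks empty
→ Dice 1 / IoU 1; no predicted (reference) positives → precision
(recall) 0.

**Fixture scale.**  Demonstration and test training runs use 64×64
phantoms, batch 4, lr 1e-3 without accumulation: the default-width
network then overfits the 8-phantom fixture to training Dice ≥ 0.95
within 200 optimizer updates on a single CPU — the package's standing
check that the architecture, loss and optimizer actually learn.  Mid-run
validation Dice can dip while the running batch-norm statistics lag the
weights; the returned model, with recalibrated statistics, is stable.

## Preprocessing and I/O

Slices (PNG/TIFF) or axial NIfTI volumes are resized to 256×256
(bilinear; nearest-neighbour for masks so they stay binary) and
intensity-normalized per slice by percentile clip-and-rescale (1st–99th)
to [0, 255]; a constant slice maps to mid-gray 127.  Histogram
equalization is available by flag.  Network input replicates the gray
slice to 3 channels scaled to [0, 1].  Probability maps are written as
16-bit PNG (round(p·65535)) or NIfTI carrying the source affine; masks
as {0, 255} 8-bit PNG.

## Known limitations

* 2-D only; volumes are processed slice-wise.
* The numpy backend is CPU-bound: full-scale (256², width-64) training is
  out of reach; the package demonstrates correctness at fixture scale.
* The PCNN detection band at the default window is coarse (one threshold
  decay per iteration); impulses closer than ~26% to the local background
  intensity are not separable by firing order alone.
* The additive attention branch realizes the block's attention term as
  channel attention; no spatial/multi-head attention is implemented.
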