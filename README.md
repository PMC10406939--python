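# hepaseg

A toolkit for liver-tumor segmentation in 2-D CT/MRI slices, built around a
two-stage pipeline:

1. **PCNN adaptive impulse-noise filtering.** A pulse-coupled neural network
   (PCNN) assigns one laterally coupled spiking unit per pixel.  Each unit
   carries a feedback input *F*, linking input *L*, internal activity
   *U = F·(1 + βL)* and a dynamic threshold *E* that decays geometrically
   (factor e^(−α_E)) and jumps by *V_E* on firing.  Because the threshold
   starts high and decays, firing *order* encodes intensity: isolated bright
   impulses fire ahead of their surroundings.  Flagged pixels are repaired by
   grayscale morphological opening restricted to the flags; dark impulses are
   handled by an inversion pass.  Quality is benchmarked with
   PSNR = 10·log₁₀(255²/MSE) against a median-filter baseline.
2. **SE-ResUnet segmentation.** A 4-stage U-shaped encoder–decoder whose
   stages are residual blocks (y = f(x) + x; basic or 1×1/3×3/1×1 bottleneck)
   gated by squeeze-and-excitation (SE) channel attention, with 2×2 max
   pooling on the way down, bilinear 2× upsampling and skip fusion on the way
   up, and a 1×1 sigmoid head producing a per-pixel foreground probability.
   Training minimizes the soft Dice loss
   `1 − (2|X∩Y|) / (|X|+|Y|)` with gradient accumulation; evaluation reports
   Dice, mIoU = TP/(TP+FP+FN), precision, recall, and ROC-AUC.

Clinical data is not distributable, so the package ships a seeded
synthetic-phantom generator (bright elliptical "liver", interior "tumor"
blob, smooth texture, impulse/Gaussian noise) that drives all tests and
examples.

The network runs on a small numpy reverse-mode autodiff engine
(`hepaseg.nn`) — no GPU or deep-learning framework required; everything is
single-threaded and bit-reproducible under a fixed seed.

## Worked example

```python
import numpy as np
from hepaseg import (PhantomSpec, NoiseSpec, generate_phantom, add_noise,
                     denoise, median_baseline, psnr)

clean, tumor_mask = generate_phantom(PhantomSpec(), seed=7)   # 256x256 uint8
noisy = add_noise(clean, NoiseSpec(impulse_density=0.02, seed=7))

print(f"PSNR noisy    {psnr(clean, noisy):.2f} dB")
print(f"PSNR PCNN     {psnr(clean, denoise(noisy)):.2f} dB")
print(f"PSNR median-3 {psnr(clean, median_baseline(noisy, 3)):.2f} dB")
```

prints

```
PSNR noisy    21.77 dB
PSNR PCNN     48.84 dB
PSNR median-3 43.59 dB
```

— 2% salt-and-pepper corruption costs ~22 dB; the PCNN filter recovers the
image to within ~49 dB of the clean phantom, ahead of the 3×3 median
baseline, because it only touches flagged pixels instead of smoothing
everywhere.

Segmentation with the sklearn-style estimator:

```python
from hepaseg import SEResUNetSegmenter
from hepaseg.trainer import phantom_dataset

X, y = phantom_dataset(8, size=64, seed=1)   # (N,3,H,W) in [0,1], (N,H,W) masks
est = SEResUNetSegmenter(epochs=100, lr=1e-3, accumulation_steps=1,
                         batch_size=4, val_fraction=0.0, seed=1)
est.fit(X, y)
print(f"training Dice {est.score(X, y):.3f}")
masks = est.predict(X)                          # binary (N,H,W)
```

prints, after 200 optimizer updates on one CPU (a few minutes):

```
training Dice 0.981
```

A command-line interface covers the same pipeline end to end:

```bash
hepaseg make-phantoms --out data/ --count 8 --size 256 --seed 1 --noise-density 0.02
hepaseg denoise data/phantom_000.png --out out/clean.png --reference ref.png --compare-median 3
hepaseg train --data data/ --out run/ --seed 1
hepaseg predict run/final.npz data/phantom_000.png --out pred/
hepaseg evaluate pred/ data/ --out report.csv
```

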