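# patdiff

Sparse-view and limited-view photoacoustic tomography (PAT) at desk scale:
simulate circular-array acquisition, reconstruct with filtered
back-projection (FBP), and restore the degraded reconstructions with a
mean-reverting diffusion model whose noise estimator is a time-conditioned
channel-attention transformer.

## The problem

PAT reconstructs the optical-absorption-induced initial pressure `p0(r)`
from ultrasound recorded by transducers surrounding the tissue.  Full ring
arrays with many elements are expensive, and in vivo geometries often cover
only part of the circle.  With few elements (*sparse view*, n of 512 kept)
FBP images grow streak artifacts; with a partial arc (*limited view*,
angular coverage Ω < 2π) whole structures vanish.  This package implements
a restoration framework for such images and every piece needed to study it
end to end with synthetic data: phantom generation, an idealized
circular-mean forward projector for a 512-element, 40 mm ring sampled at
62.5 MHz, FBP with a third-order 0.5–10 MHz Butterworth window

&nbsp;&nbsp;&nbsp;&nbsp;`b(r_d, t) = 2 p_f − t ∂p_f/∂t`,&nbsp;&nbsp;
`p0(r_s) ∝ Σ_d b(r_d, |r_s − r_d|/v) / N`,

and quantitative evaluation (PSNR / RMSE / SSIM, central line profiles).

## The restoration model

Degradation is modelled as a mean-reverting SDE that diffuses the clean
image `x(0)` toward its degraded counterpart `μ`:

&nbsp;&nbsp;&nbsp;&nbsp;`dx = θ_t (μ − x) dt + σ_t dw`,&nbsp;&nbsp;
`σ_t²/θ_t = 2λ²`,

with closed-form Gaussian marginals
`m_t = μ + (x0 − μ) e^{−θ̄_t}`, `v_t = λ² (1 − e^{−2θ̄_t})` that converge to
`N(μ, λ²)`; defaults are T = 200 states and noise level λ = 50 on the
[0, 255] image scale.  A network `s_φ(x_t, μ, t)` is trained to predict the
injected standard-normal noise, giving the score `−ε̂/√v_t`, and restoration
integrates the time-reversed SDE from `x_T ~ N(μ, v_T)` back to the clean
image.  The estimator is a five-level encoder–decoder of transformer blocks
that compute attention *across channels* (C×C maps per head instead of
pixel-by-pixel maps) from time-modulated, depth-wise-separable Q/K/V
convolutions, followed by a gated convolutional feed-forward — parameters
grow as ≈12C² per block versus 44C² for full 3×3 convolutional projections
with a dense 4× feed-forward.  Training uses Adam (β₁ = 0.9, β₂ = 0.99),
lr 3e−5 with cosine decay, batch size 2.

The network and its training loop run on an in-repo reverse-mode autodiff
engine over numpy (no GPU or deep-learning framework required).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from patdiff import (RingGeometry, ReconGrid, PhantomSpec, generate_phantom,
                     simulate_signals, subsample_views, reconstruct, psnr)

phantom = generate_phantom(PhantomSpec(kind="disks", seed=3), (64, 64), 0.3)
geom = RingGeometry(n_elements=512)           # 40 mm ring, 62.5 MHz
grid = ReconGrid((64, 64), 19.2)

sino = simulate_signals(phantom, geom)        # 512 x 2228 traces
full = reconstruct(sino, grid)                # full-view FBP reference
sparse = reconstruct(subsample_views(sino, "sparse", 64), grid)

rng = full.pixels.max() - full.pixels.min()
print(round(psnr(full.pixels, sparse.pixels, data_range=rng), 2))
```

This prints `20.98`: the 64-element reconstruction sits ~21 dB from the
512-element reference — the streak-artifact gap the diffusion model is
trained to close.  A complete study (dataset build, training, restoration,
evaluation) is one call or one command:

```bash
patdiff generate-data --kind vessels --n 10 --size 64 --seed 0 --out phantoms/
patdiff simulate --in phantoms/phantom_0000.tiff --out full.h5
patdiff subsample --mode limited --param 1.5708 --in full.h5 --out quarter.h5
patdiff reconstruct --sino quarter.h5 --grid 64 --extent-mm 19.2 --out degraded.tiff
patdiff train --config examples/study.yaml --out runs/study1   # end-to-end + report
```

`runs/study1/report.json` then contains per-image and aggregate
PSNR/RMSE/SSIM for the degraded inputs and their restorations.

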