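# Methods

`patdiff` is a desk-scale toolkit for studying image restoration in
sparse-view and limited-view circular-array photoacoustic tomography (PAT).
It couples three components: an acoustic forward model and filtered
back-projection (FBP) that manufacture degraded/reference image pairs, a
mean-reverting stochastic differential equation (SDE) that models the
degradation as a diffusion toward the degraded image, and a time-conditioned
transformer that estimates the injected noise so the SDE can be integrated
backwards to restore the image.

## Acquisition model

A ring of ideal point detectors surrounds the object: by default 512
elements uniformly spaced on a circle of radius 40 mm, sampling at
62.5 MHz.  Sound speed defaults to 1500 m/s, the standard soft-tissue
value; the physical transducer's 5 MHz centre frequency and finite bandwidth
are represented only by the reconstruction band-pass filter, not in the
forward model.  Detectors are spaced by `coverage / n_elements` starting at
the ring's start angle, so a full ring has no duplicated endpoint.

The forward projector treats each detector trace as the time derivative of
the circular mean of the initial pressure over circles of radius `v*t`
centred at the detector.  Pixels are deposited linearly into the two time
bins bracketing their arrival, annulus sums are converted to circular means,
and a central finite difference forms the derivative.  The model is exactly
linear in the image and exactly covariant under the symmetries of the square
pixel grid (90° rotations, axis and diagonal reflections).  Two consequences
of projecting a *pixelated* image are worth noting:

* the raw traces carry sub-pixel binning roughness on top of the smooth
  circular-mean signal.  The reconstruction band-pass removes it, and it is
  exactly the pixel-scale spectral content that lets FBP recover pixelated
  structures (a perfectly band-limited smooth blob has almost all of its
  energy below the 0.5 MHz low cut and cannot survive any band-pass
  reconstruction);
* at detector angles that are not grid symmetries a small residual
  square-grid anisotropy remains at the pixel scale.  Integrated traces
  (the circular means) agree across detectors to a few percent.

Sparse-view subsets keep every `(n_elements/n)`-th element starting at
element 0; limited-view subsets keep the contiguous block of
`floor(n_elements * omega / coverage)` elements starting at the start
angle.  Neither choice is stated by the acquisition geometry itself; both
match the uniform/contiguous layouts the hardware study depicts.

## Filtered back-projection

Each trace is windowed with a zero-phase third-order Butterworth band-pass
(0.5–10 MHz by default; `order:low:high` configurable) applied as a
frequency-domain magnitude window, and combined with its ramp-filtered time
derivative into the back-projection term

    b(r_d, t) = 2 p_f(r_d, t) − w · t · ∂p_f/∂t ,

with `derivative_weight w = 1` by default.  The universal back-projection
literature uses `2p − 2t ∂p/∂t`; both are supported through
`derivative_weight=2`, and the default follows the plain `2p − t ∂p/∂t`
form.  Back-projection interpolates `b` linearly at the per-pixel arrival
time `|r_s − r_d|/v` and averages with uniform weights `1/N_active` over the
active detectors; an arrival outside the recorded window is an error, not a
clamp.  Reconstructions keep their signed values; mapping to the [0, 255]
dataset range happens only when training pairs are built, jointly normalized
by the full-view image's min/max so degradation-induced intensity loss
survives normalization.

## Degradation diffusion

Restoration is phrased as a mean-reverting (Ornstein–Uhlenbeck-type)
diffusion from the clean image `x(0)` toward the degraded image `mu`:

    dx = θ_t (μ − x) dt + σ_t dw ,     σ_t² / θ_t = 2λ²  for all t,

whose marginal is Gaussian with mean `m_t = μ + (x0 − μ) e^{−θ̄_t}` and
variance `v_t = λ² (1 − e^{−2θ̄_t})`, `θ̄_t = ∫₀ᵗ θ`.  Defaults: 200
discrete states on a unit time span, stationary noise level λ = 50 on the
[0, 255] intensity scale (this is why dataset images are normalized to
[0, 255]: at unit range a λ of 50 would be meaningless).

The rate shape θ_t is free.  The default is a **constant** rate scaled so
`exp(−2θ̄_T) = 1e−4` (terminal convergence of the marginal to N(μ, λ²)).
A cosine ramp is also provided, but it concentrates θ̄ late in the schedule
and leaves the first-state marginal std at ~0.2 intensity units; the noise
prediction target `ε = (x_t − m_t)/√v_t` is then numerically unlearnable at
small t, and in practice the constant shape both trains markedly better and
halves the analytic-score reverse-integration error.

Training minimizes the per-pixel squared error between the network output
and the standard-normal draw used in the reparameterized forward sample,
with the state index drawn uniformly from {1..T} per sample.

The reverse-time SDE is integrated with explicit Euler–Maruyama from
`x_T ~ N(μ, v_T)` down to 0, substituting the score `−ε̂/√v_t`; no noise is
added on the last step and the output is clipped to [0, 255] at the end
only.  A `stochastic=False` mode integrates the same drift without injected
noise (the mean path); with an imperfectly trained noise estimator the mean
path avoids re-injecting noise the estimator cannot fully remove, and the
end-to-end study below uses it for the final restoration.  A `score_fn` hook
accepts an analytic score for oracle studies.

## Noise-estimation network

The estimator is a five-level hierarchical encoder–decoder of time-driven
transformer blocks: shallow 3×3 embedding of the 2-channel input
(`x_t` and `μ` stacked, divided by 255), three encoder levels with
pixel-unshuffle down-sampling and channel doubling (C, 2C, 4C), a latent
level (8C), three decoder levels with pixel-shuffle up-sampling and skip
concatenation, and a refinement stage at full resolution (width 2C), then a
3×3 output projection to the single-channel noise estimate.  Odd input
sizes are zero-padded to a multiple of 8 and cropped on output.

Each block applies, with bias-free channel layer norm and residual sums:

* **TMTA** — time-modulated multi-head transposed attention.  A per-block
  two-layer perceptron maps the shared sinusoidal time embedding to
  channel-wise scale/shift pairs (γ, β) for Q, K and V; each branch is a
  1×1 channel-mixing convolution followed by a depth-wise 3×3 (implemented
  as one block-diagonal pointwise pass over the 3C stack plus one depth-wise
  pass — identical algebra, fewer kernel launches).  Attention is computed
  *across channels*: per head, a (C/h)×(C/h) map `softmax(K̄·Q̄/α)` with Q̄
  and K̄ L2-normalized along the pixel axis and a learnable per-head
  temperature α initialized to √(C/h); rows of the softmax are normalized,
  so each output channel's weights over input channels sum to one.  Cost is
  linear in pixel count.
* **GCFN** — gated convolutional feed-forward: two parallel pointwise +
  depth-wise branches (expansion 2.66) combined by a GELU gate, then
  projected back.

All convolutions are bias-free (zero in → zero out; clean transposed-
attention algebra).  Plain linear convolutions are initialized
variance-preserving (`std = 1/√fan_in`) and each block's output projection
is damped by 0.1 at init so the residual stream keeps unit scale in deep
stacks while every parameter still receives gradient.

Parameter accounting is closed-form and checked against the framework
counter: one TMTA unit at width C costs `3(C² + 9C)` for Q/K/V plus `C²`
for the output projection (plus the modulation perceptron and the per-head
temperatures); a GCFN at expansion r costs `3rC² + 18rC`.  Against a
matched-width block with four full (non-separable) 3×3 convolutional
projections and a 4×-expansion dense feed-forward (44C²), the separable
TMTA+GCFN block is strictly smaller for every practical width (≈12C²,
roughly a 73% reduction at large C).  Against a block with four dense 1×1
projections (12C²) the separable block is *not* smaller — the saving comes
from factorizing spatial mixing into depth-wise kernels, not from the
channel mixing itself — so no claim is made against that baseline.

The network runs in float32 by default (float64 available for verification);
the autodiff engine underneath is an in-repo reverse-mode tape over numpy
with exactly the primitives the architecture needs.

## Training recipe

Adam with β₁ = 0.9, β₂ = 0.99, initial learning rate 3e−5 decayed to zero
with a cosine schedule over the configured step budget, batch size 2.
Checkpoints are `.npz` parameter archives with a JSON manifest (config,
seed, step); logs are JSON lines.  Identical config and seed reproduce runs
bit-for-bit.

## Synthetic phantoms

Three seeded families stand in for biological absorbers: single point
sources, soft-count disk collections, and branching vessel trees grown by a
recursive random walk with decreasing width (always a single connected
component).  A master seed fans out to per-phantom child seeds by index.
Datasets are split 80/10/10 (train/validation/test) by seeded shuffle with
floor allocation and the remainder assigned to training.

What the generator does *not* emulate: anatomical texture and contrast of
real tissue, acoustic heterogeneity (e.g. bone), transducer impulse response
and directivity, electronic noise.  Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline and the learnability of
FBP artifact removal on synthetic structure — not clinical performance.

## Study sizes

The default end-to-end study is sized for a single CPU: 200 disk phantoms
on 32×32 grids (0.6 mm pixels) inside a 256-element ring, sparse retention
of 1/8 of the elements, diffusion with T = 100 states, the C = 16 /
one-block-per-level network (~0.5 M parameters), 2 500–6 000 optimizer
steps at the recipe above, and mean-path restoration of the 20 held-out
test images.  Larger studies (500×500 grids, 512 elements, T = 200,
C = 48, multi-block levels) are pure configuration.

## Numerical choices and edge cases

* Schedule arrays live on the uniform grid `t_i = i/T` of unit span;
  continuous-time values are linearly interpolated.
* `σ_t²/θ_t = 2λ²` holds exactly by construction at every state.
* FBP raises a descriptive error naming the offending pixel/detector when
  an arrival time exceeds the recorded window.
* Reverse sampling raises a divergence error naming the step if the state
  becomes non-finite.
* SSIM uses the canonical constants K1 = 0.01, K2 = 0.03, an 11-tap
  Gaussian window with σ = 1.5, and data range 255; PSNR uses data range
  255 and reports infinity for identical images.

## Known limitations

* The forward model is 2-D, lossless and homogeneous; no full-wave effects
  (reflection, refraction, dispersion, finite bandwidth).
* Grid anisotropy leaves a few-percent detector-to-detector variation in
  circular means at non-symmetric angles.
* With desk-scale training budgets the noise estimator's residual bias is
  amplified by the reverse integration (the drift integrates ~500× the mean
  score bias over a chain); restoration quality is therefore
  training-budget-bound well before it is architecture-bound.
* The stochastic sampler follows the printed reverse SDE; the mean-path
  variant is a pragmatic default for restoration at small budgets.
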