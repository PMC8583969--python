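# Methods

## Model

A fluorescence time series `w` (T frames of Ny x Nx pixels, K = T·Ny·Nx
samples) is modelled as a per-frame blur of the true series `v` by the
microscope's point spread function `H` plus noise.  The restored series is
the minimizer of

    E(v) = Σ_t ‖H v_t − w_t‖²
         + λ  Σ_{t,m} log( [v_t ∘ v_t + Σ_i (L_i v_t ∘ L_i v_t)]_m + ε )
         + λ_T Σ_σ   log( [v ∘ v + Σ_i (D_i v ∘ D_i v)]_σ + ε )
         + λ_N Σ_{v_σ<0} |v_σ|³ ,

where the `L_i` are the three spatial second-derivative filters within a
frame (∂²/∂x², ∂²/∂y², ∂²/∂x∂y) and the `D_i` the three temporal ones
(∂²/∂t², ∂²/∂x∂t, ∂²/∂y∂t).  The log ("entropy-like") penalties are nearly
flat for large arguments and steep near zero, so they tolerate sparse,
co-localized high intensities and high derivatives — the signature of
fluorescent spots — while pushing diffuse low-amplitude fluctuations toward
zero.  With λ_T = 0 the temporal term vanishes and the functional decouples
into independent per-frame problems: the static entropy-regularized method
(ER).  λ_T > 0 couples neighbouring frames (TD ER).

The non-negativity term is a smooth (C²) cubic penalty on negative
intensities, zero on the feasible set.  (A literal reading of the penalty as
`+λ_N Σ v_σ³` on negative entries would be unbounded below; the
magnitude-cubed form is the coercive interpretation consistent with its
purpose of suppressing negative pixels.)

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| λ (`lambda_spatial`) | spatial entropy weight | 0.1 | on the normalized intensity scale (see below); 0.05–2.0 are useful values depending on SNR |
| λ_T (`lambda_temporal`) | temporal entropy weight | 0.1 | 0 gives the static ER limit |
| λ_N (`lambda_nonneg`) | negativity penalty weight | 1.0 | order-1 on the normalized scale suffices; residual negatives are clipped at output only and the clipped fraction reported |
| ε (`epsilon`) | log guard | 1e-3 | strictly positive; sets the intensity scale below which the prior saturates |
| `max_iter`, `tol` | stopping | 100, 1e-6 | relative cost decrease |

Before solving, `w` is divided by its dynamic range so intensities are of
order one and the λ defaults transfer across bit depths; the physical zero
(no fluorescence) is deliberately *not* shifted, since it anchors both the
entropy prior and the non-negativity penalty.  The solution is scaled back
afterwards.

## Solver

All operators (PSF and the six derivative stencils) are stationary
convolutions under periodic boundaries, applied via FFT; adjoints are exact
(conjugate transfer functions).  Stencils are central second differences
[1, −2, 1] per axis and outer products of central first differences
[−½, 0, ½] for the mixed terms, at unit grid spacing.  The smooth cost is
minimized by Polak–Ribière+ nonlinear conjugate gradients with a
backtracking Armijo line search (the cost trace is therefore non-increasing
by construction), warm-started at v⁰ = w, with an optional (default on)
Fourier-domain Jacobi preconditioner |Ĥ|² + λ Σ|L̂_i|² + λ_T Σ|D̂_i|² plus a
small ridge.  The scheme is deterministic; the `seed` argument is recorded
for provenance and reserved for stochastic solver extensions.

Degenerate inputs: stacks with fewer than 3 frames cannot support the
3-tap temporal stencils; the temporal operators become zero operators, a
warning is emitted, and the solve proceeds on the static path.  An optional
mirror padding of the time axis (`time_pad`) suppresses temporal wrap-around
of the periodic boundary; the default is 0, since for the movie lengths used
here the wrap affects only the curvature estimate at the two end frames.

## Richardson–Lucy baseline

The classical multiplicative update v ← v ∘ Hᵀ(w / max(Hv, floor)), run
frame by frame for 10 iterations by default (the customary toolbox default;
no authoritative count exists for the comparisons this baseline stands in
for).  Division is guarded by a floor of 1e-12 of the dynamic range.  Under
the unit-sum kernel and periodic boundary the iteration preserves
non-negativity and per-frame total intensity.

## Synthetic benchmark generator

The generator emulates low-SNR Ca²⁺ spot imaging.  A Perlin
(lattice-gradient, 4 octaves, persistence 0.5) texture is thresholded at its
70% quantile to define a clustered placeable region; initial spot centers
are drawn from that region (the texture itself never appears in the output);
spots are isotropic Gaussian peaks (σ = 2 px, amplitude 1) that follow
independent 2-D Brownian paths (per-frame step σ = 0.5 px).  Degradation is
PSF blur (Gaussian, σ = 2 px, in lieu of a measured kernel), scaled Poisson
noise (divide by `p`, sample, multiply by `p`, preserving the dynamic
range), then additive Gaussian noise.

The spot count (30), amplitude, width and Brownian step are this package's
own defaults, chosen to give visibly clustered, slowly wandering spots at
realistic densities; they are not published constants.  Likewise the noise
grid is *this package's benchmark definition*: Gaussian variance at
{0.5, 1, 2, 4, 8}% of the squared dynamic range of the blurred ground truth
("low/medium/high" = 1%, 2%, 8%) crossed with Poisson levels
p ∈ {0.05, 0.1, 0.2} × peak intensity.

What the generator does *not* emulate: photobleaching, spot blinking or
appearance/disappearance, camera offset/gain, fixed-pattern (sCMOS) noise,
sample drift, or out-of-focus structure.  Passing benchmarks therefore
demonstrate correct behaviour of the algorithms under the stated forward
model, not performance on any particular instrument's data.

## Evaluation metrics

SSIM uses a 7×7 uniform sliding window, population moments, border windows
discarded, and constants c1 = (0.01 L)², c2 = (0.03 L)² with L the dynamic
range of the clean reference (window size and weighting are this package's
documented convention).  The normalized SSIM divides the frame-averaged
SSIM of restored-vs-clean by that of noisy-vs-clean; values above one mean
improvement.  Note the normalized SSIM is extremely sensitive to the noise
level through its denominator: on mostly-dark spot scenes at strong noise
the noisy-vs-clean SSIM collapses toward zero and the ratio grows well
beyond the 2–3 range seen at moderate noise, so absolute values are only
comparable between identical noise definitions and SSIM conventions.

Background noise variance is estimated without a reference: the frame is
filtered with the 3×3 second-difference stencil [[1,−2,1],[−2,4,−2],[1,−2,1]]
(noise variance gain 36, annihilates constants and linear ramps), tiled into
8×8 patches, patches ranked by the texture energy of their upper halves, and
the variance read off the lower halves of the weakest 50% of patches by a
median-absolute-deviation estimate with the gain divided out.  Ranking and
estimation use disjoint pixel rows, so selecting quiet patches does not bias
the estimate downward.  The estimator is validated by recovery of known
injected variances and by linearity across a variance grid rather than by
equivalence to any particular published variant.

Method comparisons use paired one-sided Wilcoxon signed-rank tests over
per-scene scores (averaged over Poisson levels) with Bonferroni correction
over the tested pairs.  The signed-rank statistic is invariant under
positive affine transforms of the scores applied to all methods, but not
under general monotone transforms (which reorder the magnitude ranks of the
paired differences).

## Benchmark problem sizes

The shipped benchmark sweeps 10 random scenes of 128×128 pixels and 20
frames at the highest Gaussian noise level crossed with the three Poisson
levels, with `max_iter` = 100 and `tol` = 1e-5 for both entropy methods —
sizes at which the full sweep completes in minutes on one CPU while leaving
the qualitative comparisons unchanged.

## Known limitations

- The quadratic data-fidelity term is statistically mismatched to pure shot
  noise; a Poisson-specific fidelity would need a different scheme and is
  out of scope.
- Only 2-D frames (no z-stacks), a known shift-invariant PSF (no blind
  deconvolution), periodic boundaries.
- At strong regularization relative to noise the entropy methods flatten the
  background essentially to machine zero, so background-variance differences
  between ER and TD ER can fall below the noise-estimator's resolution.
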