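# tdeconv

Entropy-regularized variational restoration of low-SNR fluorescence
microscopy **time series**, for researchers analyzing fast, dim signals such
as Ca²⁺ microdomains and waves in live-cell imaging, where short exposures
force a poor signal-to-noise ratio.

Most deconvolution methods treat each frame independently.  `tdeconv`
restores the whole movie at once by minimizing

    E(v) = Σ_t ‖H v_t − w_t‖²
         + λ  Σ_{t,m} log( [v_t∘v_t + Σ_i (L_i v_t ∘ L_i v_t)]_m + ε )
         + λ_T Σ_σ  log( [v∘v + Σ_i (D_i v ∘ D_i v)]_σ + ε )
         + λ_N Σ_{v_σ<0} |v_σ|³

over the full space-time stack `v`: a quadratic fidelity to the measured
movie `w` under the point-spread-function blur `H`, entropy-like penalties
on intensities and second derivatives in space (the `L_i`) and in time (the
`D_i`), and a smooth non-negativity penalty.  The log penalties tolerate
sparse, co-localized bright structure while suppressing diffuse noise —
tailored to the statistics of fluorescence images.  Setting λ_T = 0 recovers
static per-frame entropy-regularized deconvolution (**ER**); λ_T > 0 adds
temporal consistency (**TD ER**).  A frame-by-frame Richardson–Lucy baseline
(**LR**), a synthetic spot-movie benchmark generator, and evaluation metrics
(SSIM, normalized SSIM, reference-free background-noise estimation, paired
Wilcoxon method comparison) are included.  See `docs/methods.md` for the
full model description and design choices.

## Worked example

```python
import numpy as np
from tdeconv import (SimulationConfig, NoiseModel, RestorationParams,
                     generate_clean_series, degrade, make_gaussian_psf,
                     solve, mean_normalized_ssim)
from tdeconv.operators import apply_psf

psf = make_gaussian_psf(sigma=1.5)
clean = generate_clean_series(SimulationConfig(canvas=(64, 64), frames=8, seed=3))
blurred = apply_psf(clean, psf)
noisy = degrade(clean, psf, NoiseModel(
    poisson_level=0.1 * blurred.data.max(),
    gaussian_variance=0.02 * blurred.dynamic_range() ** 2,   # medium noise
    seed=5))

result = solve(noisy, psf, RestorationParams(lambda_spatial=0.1,
                                             lambda_temporal=0.1,
                                             epsilon=1e-3, max_iter=50))
print("iterations:", result.n_iter, "converged:", result.converged)
print("normalized SSIM:", round(mean_normalized_ssim(result.vopt, noisy, clean), 2))
```

Output:

```
iterations: 48 converged: True
normalized SSIM: 3.27
```

The cost trace (`result.trace`) is non-increasing by construction; the
normalized SSIM of 3.27 means the restored movie is 3.27× closer to the
ground truth — in frame-averaged structural similarity — than the noisy
input was (1.0 would mean no improvement).

## Command line

```sh
tdeconv simulate --canvas 128 128 --frames 20 --gauss-var 0.02 \
        --poisson-level 0.1 --seed 3 --out-clean clean.tif --out-noisy noisy.tif
tdeconv deconvolve noisy.tif restored.tif --method tder --psf-sigma 2 \
        --lambda 0.1 --lambda-t 0.1 --epsilon 0.001
tdeconv evaluate --clean clean.tif --noisy noisy.tif \
        --restored tder restored.tif --out report.tsv
```

Input and output movies are multi-page grayscale TIFFs (float32 on output).
Every run writes a JSON provenance record (parameters, seeds, version) next
to its outputs.  `--method er` forces λ_T = 0; `--method lr` selects the
Richardson–Lucy baseline.

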