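"""Synthetic benchmark movies of diffusing fluorescent spots.

The generator emulates low-SNR Ca2+ spot imaging: small Gaussian intensity
peaks ("glowing" spots) are placed in a clustered manner on a black canvas —
clustering is obtained by sampling initial positions only where a Perlin
(lattice-gradient) noise texture exceeds a quantile threshold, after which
the texture is discarded — and the spots then move over the frames along
independent 2-D Brownian paths.  Degradation applies the imaging forward
model: PSF blur, scaled Poisson noise (signal divided by a level ``p``
before sampling and multiplied back, preserving the dynamic range), and
additive Gaussian noise of configurable variance.

Ground truth and degraded movies are returned separately so every metric can
be computed without re-simulation; a (scene seed, noise seed) pair fully
determines both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .operators import apply_psf
from .stack import PSF, ImageStack


# --------------------------------------------------------------------------
# Perlin (lattice-gradient) noise
# --------------------------------------------------------------------------

def _fade(t: np.ndarray) -> np.ndarray:
    # quintic smoothstep: C2-continuous interpolation weights
    return t * t * t * (t * (t * 6.0 - 15.0) + 10.0)


def _gradient_lattice_noise(
    shape: tuple[int, int], period: float, rng: np.random.Generator
) -> np.ndarray:
    """Single-octave 2-D gradient noise with lattice spacing ``period``."""
    ny, nx = shape
    gy = int(np.ceil(ny / period)) + 1
    gx = int(np.ceil(nx / period)) + 1
    angles = rng.uniform(0.0, 2.0 * np.pi, size=(gy + 1, gx + 1))
    grad = np.stack([np.cos(angles), np.sin(angles)], axis=-1)

    yy, xx = np.meshgrid(
        np.arange(ny) / period, np.arange(nx) / period, indexing="ij"
    )
    iy = yy.astype(int)
    ix = xx.astype(int)
    fy = yy - iy
    fx = xx - ix

    def corner_dot(dy: int, dx: int) -> np.ndarray:
        g = grad[iy + dy, ix + dx]
        return g[..., 0] * (fy - dy) + g[..., 1] * (fx - dx)

    u, v = _fade(fy), _fade(fx)
    top = corner_dot(0, 0) * (1 - v) + corner_dot(0, 1) * v
    bot = corner_dot(1, 0) * (1 - v) + corner_dot(1, 1) * v
    return top * (1 - u) + bot * u


def perlin_texture(
    shape: tuple[int, int],
    scale: float = 64.0,
    octaves: int = 4,
    persistence: float = 0.5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Fractal Perlin noise: octaves of gradient noise at doubling frequency.

    ``scale`` is the lattice period of the base octave in pixels.
    """
    if rng is None:
        rng = np.random.default_rng()
    out = np.zeros(shape)
    amplitude, period = 1.0, float(scale)
    for _ in range(octaves):
        if period < 2.0:
            break
        out += amplitude * _gradient_lattice_noise(shape, period, rng)
        amplitude *= persistence
        period /= 2.0
    return out


# --------------------------------------------------------------------------
# Scene generation
# --------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Knobs of the synthetic spot-movie generator.

    Intensities are in arbitrary fluorescence units with spot peak amplitude
    1 by default; lengths are in pixels, time in frames.
    """

    canvas: tuple[int, int] = (256, 256)
    frames: int = 50
    n_spots: int = 30
    spot_sigma: float = 2.0
    spot_amplitude: float = 1.0
    perlin_octaves: int = 4
    perlin_scale: float = 64.0
    perlin_threshold: float = 0.7
    brownian_step: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.canvas[0] < 3 or self.canvas[1] < 3:
            raise ValueError("canvas must be at least 3x3")
        if self.frames < 1 or self.n_spots < 1:
            raise ValueError("frames and n_spots must be positive")
        if self.spot_sigma <= 0 or self.spot_amplitude <= 0:
            raise ValueError("spot_sigma and spot_amplitude must be positive")
        if not 0.0 < self.perlin_threshold < 1.0:
            raise ValueError("perlin_threshold must lie strictly in (0, 1)")
        if self.brownian_step < 0:
            raise ValueError("brownian_step must be >= 0")


@dataclass
class NoiseModel:
    """Degradation noise: scaled Poisson plus additive Gaussian.

    ``poisson_level`` is the scale ``p``: the blurred signal is divided by
    ``p``, Poisson-sampled, and multiplied by ``p`` again, so the expected
    dynamic range is preserved while the relative shot noise grows with
    ``p``.  ``gaussian_variance`` is the variance of the additive read-noise
    term in squared intensity units.
    """

    poisson_level: float = 0.1
    gaussian_variance: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.poisson_level <= 0:
            raise ValueError(f"poisson_level must be > 0, got {self.poisson_level}")
        if self.gaussian_variance < 0:
            raise ValueError("gaussian_variance must be >= 0")


def brownian_paths(
    start: np.ndarray, frames: int, step: float, rng: np.random.Generator
) -> np.ndarray:
    """Independent 2-D Brownian paths: ``(frames, n, 2)`` positions.

    Per-frame displacements are i.i.d. N(0, step^2) on each axis, so the
    mean squared displacement grows as ``2 * step^2 * lag``.
    """
    n = start.shape[0]
    steps = rng.normal(0.0, step, size=(frames - 1, n, 2)) if frames > 1 else \
        np.zeros((0, n, 2))
    return np.concatenate([np.zeros((1, n, 2)), np.cumsum(steps, axis=0)]) + start


def _render_spots(
    canvas: tuple[int, int], centers: np.ndarray, sigma: float, amplitude: float
) -> np.ndarray:
    """Sum of isotropic Gaussian peaks at (possibly subpixel) centers."""
    ny, nx = canvas
    img = np.zeros((ny, nx))
    r = int(np.ceil(4.0 * sigma))
    for cy, cx in centers:
        y0, y1 = max(int(np.floor(cy)) - r, 0), min(int(np.ceil(cy)) + r + 1, ny)
        x0, x1 = max(int(np.floor(cx)) - r, 0), min(int(np.ceil(cx)) + r + 1, nx)
        if y0 >= y1 or x0 >= x1:
            continue  # spot wandered off the canvas
        ys = np.arange(y0, y1)[:, None]
        xs = np.arange(x0, x1)[None, :]
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -((ys - cy) ** 2 + (xs - cx) ** 2) / (2.0 * sigma ** 2)
        )
    return img


def generate_clean_series(cfg: SimulationConfig) -> ImageStack:
    """Ground-truth movie: clustered Gaussian spots on Brownian paths.

    Initial spot centers are drawn only from pixels where the Perlin texture
    exceeds its ``perlin_threshold`` quantile; the texture itself does not
    appear in the output.
    """
    rng = np.random.default_rng(cfg.seed)
    texture = perlin_texture(
        cfg.canvas, scale=cfg.perlin_scale, octaves=cfg.perlin_octaves, rng=rng
    )
    cutoff = np.quantile(texture, cfg.perlin_threshold)
    candidates = np.argwhere(texture >= cutoff).astype(float)
    if candidates.shape[0] == 0:
        raise ValueError(
            "placeable region is empty at the given perlin_threshold; "
            "lower the threshold"
        )
    replace = candidates.shape[0] < cfg.n_spots
    idx = rng.choice(candidates.shape[0], size=cfg.n_spots, replace=replace)
    centers = candidates[idx] + rng.uniform(-0.5, 0.5, size=(cfg.n_spots, 2))
    paths = brownian_paths(centers, cfg.frames, cfg.brownian_step, rng)

    frames = np.stack([
        _render_spots(cfg.canvas, paths[t], cfg.spot_sigma, cfg.spot_amplitude)
        for t in range(cfg.frames)
    ])
    return ImageStack(frames)


def degrade(clean: ImageStack, psf: PSF, noise: NoiseModel) -> ImageStack:
    """Apply the imaging forward model: PSF blur, then Poisson and Gaussian noise.

    Output = p * Poisson(blur(clean) / p) + N(0, gaussian_variance),
    elementwise and fully determined by ``noise.seed``.  Both noise
    injections are mean-preserving, so the expected output equals the
    blurred ground truth.
    """
    if clean.data.min() < 0:
        raise ValueError("clean input must be non-negative")
    blurred = np.maximum(apply_psf(clean, psf).data, 0.0)
    rng = np.random.default_rng(noise.seed)
    p = noise.poisson_level
    out = p * rng.poisson(blurred / p).astype(np.float64)
    if noise.gaussian_variance > 0:
        out += rng.normal(0.0, np.sqrt(noise.gaussian_variance), size=out.shape)
    return clean.copy_with(out)


def make_gaussian_psf(sigma: float, size: int | None = None) -> PSF:
    """Normalized isotropic Gaussian kernel centered on the middle pixel.

    ``size`` must be odd; by default it spans +/- 3 sigma (at least 3x3).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if size is None:
        size = max(2 * int(np.ceil(3.0 * sigma)) + 1, 3)
    if size % 2 == 0:
        raise ValueError(f"PSF size must be odd, got {size}")
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma ** 2))
    return PSF(k)
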