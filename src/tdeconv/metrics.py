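"""Quantitative evaluation: SSIM, normalized SSIM, background-noise variance.

The structural similarity index is computed per local window as

    SSIM(x, y) = (2 mu_x mu_y + c1)(2 sigma_xy + c2)
                 / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

with uniform sliding windows and c1 = (0.01 L)^2, c2 = (0.03 L)^2 for
dynamic range L.  Restoration quality on synthetic data is summarized as the
*normalized* SSIM: the frame-averaged SSIM of restored-vs-clean divided by
that of noisy-vs-clean, so values above 1 mean the restoration improved
structural similarity over the raw input.

Background noise is estimated without a reference by a patch-based scheme:
the frame is high-pass filtered with a second-difference (Laplacian-type)
stencil that annihilates constant and linear structure, patches are ranked
by texture energy, and the Gaussian noise variance is read off the
weakly-textured tail with the stencil's noise gain divided out.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, signal, stats

from .stack import ImageStack

# --------------------------------------------------------------------------
# SSIM
# --------------------------------------------------------------------------


@dataclass
class SSIMConfig:
    """Window size and stabilization constants of the SSIM computation.

    ``data_range`` is the dynamic range L entering c1 = (0.01 L)^2 and
    c2 = (0.03 L)^2; when None it is inferred from the joint range of the
    two images being compared (falling back to 1 for constant pairs).
    """

    window: int = 7
    data_range: float | None = None
    k1: float = 0.01
    k2: float = 0.03

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.data_range is not None and self.data_range <= 0:
            raise ValueError("data_range must be positive")


def ssim(a: np.ndarray, b: np.ndarray, cfg: SSIMConfig | None = None) -> float:
    """Mean local SSIM between two 2-D images (symmetric in its arguments).

    Local means, variances and covariance use uniform windows and population
    normalization; windows overhanging the border are discarded.
    """
    if cfg is None:
        cfg = SSIMConfig()
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("ssim expects 2-D images")
    if min(a.shape) < cfg.window:
        raise ValueError(
            f"images smaller than the {cfg.window}x{cfg.window} SSIM window"
        )
    if cfg.data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        drange = hi - lo if hi > lo else 1.0
    else:
        drange = cfg.data_range
    c1 = (cfg.k1 * drange) ** 2
    c2 = (cfg.k2 * drange) ** 2

    win = cfg.window
    f = lambda x: ndimage.uniform_filter(x, size=win)
    mu_a, mu_b = f(a), f(b)
    var_a = f(a * a) - mu_a * mu_a
    var_b = f(b * b) - mu_b * mu_b
    cov = f(a * b) - mu_a * mu_b

    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)
    smap = num / den
    pad = win // 2
    return float(smap[pad:-pad, pad:-pad].mean())


def mean_normalized_ssim(
    restored: ImageStack,
    noisy: ImageStack,
    clean: ImageStack,
    cfg: SSIMConfig | None = None,
) -> float:
    """Frame-averaged SSIM(restored, clean) over SSIM(noisy, clean).

    Values above 1 indicate the restoration improved structural similarity
    relative to the noisy input.  The SSIM dynamic range defaults to the
    range of the clean stack so numerator and denominator are comparable.
    """
    if not restored.shape == noisy.shape == clean.shape:
        raise ValueError("restored, noisy and clean stacks must share a shape")
    if cfg is None:
        cfg = SSIMConfig()
    if cfg.data_range is None:
        drange = clean.dynamic_range() or 1.0
        cfg = SSIMConfig(window=cfg.window, data_range=drange, k1=cfg.k1, k2=cfg.k2)
    num = np.mean([
        ssim(restored.data[t], clean.data[t], cfg) for t in range(clean.n_frames)
    ])
    den = np.mean([
        ssim(noisy.data[t], clean.data[t], cfg) for t in range(clean.n_frames)
    ])
    if den <= 0:
        raise ValueError(
            f"noisy-vs-clean SSIM is {den:.4g} <= 0; the normalized SSIM is "
            "undefined for anti-correlated inputs"
        )
    return float(num / den)


# --------------------------------------------------------------------------
# Background-noise variance estimation
# --------------------------------------------------------------------------

# second-difference high-pass stencil; annihilates constant and linear ramps,
# noise variance gain = sum of squared taps = 36
_HIGHPASS = np.array([[1.0, -2.0, 1.0], [-2.0, 4.0, -2.0], [1.0, -2.0, 1.0]])
_HIGHPASS_GAIN = float((_HIGHPASS ** 2).sum())


def estimate_background_noise(
    frame: np.ndarray, patch_size: int = 8, quantile: float = 0.5
) -> float:
    """Estimate the additive Gaussian noise variance of a frame's background.

    The frame is high-pass filtered, tiled into patches, and patches are
    ranked by the texture energy of their upper halves; the variance is then
    estimated robustly (median absolute deviation) from the *lower* halves of
    the weakest-texture patches, with the filter's noise gain divided out.
    Ranking and estimation use disjoint pixels so the selection does not bias
    the estimate.  Invariant to constant offsets.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("expected a 2-D frame")
    if frame.shape[0] < 16 or frame.shape[1] < 16:
        raise ValueError(f"frame {frame.shape} too small to tile (need >= 16x16)")
    if not 0 < quantile <= 1:
        raise ValueError("quantile must lie in (0, 1]")

    r = signal.convolve2d(frame, _HIGHPASS, mode="valid")
    ny, nx = r.shape
    py, px = ny // patch_size, nx // patch_size
    if py == 0 or px == 0:
        raise ValueError("frame too small for the requested patch size")
    r = r[: py * patch_size, : px * patch_size]
    patches = r.reshape(py, patch_size, px, patch_size).transpose(0, 2, 1, 3)
    patches = patches.reshape(-1, patch_size, patch_size)

    half = patch_size // 2
    energy = np.mean(patches[:, :half, :] ** 2, axis=(1, 2))
    cutoff = np.quantile(energy, quantile)
    selected = patches[energy <= cutoff, half:, :]
    pooled = np.abs(selected).ravel()
    sigma_r = np.median(pooled) / 0.6745
    return float(sigma_r ** 2 / _HIGHPASS_GAIN)


# --------------------------------------------------------------------------
# Method ordering test
# --------------------------------------------------------------------------


def method_ordering_test(
    scores: Mapping[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], float]:
    """Paired one-sided Wilcoxon signed-rank tests with Bonferroni correction.

    For each pair ``(a, b)`` the null is "no difference" against the
    alternative that method ``a`` scores *higher* than method ``b`` on the
    paired observations.  P-values are multiplied by the number of
    comparisons and capped at 1.

    Parameters
    ----------
    scores
        Mapping of method name to equal-length score lists (paired by index,
        e.g. one score per random scene).
    pairs
        Ordered pairs to test; defaults to every pairwise combination in the
        mapping's iteration order.
    """
    methods = list(scores)
    lengths = {m: len(scores[m]) for m in methods}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"score lists must have equal lengths, got {lengths}")
    n = next(iter(lengths.values()))
    if n < 5:
        raise ValueError(
            f"need at least 5 paired observations for the signed-rank test, got {n}"
        )
    if pairs is None:
        pairs = list(itertools.combinations(methods, 2))
    out: dict[tuple[str, str], float] = {}
    m = len(pairs)
    for a, b in pairs:
        d = np.asarray(scores[a], dtype=float) - np.asarray(scores[b], dtype=float)
        if np.all(d == 0):
            p = 1.0  # no signed ranks: the test carries no evidence
        else:
            p = float(
                stats.wilcoxon(d, alternative="greater", zero_method="wilcox").pvalue
            )
        out[(a, b)] = min(1.0, p * m)
    return out


# --------------------------------------------------------------------------
# Report container
# --------------------------------------------------------------------------


@dataclass
class MetricReport:
    """Tabular benchmark results: one record per (method, noise level, scene)."""

    records: list[dict] = field(default_factory=list)

    COLUMNS = (
        "method",
        "scene",
        "gaussian_variance",
        "gaussian_fraction",
        "poisson_fraction",
        "ssim_raw",
        "ssim_norm",
        "noise_var",
    )

    def add(self, **record) -> None:
        self.records.append(record)

    def column(self, name: str, **where) -> list:
        """Values of one column, filtered by equality on other columns."""
        return [
            rec[name]
            for rec in self.records
            if all(rec.get(k) == v for k, v in where.items())
        ]

    def mean(self, name: str, **where) -> float:
        vals = self.column(name, **where)
        if not vals:
            raise KeyError(f"no records match {where}")
        return float(np.mean(vals))

    def methods(self) -> list[str]:
        seen: list[str] = []
        for rec in self.records:
            if rec["method"] not in seen:
                seen.append(rec["method"])
        return seen

    def write(self, path) -> None:
        """Write the records as tab-separated text with a header row."""
        cols = [c for c in self.COLUMNS if any(c in r for r in self.records)]
        extra = sorted(
            {k for r in self.records for k in r} - set(cols)
        )
        cols += extra
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols, delimiter="\t")
            writer.writeheader()
            for rec in self.records:
                writer.writerow(rec)
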