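"""Discrete derivative operators and PSF convolution under periodic boundaries.

All operators are stationary convolutions on the ``(T, Ny, Nx)`` grid and are
applied in the Fourier domain, which makes the adjoint exact (conjugate
transfer function) and keeps every application an FFT pair.

Spatial regularization uses the three second-derivative filters within a
frame (d2/dx2, d2/dy2, d2/dxdy); temporal regularization uses the three
filters that couple frames (d2/dt2, d2/dxdt, d2/dydt).  Second derivatives
are central differences [1, -2, 1]; mixed derivatives are outer products of
central first differences [-1/2, 0, 1/2] on the two axes, all at unit grid
spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from .stack import PSF, ImageStack

SPATIAL_NAMES = ("d2x", "d2y", "dxy")
TEMPORAL_NAMES = ("d2t", "dxt", "dyt")

_D2 = np.array([1.0, -2.0, 1.0])
_D1 = np.array([-0.5, 0.0, 0.5])

# axis order of the stack: 0 = t, 1 = y, 2 = x
_STENCILS: dict[str, tuple[np.ndarray, tuple[int, ...]]] = {
    "d2x": (_D2, (2,)),
    "d2y": (_D2, (1,)),
    "dxy": (np.outer(_D1, _D1), (1, 2)),
    "d2t": (_D2, (0,)),
    "dxt": (np.outer(_D1, _D1), (0, 2)),
    "dyt": (np.outer(_D1, _D1), (0, 1)),
}


def _embed_kernel(kernel: np.ndarray, axes: tuple[int, ...], shape: tuple[int, int, int]) -> np.ndarray:
    """Place a small centered kernel on the full grid, centered at the origin.

    The kernel is padded to the full ``shape`` and rolled so that its center
    tap sits at index 0 on every axis (circular convolution convention).
    """
    kshape = [1, 1, 1]
    for ax, n in zip(axes, kernel.shape):
        kshape[ax] = n
    k = kernel.reshape(kshape)
    for ax in range(3):
        if k.shape[ax] > shape[ax]:
            raise ValueError(
                f"kernel extent {k.shape[ax]} exceeds stack size {shape[ax]} "
                f"on axis {ax}"
            )
    full = np.zeros(shape)
    full[tuple(slice(0, n) for n in k.shape)] = k
    for ax in range(3):
        full = np.roll(full, -(k.shape[ax] // 2), axis=ax)
    return full


def _otf(kernel: np.ndarray, axes: tuple[int, ...], shape: tuple[int, int, int]) -> np.ndarray:
    """Transfer function (rfftn) of a small centered kernel on the grid."""
    return sfft.rfftn(_embed_kernel(kernel, axes, shape))


@dataclass
class OperatorSet:
    """Derivative operators (and their adjoints) for a fixed stack shape.

    Holds the Fourier transfer function of each stencil; ``apply`` and
    ``apply_adjoint`` are exact adjoints of each other under the periodic
    boundary.  Every stencil annihilates constants (zero DC response).
    """

    shape: tuple[int, int, int]
    boundary_mode: str = "periodic"
    otfs: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    temporal_active: bool = True

    @property
    def spatial_names(self) -> tuple[str, ...]:
        return SPATIAL_NAMES

    @property
    def temporal_names(self) -> tuple[str, ...]:
        return TEMPORAL_NAMES

    def _check(self, arr: np.ndarray) -> None:
        if arr.shape != self.shape:
            raise ValueError(f"expected shape {self.shape}, got {arr.shape}")

    def apply(self, name: str, arr: np.ndarray) -> np.ndarray:
        self._check(arr)
        otf = self.otfs[name]
        if otf is None:  # degenerate temporal operator (T < 3)
            return np.zeros_like(arr)
        return sfft.irfftn(otf * sfft.rfftn(arr), s=self.shape)

    def apply_adjoint(self, name: str, arr: np.ndarray) -> np.ndarray:
        self._check(arr)
        otf = self.otfs[name]
        if otf is None:
            return np.zeros_like(arr)
        return sfft.irfftn(np.conj(otf) * sfft.rfftn(arr), s=self.shape)


def make_derivative_operators(
    shape: tuple[int, int, int], boundary_mode: str = "periodic"
) -> OperatorSet:
    """Build the six second-derivative operators for a stack shape.

    Parameters
    ----------
    shape
        ``(T, Ny, Nx)`` of the stacks the operators will act on.
    boundary_mode
        Only ``"periodic"`` is supported; derivatives and the PSF then share
        one consistent (FFT-diagonal) boundary treatment.

    For ``T < 3`` the temporal stencils do not fit; the three temporal
    operators degenerate to zero operators and a warning is emitted.
    """
    if boundary_mode != "periodic":
        raise ValueError(f"unsupported boundary mode: {boundary_mode!r}")
    t, ny, nx = shape
    if ny < 3:
        raise ValueError(f"axis y of size {ny} is too small for 3-tap stencils")
    if nx < 3:
        raise ValueError(f"axis x of size {nx} is too small for 3-tap stencils")

    ops = OperatorSet(shape=tuple(shape), boundary_mode=boundary_mode)
    for name in SPATIAL_NAMES:
        kern, axes = _STENCILS[name]
        ops.otfs[name] = _otf(kern, axes, tuple(shape))
    ops.temporal_active = t >= 3
    if not ops.temporal_active:
        warnings.warn(
            f"stack has T={t} < 3 frames: temporal derivative operators are "
            "undefined and replaced by zero operators (static restoration)",
            UserWarning,
            stacklevel=2,
        )
        for name in TEMPORAL_NAMES:
            ops.otfs[name] = None
    else:
        for name in TEMPORAL_NAMES:
            kern, axes = _STENCILS[name]
            ops.otfs[name] = _otf(kern, axes, tuple(shape))
    return ops


def psf_otf(psf: PSF, shape: tuple[int, int, int]) -> np.ndarray:
    """Transfer function of per-frame convolution with the PSF.

    The PSF acts identically on every frame (block-diagonal over time), i.e.
    it is a 2-D kernel embedded with a delta along t.
    """
    ky, kx = psf.kernel.shape
    if ky > shape[1] or kx > shape[2]:
        raise ValueError(
            f"PSF kernel {psf.kernel.shape} larger than frame "
            f"{shape[1:]} — cannot convolve"
        )
    return _otf(psf.kernel, (1, 2), tuple(shape))


def apply_psf(stack: ImageStack, psf: PSF) -> ImageStack:
    """Convolve every frame with the PSF under periodic boundaries.

    The kernel is normalized to unit sum, so total per-frame intensity is
    conserved.
    """
    otf = psf_otf(psf, stack.shape)
    out = sfft.irfftn(otf * sfft.rfftn(stack.data), s=stack.shape)
    return stack.copy_with(out)
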