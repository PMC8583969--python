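"""Core containers for image time series and point spread functions.

An :class:`ImageStack` holds a fluorescence time series as a ``T x Ny x Nx``
float array (one 2-D frame per time point).  A :class:`PSF` holds the 2-D
blur kernel of the imaging system; image formation is modelled as per-frame
convolution with this kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageStack:
    """A time series of 2-D grayscale frames.

    Parameters
    ----------
    data
        Array of shape ``(T, Ny, Nx)`` (a single 2-D frame is promoted to
        ``T = 1``).  Values must be finite; frames must be at least 3x3 so
        that second-derivative stencils fit.
    frame_interval
        Optional time between frames in seconds (metadata only).
    pixel_size
        Optional pixel edge length in micrometers (metadata only).
    """

    data: np.ndarray
    frame_interval: float | None = None
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[np.newaxis]
        if arr.ndim != 3:
            raise ValueError(
                f"expected a (T, Ny, Nx) stack or a single 2-D frame, "
                f"got ndim={arr.ndim}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("stack contains non-finite values")
        t, ny, nx = arr.shape
        if t < 1:
            raise ValueError("stack must contain at least one frame")
        if ny < 3:
            raise ValueError(f"frame height Ny={ny} too small (need >= 3)")
        if nx < 3:
            raise ValueError(f"frame width Nx={nx} too small (need >= 3)")
        self.data = arr

    # -- convenience ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def n_pixels(self) -> int:
        """Total number of space-time samples (K = T * Ny * Nx)."""
        return int(self.data.size)

    def copy_with(self, data: np.ndarray) -> "ImageStack":
        """New stack with the same metadata but different pixel data."""
        return ImageStack(
            data, frame_interval=self.frame_interval, pixel_size=self.pixel_size
        )

    def dynamic_range(self) -> float:
        return float(self.data.max() - self.data.min())


@dataclass
class PSF:
    """A 2-D point spread function.

    The kernel must have odd side lengths and non-negative entries; it is
    normalized to unit sum on construction so that convolution conserves
    total intensity under periodic boundary conditions.
    """

    kernel: np.ndarray = field()

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=np.float64)
        if k.ndim != 2:
            raise ValueError(f"PSF kernel must be 2-D, got ndim={k.ndim}")
        if k.shape[0] % 2 == 0 or k.shape[1] % 2 == 0:
            raise ValueError(f"PSF side lengths must be odd, got {k.shape}")
        if np.any(k < 0):
            raise ValueError("PSF kernel must be non-negative")
        s = k.sum()
        if not np.isfinite(s) or s <= 0:
            raise ValueError("PSF kernel must have positive finite sum")
        self.kernel = k / s

    @property
    def shape(self) -> tuple[int, int]:
        return self.kernel.shape
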