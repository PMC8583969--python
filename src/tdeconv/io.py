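"""TIFF stack I/O, flat key-value configuration, and provenance records."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .stack import ImageStack

#: keys accepted in a flat configuration file
CONFIG_KEYS = {
    "lambda", "lambda_t", "lambda_n", "epsilon", "max_iter", "tol",
    "boundary", "psf_path", "psf_sigma", "method", "iterations",
}


def read_stack(path) -> ImageStack:
    """Read a multi-page grayscale TIFF as a ``(T, Ny, Nx)`` float stack.

    Integer data are promoted to float64 with values preserved.  Single-page
    files yield ``T = 1`` with a warning that only static restoration is
    possible.  Color (RGB/RGBA) pages are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            if page.samplesperpixel != 1:
                raise ValueError(
                    f"page {i} of {path} is not grayscale "
                    f"({page.samplesperpixel} samples per pixel)"
                )
        shapes = {page.shape for page in tif.pages}
        if len(shapes) != 1:
            raise ValueError(f"ragged pages in {path}: shapes {sorted(shapes)}")
        arr = tif.asarray()
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 2:
        warnings.warn(
            f"{path} has a single page: temporal regularization is undefined, "
            "only static (per-frame) restoration applies",
            UserWarning,
            stacklevel=2,
        )
        arr = arr[np.newaxis]
    return ImageStack(arr)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a 32-bit float multi-page TIFF."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")


def load_config(path) -> dict:
    """Load a flat key-value (YAML) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a flat mapping")
    unknown = set(cfg) - CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    return cfg


def write_provenance(path, **fields) -> None:
    """Record the full parameter set of a run next to its outputs."""
    from . import __version__

    record = {"tdeconv_version": __version__, **fields}
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
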