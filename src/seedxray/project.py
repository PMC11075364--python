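"""Dimensionality reduction of 3D stacks: average-intensity Z-projection.

A tomographic stack of N aligned slices I_n(x, y) collapses to a single 2D
image by the per-pixel mean

    P(x, y) = (1/N) * sum_n I_n(x, y),

computed in floating point, then min-max normalized to 8 bit so the result
feeds the same 2D pipeline (decomposition, detection scoring) as native
radiographs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .datasets import read_image
from .errors import SizeError

__all__ = [
    "ImageStack",
    "z_project_mean",
    "normalize_projection",
    "read_stack",
    "write_stack",
]


@dataclass
class ImageStack:
    """N equally shaped grayscale slices, index n along Z."""

    slices: np.ndarray  # (N, H, W)

    def __post_init__(self) -> None:
        arr = np.asarray(self.slices)
        if arr.ndim == 2:
            arr = arr[None, ...]
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise SizeError(f"stack must be (N, H, W) with N >= 1, got {arr.shape}")
        self.slices = arr

    @property
    def n(self) -> int:
        return self.slices.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.slices.shape[1:]

    @classmethod
    def from_slices(cls, slices) -> "ImageStack":
        slices = [np.asarray(s) for s in slices]
        if not slices:
            raise SizeError("stack must contain at least one slice")
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise SizeError(f"slices have mixed shapes: {sorted(shapes)}")
        return cls(np.stack(slices, axis=0))


def z_project_mean(stack: ImageStack | np.ndarray) -> np.ndarray:
    """Per-pixel mean over slices; floating-point output, slice shape."""
    if not isinstance(stack, ImageStack):
        stack = ImageStack(stack)
    return stack.slices.astype(np.float64).mean(axis=0)


def normalize_projection(projection: np.ndarray) -> np.ndarray:
    """Linear min-max rescale to [0, 255], rounded to uint8.

    A constant projection maps to all zeros (committed degenerate rule).
    """
    proj = np.asarray(projection, dtype=np.float64)
    lo = proj.min()
    hi = proj.max()
    if hi == lo:
        return np.zeros(proj.shape, dtype=np.uint8)
    out = (proj - lo) / (hi - lo) * 255.0
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def read_stack(path: str | os.PathLike) -> ImageStack:
    """Load a stack from a multi-page TIFF or a directory of slice images.

    Directory slices are read in lexicographic name order and must share
    one shape.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.is_file())
        if not files:
            raise SizeError(f"no slice files in {path}")
        return ImageStack.from_slices([read_image(p) for p in files])
    arr = tifffile.imread(str(path))
    return ImageStack(arr)


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write a stack as a multi-page TIFF (lossless, round-trip safe)."""
    tifffile.imwrite(str(path), stack.slices, photometric="minisblack")
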