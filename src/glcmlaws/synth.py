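"""Synthetic linear-gradient images and grayscale image I/O.

The central input class of this package is the one-dimensional linear
gradient: a periodic sawtooth ramp whose intensity increases (or decreases)
by ``nabla`` gray levels per pixel along one axis and wraps around once the
top of the gray-level range is reached.  For these images the gray-level
co-occurrence matrix has an exactly known structure, which is what makes
closed-form feature predictions possible (see :mod:`glcmlaws.scaling`).

The ramp wraps over the *gradient lattice* ``{0, nabla, 2*nabla, ...,
(n_tilde - 1) * nabla}`` where ``n_tilde = 1 + (n_levels - 1) // nabla`` is
the number of distinct levels the ramp visits.  The period of the pattern is
``n_tilde`` pixels, not ``n_levels``: for ``n_levels=7, nabla=2`` a column
reads ``0, 2, 4, 6, 0, 2, 4, 6, ...`` and never visits odd levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GradientSpec",
    "GrayImage",
    "make_linear_gradient",
    "read_image",
    "write_image",
]


@dataclass(frozen=True)
class GrayImage:
    """A 2-D integer grayscale image.

    Coordinates follow the usual image convention: the origin is the upper-left
    corner, ``x`` increases to the right (columns) and ``y`` increases downward
    (rows).  ``pixels[y, x]`` is the intensity at ``(x, y)``.

    Parameters
    ----------
    pixels
        2-D array of non-negative integers, all strictly below ``n_levels``.
    n_levels
        Number of gray levels ``Ng`` (bit depth ``b`` gives ``Ng = 2**b``).
    """

    pixels: np.ndarray
    n_levels: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if px.size == 0:
            raise ValueError("image must have at least one pixel")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError(f"pixels must be an integer array, got dtype {px.dtype}")
        if self.n_levels < 1:
            raise ValueError(f"n_levels must be >= 1, got {self.n_levels}")
        if px.min() < 0 or px.max() >= self.n_levels:
            raise ValueError(
                f"pixel values must lie in [0, {self.n_levels - 1}], "
                f"got range [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        """Number of columns ``Nx``."""
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        """Number of rows ``Ny``."""
        return self.pixels.shape[0]


@dataclass(frozen=True)
class GradientSpec:
    """Parameters of a one-dimensional linear sawtooth gradient.

    Parameters
    ----------
    nabla
        Gradient magnitude ``|∇|`` in gray levels per pixel; must satisfy
        ``1 <= nabla <= n_levels - 1``.
    sign
        ``+1`` for an ascending ramp along the axis, ``-1`` for descending.
    axis
        ``"vertical"`` (intensity varies with the row ``y``) or
        ``"horizontal"`` (varies with the column ``x``).
    phase
        Starting offset on the gradient lattice, in lattice steps; the first
        row (or column) has intensity ``nabla * (phase % n_tilde)``.
    n_levels
        Gray-level count ``Ng``.
    width, height
        Image dimensions ``Nx`` and ``Ny``.
    """

    nabla: int
    sign: int = 1
    axis: str = "vertical"
    phase: int = 0
    n_levels: int = 256
    width: int = 1024
    height: int = 1024

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError(f"n_levels must be >= 2, got {self.n_levels}")
        if not (1 <= self.nabla <= self.n_levels - 1):
            raise ValueError(
                f"nabla must satisfy 1 <= nabla <= n_levels-1 = "
                f"{self.n_levels - 1}, got {self.nabla}"
            )
        if self.sign not in (1, -1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")
        if self.axis not in ("vertical", "horizontal"):
            raise ValueError(f"axis must be 'vertical' or 'horizontal', got {self.axis!r}")
        if self.width < 1 or self.height < 1:
            raise ValueError("width and height must be positive")

    @property
    def n_tilde(self) -> int:
        """Number of distinct levels visited by the ramp (its period in pixels)."""
        return 1 + (self.n_levels - 1) // self.nabla


def make_linear_gradient(spec: GradientSpec) -> GrayImage:
    """Generate the sawtooth gradient image described by *spec*.

    For a vertical gradient the intensity at row ``y`` is
    ``nabla * ((sign * y + phase) mod n_tilde)``, independent of the column;
    a horizontal gradient swaps the roles of ``x`` and ``y``.  The wraparound
    happens on the gradient lattice, so the intensity drops from
    ``(n_tilde - 1) * nabla`` straight back to 0.
    """
    nt = spec.n_tilde
    n = spec.height if spec.axis == "vertical" else spec.width
    idx = np.arange(n, dtype=np.int64)
    ramp = spec.nabla * ((spec.sign * idx + spec.phase) % nt)
    if spec.axis == "vertical":
        pixels = np.broadcast_to(ramp[:, None], (spec.height, spec.width)).copy()
    else:
        pixels = np.broadcast_to(ramp[None, :], (spec.height, spec.width)).copy()
    return GrayImage(pixels=pixels, n_levels=spec.n_levels)


def _infer_n_levels(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 256
    if arr.dtype == np.uint16:
        return 65536
    # fall back to the smallest power of two covering the data
    top = int(arr.max())
    n = 2
    while n <= top:
        n *= 2
    return n


def read_image(path: str | Path, n_levels: int | None = None) -> GrayImage:
    """Read a single-channel integer PNG or TIFF as a :class:`GrayImage`.

    ``n_levels`` defaults to ``2**bitdepth`` of the stored sample type
    (256 for 8-bit, 65536 for 16-bit); pass it explicitly to override.
    Multi-channel or floating-point files are rejected.
    """
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel grayscale image, "
            f"got array of shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: expected an integer image, got dtype {arr.dtype}")
    if n_levels is None:
        n_levels = _infer_n_levels(arr)
    return GrayImage(pixels=arr.astype(np.int64), n_levels=n_levels)


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write a :class:`GrayImage` to PNG (8-bit) or TIFF (8/16-bit)."""
    path = Path(path)
    if img.n_levels <= 256:
        out = img.pixels.astype(np.uint8)
    elif img.n_levels <= 65536:
        out = img.pixels.astype(np.uint16)
    else:
        raise ValueError(f"cannot store {img.n_levels} gray levels in PNG/TIFF")
    if path.suffix.lower() == ".png" and out.dtype == np.uint16:
        raise ValueError("16-bit output requires TIFF; PNG writer here is 8-bit only")
    iio.imwrite(path, out)
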