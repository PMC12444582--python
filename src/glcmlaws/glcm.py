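"""Gray-level co-occurrence matrices and their marginal statistics.

A co-occurrence matrix ``P_d(i, j)`` counts, over all pixel positions
``(x, y)``, the ordered pairs in which the reference pixel has gray level
``i`` and the pixel displaced by ``d = (Δx, Δy)`` has gray level ``j``.
Counting is non-symmetric by default (``P(0,1)`` and ``P(1,0)`` are separate
entries); pass ``symmetric=True`` to accumulate both orientations.

Two boundary conventions are provided.  In the default *non-cyclic* mode,
pairs whose target pixel falls outside the image are dropped, so for a
``Nx × Ny`` image the unit horizontal displacement yields ``(Nx-1)·Ny``
pairs and the unit vertical one ``(Ny-1)·Nx``.  In *cyclic* mode the target
coordinates wrap modulo the image size and every pixel contributes exactly
one pair; on a sawtooth gradient whose height is a whole number of periods
this removes edge effects entirely, which is the regime in which the
closed-form feature laws of :mod:`glcmlaws.scaling` are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import GrayImage

__all__ = [
    "Displacement",
    "CoocMatrix",
    "GlcmMarginals",
    "compute_glcm",
    "marginals",
    "diff_histogram",
    "requantize",
]


@dataclass(frozen=True)
class Displacement:
    """Offset vector ``d = (Δx, Δy)``: ``dx`` to the right, ``dy`` downward."""

    dx: int
    dy: int

    def __post_init__(self) -> None:
        if self.dx == 0 and self.dy == 0:
            raise ValueError("displacement must be nonzero")

    def __neg__(self) -> "Displacement":
        return Displacement(-self.dx, -self.dy)


@dataclass(frozen=True)
class CoocMatrix:
    """Co-occurrence counts and normalized probabilities.

    ``counts[i, j]`` is the number of ordered pairs with reference level ``i``
    and target level ``j``; ``total`` is the normalization ``R`` (the sum of
    all counts) and ``probs = counts / total``.
    """

    counts: np.ndarray
    displacement: Displacement
    n_levels: int
    cyclic: bool = False
    symmetric: bool = False

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probs(self) -> np.ndarray:
        return self.counts / self.total


@dataclass(frozen=True)
class GlcmMarginals:
    """Marginal distributions and moments of a normalized co-occurrence matrix.

    ``px[i]`` / ``py[j]`` are the reference/target gray-level marginals,
    ``pdiff[k]`` is the probability of an absolute level difference
    ``k = |i - j|``, and ``mu_x, sigma_x`` (resp. ``_y``) are the mean and
    standard deviation of ``px`` (resp. ``py``).
    """

    px: np.ndarray
    py: np.ndarray
    pdiff: np.ndarray
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float


def compute_glcm(
    img: GrayImage,
    d: Displacement,
    cyclic: bool = False,
    symmetric: bool = False,
) -> CoocMatrix:
    """Compute the co-occurrence matrix of *img* at displacement *d*.

    Parameters
    ----------
    img
        Input image; levels must already lie in ``[0, n_levels)``.
    d
        Displacement vector ``(Δx, Δy)``.
    cyclic
        Wrap target coordinates modulo the image size instead of dropping
        out-of-bounds pairs.
    symmetric
        Also count each pair in the reverse orientation (adds the transpose).

    Raises
    ------
    ValueError
        In non-cyclic mode, if the displacement is as large as the image in
        either dimension (no valid pair would remain).
    """
    px = img.pixels
    ny, nx = px.shape
    ng = img.n_levels
    if cyclic:
        ref = px
        tgt = np.roll(px, shift=(-d.dy, -d.dx), axis=(0, 1))
    else:
        if abs(d.dx) >= nx or abs(d.dy) >= ny:
            raise ValueError(
                f"displacement {(d.dx, d.dy)} leaves no valid pairs in a "
                f"{nx}x{ny} image (non-cyclic mode)"
            )
        y0, y1 = max(0, -d.dy), ny - max(0, d.dy)
        x0, x1 = max(0, -d.dx), nx - max(0, d.dx)
        ref = px[y0:y1, x0:x1]
        tgt = px[y0 + d.dy : y1 + d.dy, x0 + d.dx : x1 + d.dx]
    pairs = ref.ravel().astype(np.int64) * ng + tgt.ravel()
    counts = np.bincount(pairs, minlength=ng * ng).reshape(ng, ng)
    if symmetric:
        counts = counts + counts.T
    return CoocMatrix(
        counts=counts, displacement=d, n_levels=ng, cyclic=cyclic, symmetric=symmetric
    )


def marginals(g: CoocMatrix) -> GlcmMarginals:
    """Marginal distributions ``px``, ``py``, ``p_{x-y}`` and their moments."""
    if g.total == 0:
        raise ValueError("co-occurrence matrix is empty (total == 0)")
    p = g.probs
    ng = g.n_levels
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    levels = np.arange(ng)
    pdiff = diff_histogram(g) / g.total
    mu_x = float(levels @ px)
    mu_y = float(levels @ py)
    var_x = float(levels**2 @ px) - mu_x**2
    var_y = float(levels**2 @ py) - mu_y**2
    return GlcmMarginals(
        px=px,
        py=py,
        pdiff=pdiff,
        mu_x=mu_x,
        mu_y=mu_y,
        sigma_x=float(np.sqrt(max(var_x, 0.0))),
        sigma_y=float(np.sqrt(max(var_y, 0.0))),
    )


def diff_histogram(g: CoocMatrix) -> np.ndarray:
    """Integer histogram of absolute level differences ``k = |i - j|``.

    Kept in exact integer arithmetic so that difference-based statistics
    (Contrast in particular) incur a single rounding at the final division.
    """
    ng = g.n_levels
    levels = np.arange(ng)
    absdiff = np.abs(levels[:, None] - levels[None, :])
    hist = np.zeros(ng, dtype=np.int64)
    np.add.at(hist, absdiff.ravel(), g.counts.ravel())
    return hist


def requantize(img: GrayImage, n_levels: int) -> GrayImage:
    """Linearly bin an image down to *n_levels* gray levels.

    Bin edges are uniform on ``[0, max + 1)``; useful for real images whose
    native bit depth makes a dense co-occurrence matrix impractical.  The
    synthetic-gradient workflow never requantizes.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    top = int(img.pixels.max()) + 1
    binned = (img.pixels.astype(np.int64) * n_levels) // top
    return GrayImage(pixels=binned, n_levels=n_levels)
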