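"""Closed-form scaling laws for Haralick features of linear-gradient images.

For a sawtooth gradient of magnitude ``∇`` gray levels per pixel in an image
with ``Ng`` gray levels, probed along the gradient axis at scalar
displacement ``d``, the co-occurrence matrix has an exactly known structure:

* it has ``Ñg = 1 + floor((Ng-1)/∇)`` nonzero entries, all equal to
  ``1/Ñg`` when the image spans a whole number of periods and pairing wraps
  cyclically;
* ``m1 = Ñg - d`` of them sit on the super-diagonal at level offset
  ``k = j - i = +d∇`` and the remaining ``m2 = d`` wrapped entries sit on
  the sub-diagonal at ``k = -m1·∇``.

From this structure the four features follow in closed form::

    f1 = 1/Ñg                                       (independent of d)
    f2 = ∇² · d · (Ñg - d)
    f3 = 1 - 6·d·(Ñg - d) / ((Ñg - 1)(Ñg + 1))      (independent of ∇)
    f5 = (1/Ñg) · [ (Ñg - d)/(1 + d∇) + d/(1 + (Ñg - d)∇) ]

(the ``squared``-weight homogeneity variant replaces each denominator
``1 + m`` by ``1 + m²``).  All laws depend on the displacement only through
``d_eff = d mod Ñg``; ``d_eff = 0`` is the degenerate whole-period case
where every pair lands on the principal diagonal (``f2 = 0``, ``f3 = 1``,
``f5 = 1``).  The sign of the gradient only transposes the matrix and leaves
every feature unchanged, so ``nabla`` enters through its magnitude.

Because ``f1`` determines ``Ñg``, the laws can be inverted to estimate the
gradient magnitude from a measured Energy value; the floor in ``Ñg`` makes
the inverse a set of candidates rather than a single value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "ScalingPrediction",
    "DiagonalSplit",
    "effective_levels",
    "diagonal_split",
    "predict_asm",
    "predict_contrast",
    "predict_correlation",
    "predict_idm",
    "contrast_from_asm",
    "estimate_gradient",
    "refine_gradient",
    "predict_all",
]


def _validate(n_levels: int, nabla: int) -> int:
    """Return |nabla| after range checks."""
    nabla = abs(int(nabla))
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    if not (1 <= nabla <= n_levels - 1):
        raise ValueError(
            f"|nabla| must satisfy 1 <= |nabla| <= n_levels-1 = "
            f"{n_levels - 1}, got {nabla}"
        )
    return nabla


def effective_levels(n_levels: int, nabla: int) -> int:
    """Number of distinct levels on the gradient lattice, ``Ñg``.

    ``Ñg = 1 + floor((Ng-1)/|∇|)`` is both the period of the sawtooth in
    pixels and the number of nonzero co-occurrence entries, independent of
    the displacement.
    """
    nabla = _validate(n_levels, nabla)
    return 1 + (n_levels - 1) // nabla


class DiagonalSplit(NamedTuple):
    """How the nonzero co-occurrence entries split around the diagonal."""

    m1: int        # entries above the principal diagonal
    m2: int        # wrapped entries below it
    k_above: int   # their level offset j - i = +d_eff * |nabla|
    k_below: int   # wrapped offset j - i = -m1 * |nabla|
    degenerate: bool  # d a whole number of periods: all mass on the diagonal


def diagonal_split(n_levels: int, nabla: int, d: int) -> DiagonalSplit:
    """Split the ``Ñg`` nonzero entries into super- and sub-diagonal groups.

    ``m1 = Ñg - d_eff`` entries lie at offset ``+d_eff·|∇|`` above the
    principal diagonal; the ``m2 = d_eff`` entries that wrapped around the
    top of the gray-level range lie at offset ``-m1·|∇|`` below it.  When
    ``d`` is a whole number of periods the split is degenerate (flagged, not
    an error): every entry is on the principal diagonal.
    """
    nabla = _validate(n_levels, nabla)
    nt = effective_levels(n_levels, nabla)
    d_eff = d % nt
    if d_eff == 0:
        return DiagonalSplit(m1=0, m2=0, k_above=0, k_below=0, degenerate=True)
    m1 = nt - d_eff
    return DiagonalSplit(
        m1=m1, m2=d_eff, k_above=d_eff * nabla, k_below=-m1 * nabla, degenerate=False
    )


def predict_asm(n_levels: int, nabla: int) -> float:
    """Energy of a cyclic sawtooth gradient: ``f1 = 1/Ñg`` for any d."""
    return 1.0 / effective_levels(n_levels, nabla)


def predict_contrast(n_levels: int, nabla: int, d: int) -> float:
    """Contrast of a cyclic sawtooth gradient: ``f2 = ∇²·d_eff·(Ñg-d_eff)``."""
    nabla = _validate(n_levels, nabla)
    nt = effective_levels(n_levels, nabla)
    d_eff = d % nt
    return float(nabla**2 * d_eff * (nt - d_eff))


def predict_correlation(n_levels: int, nabla: int, d: int) -> float:
    """Correlation of a cyclic sawtooth gradient.

    ``f3 = 1 - 6·d_eff·(Ñg-d_eff) / ((Ñg-1)(Ñg+1))``; the gradient magnitude
    cancels.  Undefined (``nan``) when ``Ñg = 1`` (constant image).
    """
    nt = effective_levels(n_levels, nabla)
    if nt == 1:
        return float("nan")
    d_eff = d % nt
    return 1.0 - 6.0 * d_eff * (nt - d_eff) / ((nt - 1) * (nt + 1))


def predict_idm(n_levels: int, nabla: int, d: int, variant: str = "abs") -> float:
    """Inverse Difference Moment of a cyclic sawtooth gradient.

    The mass splits into ``Ñg - d_eff`` entries at offset ``d_eff·∇`` and
    ``d_eff`` entries at offset ``(Ñg - d_eff)·∇``, each carrying ``1/Ñg``::

        f5 = (1/Ñg) [ (Ñg-d)/(1 + d∇) + d/(1 + (Ñg-d)∇) ]        (abs)

    with ``1 + m`` replaced by ``1 + m²`` for the squared-weight variant.
    """
    nabla = _validate(n_levels, nabla)
    nt = effective_levels(n_levels, nabla)
    d_eff = d % nt
    if d_eff == 0:
        return 1.0
    off1 = d_eff * nabla
    off2 = (nt - d_eff) * nabla
    if variant == "abs":
        w1, w2 = 1.0 + off1, 1.0 + off2
    elif variant == "squared":
        w1, w2 = 1.0 + off1**2, 1.0 + off2**2
    else:
        raise ValueError(f"variant must be 'abs' or 'squared', got {variant!r}")
    return ((nt - d_eff) / w1 + d_eff / w2) / nt


def contrast_from_asm(f1: float, nabla: int, d: int) -> float:
    """Contrast inferred from Energy: ``f2 = ∇²·d·(1/f1 - d)``.

    Consistent with the direct law because ``1/f1 = Ñg`` on a sawtooth
    gradient; exposes the inverse Energy–Contrast relationship.
    """
    if not (0.0 < f1 <= 1.0):
        raise ValueError(f"f1 must be in (0, 1], got {f1}")
    return float(nabla**2) * d * (1.0 / f1 - d)


def estimate_gradient(f1: float, n_levels: int) -> set[int]:
    """Invert the Energy law: gradient magnitudes consistent with *f1*.

    Rounds ``1/f1`` to the nearest integer ``Ñg`` (requiring
    ``|1/f1 - Ñg| <= 0.5``) and returns every ``∇`` in ``[1, Ng-1]`` with
    ``1 + floor((Ng-1)/∇) = Ñg``.  The floor makes the answer a set: e.g.
    with ``Ng = 9`` both ``∇ = 3`` and ``∇ = 4`` give ``Ñg = 3``.  Empty set
    when no gradient magnitude is consistent.
    """
    if not (0.0 < f1 <= 1.0):
        raise ValueError(f"f1 must be in (0, 1], got {f1}")
    nt_hat = round(1.0 / f1)
    if nt_hat < 1 or abs(1.0 / f1 - nt_hat) > 0.5:
        return set()
    return {
        nabla
        for nabla in range(1, n_levels)
        if 1 + (n_levels - 1) // nabla == nt_hat
    }


def refine_gradient(f1: float, f2: float, n_levels: int, d: int, rtol: float = 1e-6) -> set[int]:
    """Narrow :func:`estimate_gradient` candidates using a Contrast value.

    Keeps only the candidates whose predicted Contrast at displacement *d*
    matches *f2* to relative tolerance *rtol*.  Contrast grows with ``∇²``
    at fixed ``d_eff``, so it separates candidates that Energy alone cannot.
    """
    candidates = estimate_gradient(f1, n_levels)
    return {
        nabla
        for nabla in candidates
        if abs(predict_contrast(n_levels, nabla, d) - f2)
        <= rtol * max(1.0, abs(f2))
    }


@dataclass(frozen=True)
class ScalingPrediction:
    """Bundle of analytic predictions for one ``(Ng, ∇, d)`` triple."""

    n_levels: int
    nabla: int
    d: int
    d_eff: int
    n_tilde: int
    m1: int
    m2: int
    k_above: int
    k_below: int
    f1: float
    f2: float
    f3: float
    f5_abs: float
    f5_sq: float
    degenerate: bool


def predict_all(n_levels: int, nabla: int, d: int) -> ScalingPrediction:
    """All symmetry quantities and feature predictions for one triple."""
    nabla_abs = _validate(n_levels, nabla)
    nt = effective_levels(n_levels, nabla_abs)
    split = diagonal_split(n_levels, nabla_abs, d)
    d_eff = d % nt
    return ScalingPrediction(
        n_levels=n_levels,
        nabla=nabla_abs,
        d=d,
        d_eff=d_eff,
        n_tilde=nt,
        m1=split.m1,
        m2=split.m2,
        k_above=split.k_above,
        k_below=split.k_below,
        f1=predict_asm(n_levels, nabla_abs),
        f2=predict_contrast(n_levels, nabla_abs, d),
        f3=predict_correlation(n_levels, nabla_abs, d),
        f5_abs=predict_idm(n_levels, nabla_abs, d, "abs"),
        f5_sq=predict_idm(n_levels, nabla_abs, d, "squared"),
        degenerate=split.degenerate,
    )
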