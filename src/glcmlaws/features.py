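"""Haralick texture features computed from a normalized co-occurrence matrix.

Four classical descriptors are implemented:

* ``asm`` — Energy / Angular Second Moment, ``f1 = Σ p(i,j)²``, a uniformity
  measure in ``[1/n_nonzero, 1]``;
* ``contrast`` — ``f2 = Σ_k k² p_{x-y}(k)``, the second moment of absolute
  gray-level differences;
* ``correlation`` — ``f3 = (Σ i·j·p(i,j) − μx·μy) / (σx·σy)``, the Pearson
  correlation of the level pair, undefined for constant images;
* ``homogeneity`` — the Inverse Difference Moment ``f5``, with either the
  ``1/(1+|i-j|)`` weight (common library "homogeneity") or Haralick's
  original ``1/(1+(i-j)²)`` weight.

Features are computed from the matrix exactly as stored — no implicit
symmetrization or requantization.  Two bit-depth normalization schemes are
provided: the scaling-law scheme (``f1·Ng``, ``f2/Ng``, ``f3`` and ``f5``
unchanged), and the empirical Löfstedt scheme (``f1·Ng²``, ``f2/Ng²``, and a
homogeneity weight rescaled to ``1/(1+((i-j)/Ng)²)``) included for
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .glcm import CoocMatrix, diff_histogram, marginals

__all__ = [
    "FeatureSet",
    "NormalizedFeatureSet",
    "asm",
    "contrast",
    "correlation",
    "homogeneity",
    "lofstedt_homogeneity",
    "compute_features",
    "normalize_features",
]


@dataclass(frozen=True)
class FeatureSet:
    """The four Haralick features of one co-occurrence matrix."""

    f1_asm: float
    f2_contrast: float
    f3_correlation: float
    f5_idm_abs: float
    f5_idm_sq: float
    n_levels: int


@dataclass(frozen=True)
class NormalizedFeatureSet:
    """Bit-depth-normalized feature values under a named scheme."""

    f1_tilde: float
    f2_tilde: float
    f3_tilde: float
    f5_tilde: float
    scheme: str
    n_levels: int


def _check(g: CoocMatrix) -> np.ndarray:
    if g.total == 0:
        raise ValueError("co-occurrence matrix is empty (total == 0)")
    return g.probs


def asm(g: CoocMatrix) -> float:
    """Energy / Angular Second Moment: sum of squared probabilities."""
    p = _check(g)
    return float(np.sum(p * p))


def contrast(g: CoocMatrix) -> float:
    """Second moment of the absolute gray-level difference distribution.

    Accumulated over the integer difference histogram and divided once at
    the end, so whole-period cyclic matrices reproduce the closed-form value
    exactly rather than to within a few ulp.
    """
    _check(g)
    hist = diff_histogram(g)
    k = np.arange(g.n_levels, dtype=np.int64)
    return int(k**2 @ hist) / g.total


def correlation(g: CoocMatrix) -> float:
    """Pearson correlation of the (reference, target) gray-level pair.

    Returns ``nan`` (with a warning) when either marginal is degenerate,
    i.e. for a constant image.
    """
    p = _check(g)
    m = marginals(g)
    if m.sigma_x == 0.0 or m.sigma_y == 0.0:
        warnings.warn(
            "correlation is undefined for a constant image (zero marginal "
            "standard deviation); returning nan",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    levels = np.arange(g.n_levels, dtype=float)
    cross = float(levels @ p @ levels)
    return (cross - m.mu_x * m.mu_y) / (m.sigma_x * m.sigma_y)


def homogeneity(g: CoocMatrix, variant: str = "abs") -> float:
    """Inverse Difference Moment.

    ``variant="abs"`` weights each entry by ``1/(1+|i-j|)``;
    ``variant="squared"`` uses Haralick's original ``1/(1+(i-j)²)``.
    The squared weight never exceeds the absolute one, so
    ``homogeneity(g, "squared") <= homogeneity(g, "abs")``.
    """
    p = _check(g)
    k = np.arange(g.n_levels)
    diff = np.abs(k[:, None] - k[None, :])
    if variant == "abs":
        w = 1.0 / (1.0 + diff)
    elif variant == "squared":
        w = 1.0 / (1.0 + diff.astype(float) ** 2)
    else:
        raise ValueError(f"variant must be 'abs' or 'squared', got {variant!r}")
    return float(np.sum(p * w))


def lofstedt_homogeneity(g: CoocMatrix) -> float:
    """Homogeneity with the level difference rescaled by the bit depth.

    Uses the weight ``1/(1+((i-j)/Ng)²)``.  Because the rescaled difference
    is at most 1, every weight lies in ``(1/2, 1]`` and the feature tends to
    ``Σ p(i,j) = 1`` from below as ``Ng`` grows; it is not identically 1.
    """
    p = _check(g)
    k = np.arange(g.n_levels, dtype=float)
    diff = (k[:, None] - k[None, :]) / g.n_levels
    return float(np.sum(p / (1.0 + diff**2)))


def compute_features(g: CoocMatrix) -> FeatureSet:
    """All four Haralick features of *g* (both homogeneity variants)."""
    return FeatureSet(
        f1_asm=asm(g),
        f2_contrast=contrast(g),
        f3_correlation=correlation(g),
        f5_idm_abs=homogeneity(g, "abs"),
        f5_idm_sq=homogeneity(g, "squared"),
        n_levels=g.n_levels,
    )


def normalize_features(
    fs: FeatureSet,
    scheme: str = "scaling",
    glcm: CoocMatrix | None = None,
) -> NormalizedFeatureSet:
    """Apply a bit-depth normalization scheme to a feature set.

    ``scheme="scaling"`` applies the factors derived from the linear-gradient
    scaling laws: ``f1·Ng``, ``f2/Ng``, ``f3`` and the absolute-weight ``f5``
    unchanged.  ``scheme="lofstedt"`` applies the empirical alternative
    ``f1·Ng²``, ``f2/Ng²``, ``f3`` unchanged, and recomputes homogeneity with
    the ``Ng``-rescaled weight — this last step needs the matrix itself, so
    *glcm* is required for that scheme.
    """
    ng = fs.n_levels
    if scheme == "scaling":
        return NormalizedFeatureSet(
            f1_tilde=fs.f1_asm * ng,
            f2_tilde=fs.f2_contrast / ng,
            f3_tilde=fs.f3_correlation,
            f5_tilde=fs.f5_idm_abs,
            scheme=scheme,
            n_levels=ng,
        )
    if scheme == "lofstedt":
        if glcm is None:
            raise ValueError(
                "the lofstedt scheme recomputes homogeneity from the "
                "co-occurrence matrix; pass glcm="
            )
        return NormalizedFeatureSet(
            f1_tilde=fs.f1_asm * ng**2,
            f2_tilde=fs.f2_contrast / ng**2,
            f3_tilde=fs.f3_correlation,
            f5_tilde=lofstedt_homogeneity(glcm),
            scheme=scheme,
            n_levels=ng,
        )
    raise ValueError(f"scheme must be 'scaling' or 'lofstedt', got {scheme!r}")
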