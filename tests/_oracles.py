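"""Independent brute-force reference implementations.

Deliberately written as plain double loops over pixels / matrix entries,
with no vectorization and no reuse of package code, so they can serve as
oracles for the fast implementations.
"""

from __future__ import annotations

import math

import numpy as np


def naive_glcm(pixels, n_levels, dx, dy, cyclic=False, symmetric=False):
    """O(Nx*Ny) pairwise counting, one pixel at a time."""
    pixels = np.asarray(pixels)
    ny, nx = pixels.shape
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    for y in range(ny):
        for x in range(nx):
            tx, ty = x + dx, y + dy
            if cyclic:
                tx %= nx
                ty %= ny
            elif not (0 <= tx < nx and 0 <= ty < ny):
                continue
            i = pixels[y, x]
            j = pixels[ty, tx]
            counts[i, j] += 1
            if symmetric:
                counts[j, i] += 1
    return counts


def naive_asm(probs):
    total = 0.0
    for row in probs:
        for p in row:
            total += p * p
    return total


def naive_contrast(probs):
    ng = len(probs)
    total = 0.0
    for i in range(ng):
        for j in range(ng):
            total += (i - j) ** 2 * probs[i][j]
    return total


def naive_correlation(probs):
    ng = len(probs)
    mu_x = mu_y = 0.0
    for i in range(ng):
        for j in range(ng):
            mu_x += i * probs[i][j]
            mu_y += j * probs[i][j]
    var_x = var_y = cross = 0.0
    for i in range(ng):
        for j in range(ng):
            var_x += (i - mu_x) ** 2 * probs[i][j]
            var_y += (j - mu_y) ** 2 * probs[i][j]
            cross += i * j * probs[i][j]
    if var_x == 0.0 or var_y == 0.0:
        return float("nan")
    return (cross - mu_x * mu_y) / (math.sqrt(var_x) * math.sqrt(var_y))


def naive_homogeneity(probs, squared=False):
    ng = len(probs)
    total = 0.0
    for i in range(ng):
        for j in range(ng):
            w = (i - j) ** 2 if squared else abs(i - j)
            total += probs[i][j] / (1 + w)
    return total
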