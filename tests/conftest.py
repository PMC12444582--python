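from __future__ import annotations

import numpy as np
import pytest

from glcmlaws import Displacement, GradientSpec, compute_glcm, make_linear_gradient


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def sawtooth_glcm(n_levels, nabla, d, periods=2, width=2, phase=0, cyclic=True):
    """Cyclic GLCM of a vertical sawtooth spanning a whole number of periods."""
    n_tilde = 1 + (n_levels - 1) // abs(nabla)
    spec = GradientSpec(
        nabla=abs(nabla),
        sign=1 if nabla > 0 else -1,
        n_levels=n_levels,
        phase=phase,
        width=width,
        height=n_tilde * periods,
    )
    img = make_linear_gradient(spec)
    return compute_glcm(img, Displacement(0, d), cyclic=cyclic)
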