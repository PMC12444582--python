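"""Invert the Energy scaling law to estimate a gradient magnitude.

Energy of a linear gradient is 1/n_tilde with n_tilde = 1+floor((Ng-1)/nabla),
so a measured Energy value constrains nabla.  The floor makes the inverse a
set; a Contrast value (which grows as nabla^2) disambiguates.
"""

from glcmlaws import (
    Displacement,
    GradientSpec,
    asm,
    compute_glcm,
    contrast,
    estimate_gradient,
    make_linear_gradient,
    refine_gradient,
)

ng, true_nabla = 9, 4
img = make_linear_gradient(GradientSpec(nabla=true_nabla, n_levels=ng, width=4, height=12))
g = compute_glcm(img, Displacement(0, 1), cyclic=True)

f1, f2 = asm(g), contrast(g)
candidates = estimate_gradient(f1, ng)
print(f"measured Energy {f1:.4f} -> candidate gradients {sorted(candidates)}")
# both 3 and 4 give n_tilde=3 when Ng=9: the inversion is non-unique

refined = refine_gradient(f1, f2, ng, d=1)
print(f"adding Contrast {f2:.1f} at d=1 -> {sorted(refined)} (true value {true_nabla})")
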