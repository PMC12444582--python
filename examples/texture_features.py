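"""Compute a co-occurrence matrix and Haralick features for one image.

Prints the raw features and both bit-depth normalization schemes.  The
scaling-law scheme multiplies Energy by Ng and divides Contrast by Ng,
which removes their leading dependence on the gray-level count.
"""

from glcmlaws import (
    Displacement,
    GradientSpec,
    compute_features,
    compute_glcm,
    make_linear_gradient,
    normalize_features,
)

# height 258 = 3 whole sawtooth periods (n_tilde = 86), so cyclic pairing is exact
img = make_linear_gradient(GradientSpec(nabla=3, n_levels=256, width=256, height=258))
g = compute_glcm(img, Displacement(0, 1), cyclic=True)
fs = compute_features(g)

print(f"Ng={fs.n_levels}, displacement (0,1), cyclic pairing")
print(f"  Energy (ASM)      f1 = {fs.f1_asm:.6f}   (= 1/n_tilde = 1/86)")
print(f"  Contrast          f2 = {fs.f2_contrast:.3f}")
print(f"  Correlation       f3 = {fs.f3_correlation:.6f}")
print(f"  Homogeneity |k|   f5 = {fs.f5_idm_abs:.6f}")
print(f"  Homogeneity k^2   f5 = {fs.f5_idm_sq:.6f}")

for scheme in ("scaling", "lofstedt"):
    n = normalize_features(fs, scheme, glcm=g)
    print(
        f"  [{scheme:8s}] f1~={n.f1_tilde:.4f}  f2~={n.f2_tilde:.4f}  "
        f"f3~={n.f3_tilde:.4f}  f5~={n.f5_tilde:.4f}"
    )
# Energy*Ng stays O(1) across bit depths; the lofstedt f1*Ng^2 overshoots.
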