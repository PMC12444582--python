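"""Generate a sawtooth gradient image and inspect its structure.

A linear gradient of magnitude nabla in an Ng-level image only visits the
lattice {0, nabla, 2*nabla, ...}; the pattern repeats every
n_tilde = 1 + floor((Ng-1)/nabla) pixels.
"""

import numpy as np

from glcmlaws import GradientSpec, make_linear_gradient, write_image

spec = GradientSpec(nabla=2, n_levels=7, width=8, height=12)
img = make_linear_gradient(spec)

print(f"gradient magnitude {spec.nabla} levels/pixel, Ng={spec.n_levels}")
print(f"period n_tilde = {spec.n_tilde} pixels")
print("first column:", img.pixels[:, 0].tolist())
print("distinct levels:", np.unique(img.pixels).tolist())
# -> the column cycles 0,2,4,6 every 4 rows; odd levels never occur.

write_image(img, "gradient_ng7.png")
print("wrote gradient_ng7.png")
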