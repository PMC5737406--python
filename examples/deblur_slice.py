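"""Slice-wise TVL2 deconvolution: blur a sharp slice, then restore it by ADMM.

The blur operator models the combined point-spread of acquisition, printing
and scanning as a Gaussian of variance 0.25 px^2; the restoration solves
min_x 1/2||y - Ax||^2 + lambda*TV(x) subject to x >= 0 with 10 scaled-ADMM
iterations (lambda = 5, rho = 0.5 on the 8-bit intensity scale).
"""

import numpy as np

from filmrecon.synth import PhantomSpec, make_phantom
from filmrecon.tv import BlurOperator, admm_tvl2

volume, _, _ = make_phantom(PhantomSpec(seed=0))
sharp = volume[35:40].mean(axis=0) * 255.0  # one thick slab, film intensity scale

op = BlurOperator(sigma2=0.25)
blurred = op.apply(sharp)
restored = admm_tvl2(blurred, op=op, lam=5.0, rho=0.5, n_iter=10)


def psnr(img):
    return 10 * np.log10(sharp.max() ** 2 / np.mean((img - sharp) ** 2))


print(f"PSNR blurred vs sharp:  {psnr(blurred):6.2f} dB")
print(f"PSNR restored vs sharp: {psnr(restored):6.2f} dB")
print("the gain is what matched-PSF deconvolution recovers; the non-negativity "
      "constraint keeps background exactly at 0 "
      f"(min restored = {restored.min():.3f})")
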