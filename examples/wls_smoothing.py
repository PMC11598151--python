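"""Edge-preserving WLS smoothing of a noisy step image.

Solves (I + lambda*L) u = y with gradient-adaptive weights: flat regions are
averaged hard, the step is left almost intact. This is the stage that cleans
the continuous detection map before Otsu binarization.
"""

import numpy as np

from omfwls import WlsParams, wls_filter
from omfwls.omf import DetectionMap

rng = np.random.default_rng(3)
clean = np.zeros((24, 24))
clean[:, 12:] = 1.0
noisy = clean + rng.normal(0, 0.05, size=clean.shape)

u = wls_filter(DetectionMap(noisy), WlsParams(lam=1.0, alpha=1.2)).scores

step_before = noisy[:, 13:23].mean() - noisy[:, 1:11].mean()
step_after = u[:, 13:23].mean() - u[:, 1:11].mean()
noise_before = (noisy - clean)[:, 1:10].std()
noise_after = (u - clean)[:, 1:10].std()

print(f"step magnitude:   {step_before:.3f} -> {step_after:.3f} "
      f"({100 * step_after / step_before:.0f}% retained)")
print(f"flat-region noise std: {noise_before:.4f} -> {noise_after:.4f} "
      f"({100 * (1 - noise_after / noise_before):.0f}% reduction)")
print("A good edge-preserving filter keeps most of the step while strongly "
      "suppressing noise in the flat regions.")
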