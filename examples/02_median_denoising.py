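"""Remove salt-and-pepper noise with the 3x3 median filter.

Corrupts a clean phantom at 10% density, filters it, and reports the mean
absolute error to the clean slice before and after — the filter should cut
the error by an order of magnitude while preserving edges.
"""

import numpy as np

from wavemri import PhantomParams, add_salt_pepper, make_phantom, median_filter

params = PhantomParams(seed=0, noise_density=0.0)
clean = make_phantom(params, label=0, seed=1).astype(float)
noisy = add_salt_pepper(clean, density=0.10, seed=2)
filtered = median_filter(noisy, window=3)

mae_before = np.abs(noisy - clean).mean()
mae_after = np.abs(filtered - clean).mean()
print(f"MAE vs clean slice, corrupted: {mae_before:6.3f}")
print(f"MAE vs clean slice, filtered:  {mae_after:6.3f}")
print("the median filter removes impulse noise almost completely;")
print("residual error comes from genuine fine texture it smooths away")
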