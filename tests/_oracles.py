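"""Independent brute-force oracles used by several test modules."""

import numpy as np


def brute_force_best_threshold_mask(pixels: np.ndarray) -> np.ndarray:
    """Naive scan of every integer cut for minimal within-cluster SS.

    Independent of the histogram/prefix-sum implementation in the package:
    recomputes both cluster sums from scratch at each candidate cut.
    """
    flat = pixels.astype(float).ravel()
    best_ss, best_cut = np.inf, None
    for cut in range(256):
        lo, hi = flat[flat <= cut], flat[flat > cut]
        if lo.size == 0 or hi.size == 0:
            continue
        ss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if ss < best_ss - 1e-9:
            best_ss, best_cut = ss, cut
    return pixels > best_cut
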