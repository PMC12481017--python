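"""Independent oracles shared across test modules."""

import numpy as np


def brute_force_smooth(scores, factor, n_flank):
    """Per-position weighted mean with truncation/renormalization, written
    independently of the vectorized implementation it checks."""
    s = np.asarray(scores, dtype=float)
    out = np.full(s.size, np.nan)
    for i in range(s.size):
        num = den = 0.0
        for k in range(-n_flank, n_flank + 1):
            j = i + k
            if 0 <= j < s.size and np.isfinite(s[j]):
                w = 1.0 if k == 0 else factor ** abs(k)
                num += w * s[j]
                den += w
        if den > 0:
            out[i] = num / den
    return out
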