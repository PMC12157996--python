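"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def grid_refine_diffusion(t, q, b_range=(0.0, 0.95), k_range=(1e-4, 1e-1)):
    """Minimise sum (ln(1-q) - [ln(1-b) - k t])^2 by nested grid refinement.

    Deliberately knows nothing about the closed-form regression solution;
    it only evaluates the same linearized objective on a shrinking grid.
    """
    y = np.log(1.0 - np.asarray(q, dtype=float))
    t = np.asarray(t, dtype=float)

    def sse(b, k):
        return np.sum((y - (np.log(1.0 - b) - k * t)) ** 2)

    b_lo, b_hi = b_range
    k_lo, k_hi = k_range
    best = (b_lo, k_lo)
    for _ in range(40):
        bs = np.linspace(b_lo, b_hi, 21)
        ks = np.linspace(k_lo, k_hi, 21)
        vals = np.array([[sse(b, k) for k in ks] for b in bs])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        best = (bs[i], ks[j])
        db, dk = bs[1] - bs[0], ks[1] - ks[0]
        b_lo, b_hi = max(0.0, bs[i] - db), min(0.999, bs[i] + db)
        k_lo, k_hi = max(1e-12, ks[j] - dk), ks[j] + dk
    return best
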