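"""Independent reference computations used by the test suite only.

These deliberately avoid the package's algorithms: the 2-means oracle
enumerates every 2-partition (not just sorted-contiguous ones) and the
Fisher oracle sums hypergeometric probabilities in exact rational
arithmetic.
"""

from fractions import Fraction
from math import comb

import numpy as np


def exhaustive_two_means_sse(values) -> float:
    """Minimum within-cluster SSE over all 2-partitions of the values."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    idx = np.arange(2 ** n, dtype=np.uint32)[:, None]
    bits = (idx >> np.arange(n)) & 1  # (2^n, n) membership matrix
    bits = bits[(bits[:, 0] == 0)]    # pin element 0 to cluster A
    k1 = bits.sum(axis=1)
    valid = (k1 > 0) & (k1 < n)
    bits, k1 = bits[valid], k1[valid]
    k0 = n - k1
    s1 = bits @ v
    q1 = bits @ (v * v)
    s0 = v.sum() - s1
    q0 = (v * v).sum() - q1
    sse = (q1 - s1**2 / k1) + (q0 - s0**2 / k0)
    return float(sse.min())


def exact_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact-rational hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    pmf = {
        k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))
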