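"""Independent reference implementations used only as test oracles.

These are deliberately naive, written straight from the definitions, and
share no code with the package.
"""

import numpy as np


def lz76_oracle(bits) -> int:
    """LZ76 exhaustive-history phrase count, by direct definition.

    At position p, grow the candidate phrase while it can be copied from
    the extended history (any occurrence starting before p); the phrase is
    the copied run plus one innovation symbol.  The final phrase may end
    without an innovation.
    """
    s = "".join(str(int(b)) for b in bits)
    n = len(s)
    c = 0
    p = 0
    while p < n:
        l = 0
        while p + l < n and s[p:p + l + 1] in s[:p + l]:
            l += 1
        c += 1
        p += l + 1
    return c


def apen_oracle(x, m: int = 2, r_frac: float = 0.2) -> float:
    """ApEn(m, r_frac * SD) by the direct O(N^2) formula (self-matches in,
    Chebyshev distance, natural log)."""
    x = np.asarray(x, dtype=float)
    N = x.size
    r = r_frac * x.std()

    def phi(m):
        M = N - m + 1
        templates = np.array([x[i:i + m] for i in range(M)])
        total = 0.0
        for i in range(M):
            d = np.max(np.abs(templates - templates[i]), axis=1)
            total += np.log(np.sum(d <= r) / M)
        return total / M

    return phi(m) - phi(m + 1)


def bh_oracle(p) -> np.ndarray:
    """Brute-force BH q-values: q(i) = min over j with p(j) >= p(i) of
    m * p(j) / rank(j), evaluated from the definition on the sorted list."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for idx in range(m):
        tail = [m * p[order[j]] / (j + 1) for j in range(idx, m)]
        q_sorted[idx] = min(1.0, min(tail))
    q = np.empty(m)
    q[order] = q_sorted
    return q
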