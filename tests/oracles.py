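"""Independent reference implementations used only by the tests.

These are written as plainly as possible (pure Python, no shared code with
the package kernels) so they can serve as oracles for the optimised
implementations.
"""

from __future__ import annotations

import math


def sw_affine_score(a: str, b: str, score, gap_open: int, gap_extend: int) -> int:
    """Naive affine-gap Smith-Waterman best local score.

    ``score(x, y)`` returns the substitution score for a residue pair.  A
    gap of length k costs gap_open + k * gap_extend.  Straightforward Gotoh
    recurrences over full Python-list matrices; O(n*m) time and memory.
    """
    n, m = len(a), len(b)
    NEG = -10 ** 9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          F[i][j - 1] - gap_extend)
            H[i][j] = max(0,
                          H[i - 1][j - 1] + score(a[i - 1], b[j - 1]),
                          E[i][j],
                          F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def t_sf_df2(t: float) -> float:
    """Two-tailed p-value of Student's t with 2 degrees of freedom.

    Closed form: P(T <= t) = 1/2 + t / (2 * sqrt(2 + t^2)).
    """
    return 2.0 * (0.5 - abs(t) / (2.0 * math.sqrt(2.0 + t * t)))


def window_entropy(residues: str) -> float:
    """Shannon entropy (bits) of the residue composition of a window."""
    h = 0.0
    n = len(residues)
    for c in set(residues):
        f = residues.count(c) / n
        h -= f * math.log2(f)
    return h
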