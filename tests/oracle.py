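"""Brute-force affine-gap alignment oracle.

A deliberately simple memoized recursion over (i, j, previous-state) that
scores global alignments with affine gaps and free terminal gaps on either
sequence.  Used only to validate the production DP: it shares the scoring
model but none of the implementation.
"""

from __future__ import annotations

import sys
from functools import lru_cache


def oracle_score(a: str, b: str, sub, gap_open: float,
                 gap_extend: float) -> float:
    """Best alignment score of a vs b.

    ``sub`` is a callable (res_a, res_b) -> score.  Terminal gaps (a prefix
    or suffix of either sequence left unaligned) are free; internal gaps
    cost open + (L-1)*extend, and a gap immediately following a gap in the
    other sequence pays a fresh open.
    """
    n, m = len(a), len(b)
    sys.setrecursionlimit(10000 + 4 * (n + 1) * (m + 1))

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == n or j == m:
            return 0.0  # the rest is a free terminal gap
        options = [sub(a[i], b[j]) + best(i + 1, j + 1, "M")]
        cost_d = gap_extend if state == "D" else gap_open
        options.append(-cost_d + best(i + 1, j, "D"))
        cost_i = gap_extend if state == "I" else gap_open
        options.append(-cost_i + best(i, j + 1, "I"))
        return max(options)

    # free leading gap in one sequence (not both)
    starts = [best(i0, 0, "M") for i0 in range(n + 1)]
    starts += [best(0, j0, "M") for j0 in range(m + 1)]
    result = max(starts)
    best.cache_clear()
    return result
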