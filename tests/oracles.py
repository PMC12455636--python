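"""Independent brute-force oracles used only by the test suite.

Deliberately naive implementations — plain dynamic programming, no
heuristics — against which the production alignment paths are checked.
"""

from __future__ import annotations

import numpy as np


def brute_force_infix_distance(barcode: str, read: str) -> tuple[int, int]:
    """Best Levenshtein distance of ``barcode`` against any substring of
    ``read``, enumerating every start; returns (distance, smallest start).

    For each start position a full edit-distance DP is run against the
    suffix and the minimum over all end positions taken.
    """
    m = len(barcode)
    best = (m, 0)  # empty-substring alignment costs len(barcode) deletions
    for start in range(len(read)):
        suffix = read[start : start + 2 * m]  # longer substrings only add cost
        prev = np.arange(len(suffix) + 1)  # NW row: substring is fixed at `start`
        for i, b in enumerate(barcode, start=1):
            cur = np.empty(len(suffix) + 1, dtype=int)
            cur[0] = i
            for j, c in enumerate(suffix, start=1):
                cur[j] = min(
                    prev[j] + 1,
                    cur[j - 1] + 1,
                    prev[j - 1] + (b != c),
                )
            prev = cur
        row_min = int(prev.min())
        if row_min < best[0]:
            best = (row_min, start)
    return best


def affine_sw_score(target: str, query: str, match=2, mismatch=-3,
                    gap_open=-4, gap_extend=-2) -> float:
    """Optimal local alignment score with affine gaps (open cost applies to
    the first gapped position, extend to each subsequent one)."""
    n, m = len(target), len(query)
    NEG = -1e9
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)  # gap in query (target consumed)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in target (query consumed)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if target[i - 1] == query[j - 1] else mismatch
            diag = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1], 0.0)
            M[i, j] = diag + s
            Ix[i, j] = max(M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend)
            Iy[i, j] = max(M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend)
            best = max(best, M[i, j], Ix[i, j], Iy[i, j])
    return best
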