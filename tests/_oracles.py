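"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

import numpy as np


class UnionFind:
    """Textbook disjoint-set forest, independent of the graph library."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def components(self) -> set[frozenset]:
        groups: dict = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return {frozenset(g) for g in groups.values()}


def smith_waterman_identity(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> tuple[float, float]:
    """Affine-gap local alignment by full dynamic programming.

    Returns (best score, identity = matches / alignment columns along the
    traceback of one optimal alignment).  Three-state DP with explicit
    state tracking; O(nm), used only on short sequences.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # alignment ends with gap in a
    F = np.full((n + 1, m + 1), NEG)  # alignment ends with gap in b
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            sub = match if ai == b[j - 1] else mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
    score = float(H.max())
    if score <= 0:
        return 0.0, 0.0
    i, j = map(int, np.unravel_index(int(np.argmax(H)), H.shape))
    state = "H"
    matches = columns = 0
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            sub = match if a[i - 1] == b[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + sub:
                matches += int(a[i - 1] == b[j - 1])
                columns += 1
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if E[i, j] == E[i, j - 1] + gap_extend:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:
            columns += 1
            if F[i, j] == F[i - 1, j] + gap_extend:
                i -= 1
            else:
                i -= 1
                state = "H"
    return score, matches / columns if columns else 0.0
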