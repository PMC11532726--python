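"""Independent brute-force reference implementations used only by tests."""

from __future__ import annotations


def sw_affine_bruteforce(q: str, s: str, score_of, gap_open: int, gap_extend: int) -> int:
    """Naive cubic-time Smith-Waterman with affine gaps (gap k costs open + k*ext).

    Returns the best local alignment score (0 if nothing positive). Kept
    deliberately simple and slow; independent of the production aligner.
    """
    n, m = len(q), len(s)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        row = H[i]
        prev = H[i - 1]
        for j in range(1, m + 1):
            v = prev[j - 1] + score_of((q[i - 1], s[j - 1]))
            if v < 0:
                v = 0
            for k in range(1, i + 1):
                cand = H[i - k][j] - gap_open - gap_extend * k
                if cand > v:
                    v = cand
            for k in range(1, j + 1):
                cand = row[j - k] - gap_open - gap_extend * k
                if cand > v:
                    v = cand
            row[j] = v
            if v > best:
                best = v
    return best


def overlap_groups_bruteforce(spans: list[tuple[int, int]]) -> list[set[int]]:
    """Transitive closure of pairwise span overlap (>= 1 shared base), O(n^2)."""
    n = len(spans)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = spans[i], spans[j]
            if min(e1, e2) >= max(s1, s2):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=lambda g: min(g))
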