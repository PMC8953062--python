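"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: the alignment oracle is
a full O(nm) three-matrix dynamic program, Shannon and UniFrac oracles are
direct summations, and the LCA oracle intersects explicit lineage lists.
"""

from __future__ import annotations

import math

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def affine_local_score_one_strand(
    a: str, b: str, match: int, mismatch: int, gap_open: int, gap_extend: int
) -> int:
    """Full-matrix affine-gap Smith-Waterman; a gap of length L costs
    gap_open + L * gap_extend.  N never matches anything."""
    n, m = len(a), len(b)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open + gap_extend)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open + gap_extend)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGT") else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def affine_local_score(a, b, match=2, mismatch=-4, gap_open=-4, gap_extend=-2) -> int:
    return max(
        affine_local_score_one_strand(a, b, match, mismatch, gap_open, gap_extend),
        affine_local_score_one_strand(revcomp(a), b, match, mismatch, gap_open, gap_extend),
    )


def shannon_direct(fractions) -> float:
    return -sum(p * math.log(p) for p in fractions if p > 0)


def lca_bruteforce(tree, ids) -> int:
    """Deepest common element of explicit root-to-node paths."""
    paths = []
    for i in ids:
        path = []
        cur = i
        while True:
            path.append(cur)
            if cur == tree.root_id:
                break
            cur = tree.parent(cur)
        paths.append(list(reversed(path)))
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    # deepest = the common node with the longest own path
    return max(common, key=lambda c: paths[0].index(c))


def weighted_unifrac_direct(tree, pa: dict, pb: dict, normalized: bool) -> float:
    """Branch-by-branch summation on an skbio TreeNode."""
    raw = 0.0
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        fa = sum(pa.get(t, 0.0) for t in tips)
        fb = sum(pb.get(t, 0.0) for t in tips)
        raw += (node.length or 0.0) * abs(fa - fb)
    if not normalized:
        return raw
    denom = 0.0
    for tip in tree.tips():
        d = 0.0
        node = tip
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        denom += d * (pa.get(tip.name, 0.0) + pb.get(tip.name, 0.0))
    return raw / denom if denom else 0.0
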