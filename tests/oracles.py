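"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementation: the
aligner oracle is a full dynamic-programming scan over all references and
offsets, the adapter oracle a naive position scan, and the clustering
oracle a union-find over the complete pairwise distance matrix.
"""

from __future__ import annotations

import numpy as np


def dp_edit_distance(a: str, b: str, sub=None) -> int:
    """Plain full-matrix Levenshtein distance. ``sub(x, y)`` may override
    the substitution cost (for asymmetric bisulfite matching)."""
    if sub is None:
        sub = lambda x, y: 0 if x == y else 1
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + sub(a[i - 1], b[j - 1]),
            )
        prev = cur
    return prev[m]


def semiglobal_best_distance(read: str, ref: str, bisulfite: bool = False) -> int:
    """Best edit distance of ``read`` placed anywhere inside ``ref`` (read
    fully aligned, reference overhangs free): full DP, no banding."""
    sub = None
    if bisulfite:
        sub = lambda x, y: 0 if (x == y or (x == "T" and y == "C")) else 1
    n, m = len(read), len(ref)
    prev = [0] * (m + 1)  # free leading reference gap
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (sub(read[i - 1], ref[j - 1]) if sub else (0 if read[i - 1] == ref[j - 1] else 1)),
            )
        prev = cur
    return min(prev)  # free trailing reference gap


def oracle_best_hits(read: str, refs: dict[str, str], max_edits: int, bisulfite: bool = False):
    """(best distance, set of co-optimal reference ids), or (None, set())."""
    dists = {rid: semiglobal_best_distance(read, seq, bisulfite) for rid, seq in refs.items()}
    best = min(dists.values())
    if best > max_edits:
        return None, set()
    return best, {rid for rid, d in dists.items() if d == best}


def oracle_find_adapter(seq: str, adapter: str, start: int, min_overlap: int):
    """Naive leftmost adapter-prefix scan with 1 mismatch per 10 compared
    bases allowed."""
    for j in range(start, len(seq) - min(min_overlap, len(adapter)) + 1):
        span = min(len(adapter), len(seq) - j)
        mism = sum(1 for k in range(span) if seq[j + k] != adapter[k])
        if mism <= span // 10:
            return j
    return None


def oracle_similarity_clusters(seqs: dict[str, str], max_diff: int) -> set[frozenset[str]]:
    """Union-find over the full pairwise edit-distance matrix."""
    ids = sorted(seqs)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if dp_edit_distance(seqs[a], seqs[b]) <= max_diff:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    groups: dict[str, set[str]] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def random_refs(rng: np.random.Generator, n_refs: int, min_len: int = 60, max_len: int = 120) -> dict[str, str]:
    return {
        f"r{i}": "".join(rng.choice(list("ACGT"), size=rng.integers(min_len, max_len + 1)))
        for i in range(n_refs)
    }


def mutate(rng: np.random.Generator, seq: str, n_edits: int) -> str:
    s = list(seq)
    for _ in range(n_edits):
        kind = rng.integers(3)
        pos = int(rng.integers(len(s)))
        if kind == 0:
            s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
        elif kind == 1 and len(s) > 20:
            del s[pos]
        else:
            s.insert(pos, rng.choice(list("ACGT")))
    return "".join(s)
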