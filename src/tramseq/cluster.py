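"""Two-stage clustering of tRNA references.

Stage 1 merges references by sequence similarity: any pair within
``max_seq_diff`` edits (edit distance, so length variants are covered) is
joined, with single-linkage transitive closure. Stage 2 merges clusters by
the extent of multimapping observed in the demethylated libraries: a
cluster whose best-hit reads are mostly (strictly more than
``shared_read_frac``) also co-optimal in a larger cluster is absorbed into
that cluster, smallest clusters first, iterated to a fixpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd

from .align import AlignmentRecord
from .reference import ReferenceSet, sprinzl_key


@dataclass
class ClusterParams:
    max_seq_diff: int = 3
    shared_read_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.max_seq_diff < 0:
            raise ValueError("max_seq_diff must be >= 0")
        if not 0 < self.shared_read_frac <= 1:
            raise ValueError("shared_read_frac must be in (0, 1]")


@dataclass
class Cluster:
    cluster_id: str
    member_ref_ids: list[str]
    read_count: int = 0


class ClusterSet:
    """Disjoint partition of references into clusters."""

    def __init__(self, clusters: Iterable[Cluster]):
        self.clusters: list[Cluster] = list(clusters)
        self._by_ref: dict[str, str] = {}
        for cl in self.clusters:
            for r in cl.member_ref_ids:
                if r in self._by_ref:
                    raise ValueError(f"reference {r} in more than one cluster")
                self._by_ref[r] = cl.cluster_id

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def __getitem__(self, cluster_id: str) -> Cluster:
        for cl in self.clusters:
            if cl.cluster_id == cluster_id:
                return cl
        raise KeyError(cluster_id)

    def cluster_of(self, ref_id: str) -> str:
        return self._by_ref[ref_id]

    @property
    def cluster_ids(self) -> list[str]:
        return [cl.cluster_id for cl in self.clusters]

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"cluster_id": cl.cluster_id, "ref_id": r} for cl in self.clusters for r in cl.member_ref_ids]
        )


def _cluster_name(member_refs, refset: ReferenceSet) -> str:
    """Join member identities: anticodons within an amino acid are joined
    with '/', distinct amino-acid groups with '_' (e.g. "Gln-CTG/TTG",
    "Lys-TTT_Sup-TTA")."""
    by_aa: dict[str, set[str]] = {}
    for r in member_refs:
        by_aa.setdefault(refset[r].amino_acid, set()).add(refset[r].anticodon)
    parts = [f"{aa}-{'/'.join(sorted(acs))}" for aa, acs in sorted(by_aa.items())]
    prefix = "mt-" if all(refset[r].origin == "mito" for r in member_refs) else ""
    return prefix + "_".join(parts)


def _unique_names(groups: Sequence[list[str]], refset: ReferenceSet) -> list[str]:
    names = [_cluster_name(g, refset) for g in groups]
    seen: dict[str, int] = {}
    out = []
    for n in names:
        seen[n] = seen.get(n, 0) + 1
        out.append(n if seen[n] == 1 else f"{n}.{seen[n]}")
    return out


def cluster_by_similarity(refset: ReferenceSet, params: ClusterParams | None = None) -> ClusterSet:
    """Single-linkage merge of references within ``max_seq_diff`` edits."""
    params = params or ClusterParams()
    ids = refset.ref_ids
    parent = {r: r for r in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = edlib.align(refset[a].mature_seq, refset[b].mature_seq,
                            mode="NW", k=params.max_seq_diff)["editDistance"]
            if 0 <= d <= params.max_seq_diff:
                parent[find(a)] = find(b)

    groups: dict[str, list[str]] = {}
    for r in ids:
        groups.setdefault(find(r), []).append(r)
    members = [sorted(g) for g in groups.values()]
    members.sort()
    names = _unique_names(members, refset)
    return ClusterSet(Cluster(n, m) for n, m in zip(names, members))


def refine_clusters_by_multimapping(
    clusters: ClusterSet,
    records_by_read: Mapping[str, Sequence[AlignmentRecord]],
    params: ClusterParams | None = None,
    refset: ReferenceSet | None = None,
) -> ClusterSet:
    """Absorb clusters dominated by cross-cluster multimappers.

    For each cluster c, shared(c->d) is the fraction of reads with a
    co-optimal hit in c that also have one in d. If the largest such
    fraction over bigger clusters (by read count) strictly exceeds
    ``shared_read_frac``, c merges into the argmax (ties resolved toward
    the larger read count, then the lexicographically smaller id).
    Smallest clusters are considered first and the rule is iterated to a
    fixpoint; merged clusters pool their mapping results.
    """
    params = params or ClusterParams()
    membership: dict[str, list[str]] = {cl.cluster_id: list(cl.member_ref_ids) for cl in clusters}
    ref_cluster = {r: cl.cluster_id for cl in clusters for r in cl.member_ref_ids}
    read_refsets = [tuple({rec.ref_id for rec in recs}) for recs in records_by_read.values()]

    def counts_and_overlap():
        counts: dict[str, int] = {c: 0 for c in membership}
        overlap: dict[tuple[str, str], int] = {}
        for refs in read_refsets:
            cset = {ref_cluster[r] for r in refs if r in ref_cluster}
            for c in cset:
                counts[c] += 1
            for c in cset:
                for d in cset:
                    if c != d:
                        overlap[(c, d)] = overlap.get((c, d), 0) + 1
        return counts, overlap

    changed = True
    while changed and len(membership) > 1:
        changed = False
        counts, overlap = counts_and_overlap()
        for c in sorted(membership, key=lambda x: (counts[x], x)):
            n_c = counts[c]
            if n_c == 0:
                continue
            candidates = [
                (overlap.get((c, d), 0) / n_c, counts[d], d)
                for d in membership
                if d != c and counts[d] > counts[c]
            ]
            if not candidates:
                continue
            frac, _, best = min(candidates, key=lambda t: (-t[0], -t[1], t[2]))
            if frac > params.shared_read_frac:
                membership[best].extend(membership.pop(c))
                for r in membership[best]:
                    ref_cluster[r] = best
                changed = True
                break  # recompute counts after each merge

    groups = [sorted(m) for m in membership.values()]
    groups.sort()
    counts, _ = counts_and_overlap()
    if refset is not None:
        names = _unique_names(groups, refset)
    else:
        old = {tuple(sorted(cl.member_ref_ids)): cl.cluster_id for cl in clusters}
        names = [old.get(tuple(g), "+".join(g)) for g in groups]
    out = []
    for n, g in zip(names, groups):
        n_reads = sum(1 for refs in read_refsets if any(r in g for r in refs))
        out.append(Cluster(n, g, read_count=n_reads))
    return ClusterSet(out)


def cluster_composition(cluster: Cluster, refset: ReferenceSet) -> pd.DataFrame:
    """Per canonical label, the member base multiset of a cluster.

    A member lacking a label contributes the absence marker "." — this is
    what flags intra-cluster variable positions (and length variants) for
    coverage-plot shading.
    """
    labels: set[str] = set()
    maps = {}
    for r in cluster.member_ref_ids:
        ref = refset[r]
        lab2idx = {lab: i for i, lab in ref.canonical_map.items()}
        maps[r] = lab2idx
        labels.update(lab2idx)
    rows = []
    for lab in sorted(labels, key=sprinzl_key):
        bases: dict[str, int] = {}
        for r in cluster.member_ref_ids:
            idx = maps[r].get(lab)
            b = refset[r].mature_seq[idx] if idx is not None else "."
            bases[b] = bases.get(b, 0) + 1
        for b, n in sorted(bases.items()):
            rows.append({"cluster_id": cluster.cluster_id, "canonical_label": lab, "base": b, "n_members": n})
    return pd.DataFrame(rows, columns=["cluster_id", "canonical_label", "base", "n_members"])


def composition_table(clusters: ClusterSet, refset: ReferenceSet) -> pd.DataFrame:
    frames = [cluster_composition(cl, refset) for cl in clusters]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
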