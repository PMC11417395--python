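"""Cluster and reference abundance from demethylated-library alignments.

Multimapping reads are resolved by seeded uniform random assignment among
their co-optimal hits. The per-read draw is keyed on (seed, read_id) via a
cryptographic hash rather than a shared RNG stream, so the assignment is
reproducible, order-independent, and stable under parallel processing.
Abundances are reported as fractions of total mapped reads (the primary
output) alongside reads-per-million.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentRecord
from .cluster import ClusterSet
from .reference import ReferenceSet


def _draw(seed: int, read_id: str, n: int) -> int:
    h = hashlib.blake2b(f"{seed}:{read_id}".encode(), digest_size=8).digest()
    return int.from_bytes(h, "big") % n


def assign_multimappers(
    records_by_read: Mapping[str, Sequence[AlignmentRecord]],
    seed: int,
) -> list[AlignmentRecord]:
    """One uniquely-assigned record per read, drawn uniformly among its
    co-optimal hits with a per-read seeded hash."""
    assigned = []
    for read_id, records in records_by_read.items():
        if len(records) == 1:
            assigned.append(records[0])
            continue
        ordered = sorted(records, key=lambda r: (r.ref_id, r.ref_start))
        assigned.append(ordered[_draw(seed, read_id, len(ordered))])
    return assigned


@dataclass
class AbundanceResult:
    """Sample x cluster abundance fractions plus per-reference deconvolution."""

    cluster_fractions: pd.DataFrame  # rows sample, columns cluster_id
    ref_fractions: pd.DataFrame  # rows sample, columns ref_id
    rpm: pd.DataFrame  # cluster RPM
    total_mapped: pd.Series  # per sample
    seed: int | None = None


def abundance_table(
    assigned_by_sample: Mapping[str, Sequence[AlignmentRecord]],
    clusters: ClusterSet,
    seed: int | None = None,
) -> AbundanceResult:
    """Per-sample cluster fractions: per-reference counts summed per
    cluster and divided by the sample's total mapped reads."""
    cluster_ids = clusters.cluster_ids
    samples = list(assigned_by_sample)
    ref_counts = {}
    for sample, records in assigned_by_sample.items():
        if len(records) == 0:
            raise ValueError(f"sample {sample!r} has zero mapped reads")
        counts: dict[str, int] = {}
        for rec in records:
            counts[rec.ref_id] = counts.get(rec.ref_id, 0) + 1
        ref_counts[sample] = counts
    all_refs = sorted({r for c in ref_counts.values() for r in c})
    ref_df = pd.DataFrame(
        [[ref_counts[s].get(r, 0) for r in all_refs] for s in samples],
        index=samples, columns=all_refs, dtype=float,
    )
    totals = ref_df.sum(axis=1)
    ref_frac = ref_df.div(totals, axis=0)
    cl_frac = pd.DataFrame(0.0, index=samples, columns=cluster_ids)
    for r in all_refs:
        cl_frac[clusters.cluster_of(r)] += ref_frac[r]
    return AbundanceResult(
        cluster_fractions=cl_frac,
        ref_fractions=ref_frac,
        rpm=cl_frac * 1e6,
        total_mapped=totals.astype(int),
        seed=seed,
    )


def per_reference_counts(assigned: Sequence[AlignmentRecord]) -> pd.Series:
    counts: dict[str, int] = {}
    for rec in assigned:
        counts[rec.ref_id] = counts.get(rec.ref_id, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def anticodon_family_abundance(
    assigned: Sequence[AlignmentRecord],
    refset: ReferenceSet,
) -> pd.Series:
    """Fraction of genomic (nuclear) tRNA reads per anticodon family.

    Mitochondrial references are excluded from both numerator and
    denominator; fractions sum to 1 over anticodons."""
    counts: dict[str, int] = {}
    total = 0
    for rec in assigned:
        ref = refset[rec.ref_id]
        if ref.origin != "nuclear":
            continue
        counts[ref.anticodon] = counts.get(ref.anticodon, 0) + 1
        total += 1
    if total == 0:
        return pd.Series(dtype=float)
    return (pd.Series(counts, dtype=float) / total).sort_index()


def mito_pool_abundance(
    assigned: Sequence[AlignmentRecord],
    refset: ReferenceSet,
) -> pd.Series:
    """Individual mitochondrial tRNA fractions over the mitochondrial pool
    (the organellar-normalized view)."""
    counts: dict[str, int] = {}
    total = 0
    for rec in assigned:
        ref = refset[rec.ref_id]
        if ref.origin != "mito":
            continue
        counts[ref.ref_id] = counts.get(ref.ref_id, 0) + 1
        total += 1
    if total == 0:
        return pd.Series(dtype=float)
    return (pd.Series(counts, dtype=float) / total).sort_index()


def write_abundance(result: AbundanceResult, prefix: str) -> None:
    """Write wide and long cluster tables, RPM, and the per-reference
    deconvolution as TSV files under the given path prefix."""
    result.cluster_fractions.rename_axis("sample").to_csv(f"{prefix}.clusters.tsv", sep="\t")
    result.rpm.rename_axis("sample").to_csv(f"{prefix}.rpm.tsv", sep="\t")
    result.ref_fractions.rename_axis("sample").to_csv(f"{prefix}.refs.tsv", sep="\t")
    long = result.cluster_fractions.rename_axis("sample").reset_index().melt(
        id_vars="sample", var_name="cluster_id", value_name="fraction"
    )
    long.to_csv(f"{prefix}.long.tsv", sep="\t", index=False)
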