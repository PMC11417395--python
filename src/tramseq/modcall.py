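"""Modification signatures at canonical positions, per cluster.

Three read-level signals are turned into per-cluster, per-canonical-position
profiles:

* misincorporation — reads whose observed base differs from their assigned
  reference's base (intra-cluster reference variants are therefore not
  mismatches); deletions count toward the mismatch tally. Rates aggregate
  across cluster members by summing mismatch and coverage counts at
  equivalent (same canonical label) positions before dividing.
* RT stops — reverse transcription halting AT position N produces a read
  whose 5'-most mapped base is N+1 (cDNA is synthesised 3'->5'), so
  stop(N) = read starts at N+1 / coverage at N+1, aggregated per label.
* bisulfite C retention — at reference Cs, retained Cs over retained Cs
  plus converted Ts; the cluster-level rule also counts read Ts mapped to
  reference Ts in the denominator, which deflates retention at positions
  where members disagree (a known caveat of the clustered view).

Cells with coverage below ``min_cov`` are reported as missing (NaN), never
as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import PositionStats
from .cluster import Cluster, ClusterSet
from .reference import BASE_INDEX, BASES, ReferenceSet, sprinzl_key

PileupsBySample = Mapping[str, Mapping[str, PositionStats]]


def _member_positions(cluster: Cluster, refset: ReferenceSet) -> dict[str, list[tuple[str, int]]]:
    """canonical label -> [(ref_id, index)] over cluster members."""
    out: dict[str, list[tuple[str, int]]] = {}
    for r in cluster.member_ref_ids:
        for i, lab in refset[r].canonical_map.items():
            out.setdefault(lab, []).append((r, i))
    return out


def misincorporation_profile(
    pileups_by_sample: PileupsBySample,
    clusters: ClusterSet,
    refset: ReferenceSet,
    min_cov: int = 20,
    count_deletions: bool = True,
) -> pd.DataFrame:
    """Long-format misincorporation rates per (cluster, canonical label,
    sample), with coverage and the dominant mismatched base."""
    rows = []
    for cluster in clusters:
        positions = _member_positions(cluster, refset)
        for lab in sorted(positions, key=sprinzl_key):
            members = positions[lab]
            ref_bases = "".join(sorted({refset[r].mature_seq[i] for r, i in members}))
            for sample, pileups in pileups_by_sample.items():
                cov = 0
                mismatch = 0
                mis_bases = np.zeros(4, dtype=np.int64)
                for r, i in members:
                    st = pileups.get(r)
                    if st is None:
                        continue
                    c = int(st.coverage[i])
                    ref_idx = BASE_INDEX[refset[r].mature_seq[i]]
                    m = c - int(st.base_counts[i, ref_idx])
                    if not count_deletions:
                        m -= int(st.deletion_count[i])
                        c -= int(st.deletion_count[i])
                    cov += c
                    mismatch += m
                    mis_bases += st.base_counts[i]
                    mis_bases[ref_idx] -= st.base_counts[i, ref_idx]
                rate = mismatch / cov if cov >= min_cov else np.nan
                top = BASES[int(mis_bases.argmax())] if mis_bases.sum() > 0 else ""
                rows.append({
                    "cluster_id": cluster.cluster_id, "canonical_label": lab, "sample": sample,
                    "metric": "misincorporation", "value": rate, "coverage": cov,
                    "mismatch_count": mismatch, "ref_bases": ref_bases, "top_mismatch_base": top,
                })
    return pd.DataFrame(rows)


def rt_stop_profile(
    pileups_by_sample: PileupsBySample,
    clusters: ClusterSet,
    refset: ReferenceSet,
    min_cov: int = 20,
) -> pd.DataFrame:
    """RT-stop fraction per (cluster, canonical label, sample):
    reads starting one nucleotide downstream (+1 in reference coordinates)
    over the coverage of that downstream position."""
    rows = []
    for cluster in clusters:
        positions = _member_positions(cluster, refset)
        for lab in sorted(positions, key=sprinzl_key):
            members = positions[lab]
            for sample, pileups in pileups_by_sample.items():
                starts = 0
                cov_down = 0
                defined = False
                for r, i in members:
                    st = pileups.get(r)
                    if st is None or i + 1 >= len(st):
                        continue
                    defined = True
                    starts += int(st.read_start_count[i + 1])
                    cov_down += int(st.coverage[i + 1])
                value = starts / cov_down if defined and cov_down >= min_cov else np.nan
                rows.append({
                    "cluster_id": cluster.cluster_id, "canonical_label": lab, "sample": sample,
                    "metric": "rt_stop", "value": value, "coverage": cov_down,
                })
    return pd.DataFrame(rows)


def retention_per_reference(stats: PositionStats, ref_seq: str) -> np.ndarray:
    """Single-reference C-retention: at reference Cs, read C count over
    read C + T count; NaN elsewhere or at zero denominator."""
    out = np.full(len(ref_seq), np.nan)
    for i, b in enumerate(ref_seq):
        if b != "C":
            continue
        n_c = stats.base_counts[i, BASE_INDEX["C"]]
        n_t = stats.base_counts[i, BASE_INDEX["T"]]
        if n_c + n_t > 0:
            out[i] = n_c / (n_c + n_t)
    return out


def c_retention_profile(
    pileups_by_sample: PileupsBySample,
    clusters: ClusterSet,
    refset: ReferenceSet,
    min_cov: int = 20,
) -> pd.DataFrame:
    """Cluster-level bisulfite C-retention per canonical label.

    Counted Cs: read Cs mapped to a reference C. Counted Ts: read Ts mapped
    to a reference C or T. Retention = Cs / (Cs + Ts); other read bases are
    excluded from both counts. Labels with no member C are omitted."""
    rows = []
    for cluster in clusters:
        positions = _member_positions(cluster, refset)
        for lab in sorted(positions, key=sprinzl_key):
            members = positions[lab]
            member_bases = {refset[r].mature_seq[i] for r, i in members}
            if "C" not in member_bases:
                continue
            for sample, pileups in pileups_by_sample.items():
                n_c = 0
                n_t = 0
                for r, i in members:
                    st = pileups.get(r)
                    if st is None:
                        continue
                    base = refset[r].mature_seq[i]
                    if base == "C":
                        n_c += int(st.base_counts[i, BASE_INDEX["C"]])
                        n_t += int(st.base_counts[i, BASE_INDEX["T"]])
                    elif base == "T":
                        n_t += int(st.base_counts[i, BASE_INDEX["T"]])
                denom = n_c + n_t
                value = n_c / denom if denom >= min_cov else np.nan
                rows.append({
                    "cluster_id": cluster.cluster_id, "canonical_label": lab, "sample": sample,
                    "metric": "c_retention", "value": value, "coverage": denom,
                })
    return pd.DataFrame(rows)


def classify_sites(
    mock_profile: pd.DataFrame,
    dm_profile: pd.DataFrame,
    min_rate: float = 0.15,
    drop_frac: float = 0.5,
) -> pd.DataFrame:
    """Differential mock-vs-DM classification of candidate sites.

    A site enters the table when its mock misincorporation rate reaches
    ``min_rate`` in at least one sample. It is demethylation_sensitive when
    the mean DM rate falls below ``drop_frac`` times the mean mock rate
    (methylation-type candidates: m1A/m1G/m3C/m2,2G), otherwise
    demethylation_resistant (editing/acp3U/bulky candidates). Resistant
    sites at an encoded A34 with dominant G misincorporation are flagged
    inosine_consistent."""
    key = ["cluster_id", "canonical_label"]

    def agg(df: pd.DataFrame) -> pd.DataFrame:
        g = df.groupby(key, sort=False)
        out = g["value"].agg(["mean", "max"]).rename(columns={"mean": "mean_rate", "max": "max_rate"})
        out["top_mismatch_base"] = g["top_mismatch_base"].agg(
            lambda s: s.mode().iloc[0] if not s.mode().empty else ""
        )
        out["ref_bases"] = g["ref_bases"].first()
        return out.reset_index()

    mock = agg(mock_profile.dropna(subset=["value"]))
    dm = agg(dm_profile.dropna(subset=["value"]))
    merged = mock.merge(dm, on=key, how="left", suffixes=("_mock", "_dm"))
    merged = merged[merged["max_rate_mock"] >= min_rate].copy()
    dm_rate = merged["mean_rate_dm"].fillna(0.0)
    sensitive = dm_rate < drop_frac * merged["mean_rate_mock"]
    merged["classification"] = np.where(sensitive, "demethylation_sensitive", "demethylation_resistant")
    merged["inosine_consistent"] = (
        ~sensitive
        & (merged["canonical_label"] == "34")
        & (merged["ref_bases_mock"] == "A")
        & (merged["top_mismatch_base_mock"] == "G")
    )
    cols = key + ["mean_rate_mock", "max_rate_mock", "mean_rate_dm", "classification", "inosine_consistent"]
    return merged[cols].reset_index(drop=True)


def profile_matrix(profile: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Wide heat-map matrix: rows cluster, columns canonical labels in
    Sprinzl order, values averaged over samples."""
    wide = profile.pivot_table(index="cluster_id", columns="canonical_label", values=value, aggfunc="mean")
    return wide[sorted(wide.columns, key=sprinzl_key)]


def plot_cluster_coverage(
    pileups: Mapping[str, PositionStats],
    cluster: Cluster,
    refset: ReferenceSet,
    path: str | Path,
    title: str | None = None,
) -> None:
    """Stacked per-base coverage along canonical positions for one cluster
    (light = matches the member reference, dark = mismatch)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    positions = _member_positions(cluster, refset)
    labels = sorted(positions, key=sprinzl_key)
    match = np.zeros(len(labels))
    mismatch = np.zeros(len(labels))
    dele = np.zeros(len(labels))
    for k, lab in enumerate(labels):
        for r, i in positions[lab]:
            st = pileups.get(r)
            if st is None:
                continue
            ref_idx = BASE_INDEX[refset[r].mature_seq[i]]
            match[k] += st.base_counts[i, ref_idx]
            mismatch[k] += st.base_counts[i].sum() - st.base_counts[i, ref_idx]
            dele[k] += st.deletion_count[i]
    fig, ax = plt.subplots(figsize=(max(6, len(labels) / 6), 3))
    x = np.arange(len(labels))
    ax.bar(x, match, color="#9ecae1", label="match")
    ax.bar(x, mismatch, bottom=match, color="#08519c", label="mismatch")
    ax.bar(x, dele, bottom=match + mismatch, color="#bdbdbd", label="deletion")
    step = max(1, len(labels) // 25)
    ax.set_xticks(x[::step])
    ax.set_xticklabels(labels[::step], rotation=90, fontsize=6)
    ax.set_ylabel("reads")
    ax.set_title(title or cluster.cluster_id)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_profiles(profiles: Sequence[pd.DataFrame], path: str | Path) -> None:
    """Concatenate long-format profile tables into one TSV."""
    cols = ["cluster_id", "canonical_label", "sample", "metric", "value", "coverage"]
    df = pd.concat([p[[c for c in cols if c in p.columns]] for p in profiles], ignore_index=True)
    df.to_csv(path, sep="\t", index=False)
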