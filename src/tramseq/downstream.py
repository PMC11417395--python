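"""Genome-context and codon-usage analyses downstream of quantification.

Genome context: tRNA genes of maternally deposited (early-expressed)
isodecoders tend to sit in tandem repetitive arrays, while isodecoders
switched on later in development are isolated. For each expressed
isodecoder the mean number of predicted tRNA genes within a +/-5 kb window
of its gene copies is compared between the early and late groups (late =
at least a ``late_fold`` increase between the two stages) with a two-sided
Mann-Whitney U test.

Codon usage: per-sample codon frequencies are expression-weighted over
representative coding sequences, mapped to anticodon families through a
wobble decoding table, and correlated (Pearson) with anticodon-family tRNA
abundance, per stage and across the time course with Holm-Bonferroni
correction.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("tramseq.downstream")


# ---------------------------------------------------------------------------
# Genome context
# ---------------------------------------------------------------------------


@dataclass
class ContextParams:
    window_flank: int = 5000
    min_mean_fraction: float = 0.002
    late_fold: float = 4.0
    stages: tuple[str, str] = ("early", "late")
    include_self: bool = True

    def __post_init__(self) -> None:
        if self.window_flank <= 0:
            raise ValueError("window_flank must be > 0")
        if self.late_fold <= 1:
            raise ValueError("late_fold must be > 1")


def window_gene_counts(bed: pd.DataFrame, params: ContextParams | None = None) -> pd.Series:
    """Per gene, the number of predicted tRNA genes whose interval midpoint
    falls within [start - flank, end + flank); the focal gene itself is
    included (its midpoint always lies in its own window)."""
    params = params or ContextParams()
    counts = pd.Series(0, index=bed["name"], dtype=int)
    for _, sub in bed.groupby("chrom"):
        mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
        order = np.sort(mids)
        lo = np.searchsorted(order, sub["start"].to_numpy() - params.window_flank, side="left")
        hi = np.searchsorted(order, sub["end"].to_numpy() + params.window_flank, side="left")
        n = hi - lo
        if not params.include_self:
            n = n - 1
        counts.loc[sub["name"]] = n
    return counts


def genomic_context(
    bed: pd.DataFrame,
    gene_isodecoder: Mapping[str, str],
    abundance: pd.DataFrame,
    params: ContextParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Early/late genome-context comparison.

    ``bed``: all predicted tRNA genes (columns chrom/start/end/name/...).
    ``gene_isodecoder``: gene name -> isodecoder id (genes not mapped still
    count as neighbours). ``abundance``: per-isodecoder fractions, columns
    named as ``params.stages``. Returns the per-isodecoder table and the
    Mann-Whitney U result.
    """
    params = params or ContextParams()
    early_s, late_s = params.stages
    for s in params.stages:
        if s not in abundance.columns:
            raise ValueError(f"stage {s!r} missing from abundance table")
    counts = window_gene_counts(bed, params)
    per_iso: dict[str, list[int]] = {}
    for gene, n in counts.items():
        iso = gene_isodecoder.get(gene)
        if iso is not None:
            per_iso.setdefault(iso, []).append(int(n))
    rows = []
    for iso, ns in per_iso.items():
        if iso not in abundance.index:
            continue
        f_early = float(abundance.loc[iso, early_s])
        f_late = float(abundance.loc[iso, late_s])
        if max(f_early, f_late) < params.min_mean_fraction:
            continue
        fold = np.inf if f_early == 0 else f_late / f_early
        rows.append({
            "isodecoder": iso,
            "mean_gene_count": float(np.mean(ns)),
            "n_copies": len(ns),
            early_s: f_early,
            late_s: f_late,
            "group": "late" if fold >= params.late_fold else "early",
        })
    table = pd.DataFrame(rows)
    result: dict = {"n_early": 0, "n_late": 0, "U": np.nan, "p_value": np.nan}
    if not table.empty:
        early = table.loc[table["group"] == "early", "mean_gene_count"]
        late = table.loc[table["group"] == "late", "mean_gene_count"]
        result["n_early"], result["n_late"] = len(early), len(late)
        result["median_early"] = float(early.median()) if len(early) else np.nan
        result["median_late"] = float(late.median()) if len(late) else np.nan
        if len(early) and len(late):
            u = stats.mannwhitneyu(early, late, alternative="two-sided", method="asymptotic")
            result["U"], result["p_value"] = float(u.statistic), float(u.pvalue)
    return table, result


# ---------------------------------------------------------------------------
# Expression-weighted codon frequency
# ---------------------------------------------------------------------------


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def pick_isoforms(
    cds: Mapping[str, str],
    isoform_table: pd.DataFrame | None = None,
) -> dict[str, str]:
    """One representative CDS per gene: a primary-isoform table
    (columns gene_id, transcript_id) when available, longest CDS otherwise."""
    if isoform_table is not None:
        out = {}
        for _, row in isoform_table.iterrows():
            tid = row["transcript_id"]
            if tid in cds:
                out[row["gene_id"]] = cds[tid]
        return out
    return dict(cds)


def weighted_codon_frequency(
    cds_by_gene: Mapping[str, str],
    expression: Mapping[str, float],
    skip_internal_stops: bool = True,
) -> pd.Series:
    """freq(c) = sum_g count_g(c) * w_g / sum_g n_codons(g) * w_g.

    CDS whose length is not a multiple of 3 (or with internal stops, when
    ``skip_internal_stops``) are logged and skipped. Frequencies sum to 1
    and are invariant to rescaling all expression weights.
    """
    totals: Counter[str] = Counter()
    denom = 0.0
    for gene, seq in cds_by_gene.items():
        w = float(expression.get(gene, 0.0))
        if w <= 0:
            continue
        if len(seq) % 3 != 0:
            logger.warning("%s: CDS length %d not divisible by 3; skipped", gene, len(seq))
            continue
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if skip_internal_stops and any(c in ("TAA", "TAG", "TGA") for c in codons[:-1]):
            logger.warning("%s: internal stop codon; skipped", gene)
            continue
        counts = Counter(codons)
        for c, n in counts.items():
            totals[c] += n * w
        denom += len(codons) * w
    if denom == 0:
        raise ValueError("no usable CDS/expression pairs")
    return (pd.Series(totals, dtype=float) / denom).sort_index()


# ---------------------------------------------------------------------------
# Wobble decoding and correlation
# ---------------------------------------------------------------------------

_WOBBLE_34 = {
    # anticodon position 34 -> codon third positions decoded
    "G": ["C", "T"],
    "T": ["A", "G"],
    "C": ["G"],
    "A": ["T", "C", "A"],  # A34 is read as inosine
}


def default_decoding_table(anticodons: Iterable[str]) -> dict[str, list[str]]:
    """Crick wobble (with inosine at A34): anticodon -> decoded codons."""
    table = {}
    for ac in anticodons:
        stem = str(Seq(ac[1:]).reverse_complement())
        table[ac] = sorted(stem + third for third in _WOBBLE_34[ac[0]])
    return table


def write_decoding_table(table: Mapping[str, Sequence[str]], path: str | Path) -> None:
    pd.DataFrame(
        [{"anticodon": ac, "codons": ",".join(codons)} for ac, codons in sorted(table.items())]
    ).to_csv(path, sep="\t", index=False)


def read_decoding_table(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return {row["anticodon"]: row["codons"].split(",") for _, row in df.iterrows()}


def holm_bonferroni(pvalues: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="holm")[1]
    return out


def correlate_abundance_codon(
    anticodon_fractions: pd.DataFrame,
    codon_frequency: pd.DataFrame,
    decoding: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Pearson correlation of anticodon-family tRNA abundance with decoded
    codon frequency.

    ``anticodon_fractions``: anticodon x stage; ``codon_frequency``: codon x
    stage. Returns per-stage cross-sectional correlations and per-anticodon
    time-course correlations with Holm-Bonferroni adjusted p-values.
    Correlations over fewer than 3 points are reported as missing.
    """
    decoding = decoding or default_decoding_table(anticodon_fractions.index)
    stages = [s for s in anticodon_fractions.columns if s in codon_frequency.columns]
    per_ac_freq = pd.DataFrame(
        {
            ac: codon_frequency.reindex(decoding[ac]).fillna(0.0).sum(axis=0)
            for ac in anticodon_fractions.index
        }
    ).T  # anticodon x stage
    per_stage_rows = []
    for s in stages:
        x = anticodon_fractions[s].to_numpy(dtype=float)
        y = per_ac_freq[s].to_numpy(dtype=float)
        if len(x) >= 3 and np.std(x) > 0 and np.std(y) > 0:
            r, p = stats.pearsonr(x, y)
        else:
            r, p = np.nan, np.nan
        per_stage_rows.append({"stage": s, "r": r, "p": p, "n": len(x)})
    tc_rows = []
    for ac in anticodon_fractions.index:
        x = anticodon_fractions.loc[ac, stages].to_numpy(dtype=float)
        y = per_ac_freq.loc[ac, stages].to_numpy(dtype=float)
        if len(stages) >= 3 and np.std(x) > 0 and np.std(y) > 0:
            r, p = stats.pearsonr(x, y)
        else:
            r, p = np.nan, np.nan
        tc_rows.append({"anticodon": ac, "r": r, "p": p, "n": len(stages)})
    time_course = pd.DataFrame(tc_rows)
    time_course["p_adj"] = holm_bonferroni(time_course["p"])
    return {"per_stage": pd.DataFrame(per_stage_rows), "time_course": time_course}
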