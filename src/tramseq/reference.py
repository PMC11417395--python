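"""Mature tRNA reference sets with canonical (Sprinzl) position numbering.

This module builds the reference layer of the pipeline: it parses tRNA gene
predictions (nuclear tRNAscan-SE/GtRNAdb-style plus mitochondrial FASTA),
converts genomic sequences to their mature form (intron removal, 3' CCA,
His G-1), collapses identical mature sequences into single references,
transfers canonical position labels from a numbered structural alignment,
filters references by sequencing coverage (RPM), and polishes references
for SNPs seen in demethylated-library pileups.

Canonical labels are strings: "1".."76" for the core positions, "-1" for the
His 5' guanosine, letter-suffixed insertions such as "20a"/"20b" in the
D-loop, and "e1","e2",... for variable-arm positions between 45 and 46.
They let positions be compared across tRNAs of different lengths.
"""

from __future__ import annotations

import itertools
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("tramseq.reference")

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Canonical 76-nt tRNA backbone (cloverleaf-consistent; anticodon GAA at
#: positions 34-36, T-loop T54/U55/C56, A58, discriminator + CCA). Sequence
#: index i carries canonical label str(i + 1).
CANONICAL_BACKBONE = (
    "GCGGATTTAGCTCAGTTGGGAGAGCGCCAGACTGAAGATCTGGAGGTCCTGTGTTCGATCCACAGAATTCGCACCA"
)
BACKBONE_LABELS = tuple(str(i + 1) for i in range(len(CANONICAL_BACKBONE)))

_PACKAGED_ALIGNMENT = "synthetic_numbering.sto"


class ReferenceError(ValueError):
    """Raised for unusable reference inputs (empty FASTA, bad labels...)."""


class NumberingError(ReferenceError):
    """Raised when a reference cannot be canonically numbered."""


# ---------------------------------------------------------------------------
# Canonical label ordering
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"^(-1|\d+)([a-z]?)$")
_E_RE = re.compile(r"^e(\d+)$")


def sprinzl_key(label: str) -> tuple[int, int, int]:
    """Sort key placing canonical labels in 5'->3' Sprinzl order.

    "-1" < "1" < ... < "20" < "20a" < "20b" < "21" < ... < "45" <
    "e1" < "e2" < ... < "46" < ... < "76".
    """
    m = _E_RE.match(label)
    if m:
        # variable-arm extensions live between 45 and 46
        return (45, 1000, int(m.group(1)))
    m = _LABEL_RE.match(label)
    if not m:
        raise ReferenceError(f"unrecognised canonical label: {label!r}")
    num = int(m.group(1))
    suffix = m.group(2)
    return (num, ord(suffix) - ord("a") + 1 if suffix else 0, 0)


def validate_canonical_map(seq: str, cmap: Mapping[int, str]) -> None:
    """Check a canonical map covers every index once, strictly increasing."""
    if sorted(cmap) != list(range(len(seq))):
        raise ReferenceError("canonical map must label every sequence index exactly once")
    keys = [sprinzl_key(cmap[i]) for i in range(len(seq))]
    for a, b in zip(keys, keys[1:]):
        if not a < b:
            raise ReferenceError(f"canonical labels not in Sprinzl order near key {a}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TRNAGene:
    """One predicted tRNA gene (genomic form, pre-maturation)."""

    gene_id: str
    origin: str  # "nuclear" | "mito"
    amino_acid: str  # 3-letter code, or "iMet"/"Sup"/"Unk"
    anticodon: str  # 3-mer over ACGT, or "NNN" when unknown
    genomic_seq: str
    locus: tuple[str, int, int, str] | None = None  # chrom, start, end (0-based half-open), strand
    confidence: str | None = None  # "high" | "low" | "pseudo"
    intron: tuple[int, int] | None = None  # 1-based inclusive span within genomic_seq

    def __post_init__(self) -> None:
        if not self.genomic_seq:
            raise ReferenceError(f"{self.gene_id}: empty genomic sequence")
        bad = set(self.genomic_seq) - set(BASES)
        if bad:
            raise ReferenceError(f"{self.gene_id}: non-ACGT characters {sorted(bad)}")


@dataclass
class ReferenceSeq:
    """One mature tRNA reference (possibly representing many gene copies)."""

    ref_id: str
    mature_seq: str
    source_gene_ids: list[str]
    amino_acid: str = "Unk"
    anticodon: str = "NNN"
    origin: str = "nuclear"
    canonical_map: dict[int, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.mature_seq)

    def label_of(self, index: int) -> str:
        return self.canonical_map[index]

    def index_of(self, label: str) -> int | None:
        for i, lab in self.canonical_map.items():
            if lab == label:
                return i
        return None


class ReferenceSet:
    """Ordered collection of ReferenceSeq, addressable by ref_id."""

    def __init__(self, refs: Iterable[ReferenceSeq] = ()):
        self._refs: dict[str, ReferenceSeq] = {}
        for r in refs:
            self.add(r)

    def add(self, ref: ReferenceSeq) -> None:
        if ref.ref_id in self._refs:
            raise ReferenceError(f"duplicate ref_id {ref.ref_id}")
        self._refs[ref.ref_id] = ref

    def __len__(self) -> int:
        return len(self._refs)

    def __iter__(self):
        return iter(self._refs.values())

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._refs

    def __getitem__(self, ref_id: str) -> ReferenceSeq:
        return self._refs[ref_id]

    @property
    def ref_ids(self) -> list[str]:
        return list(self._refs)

    def subset(self, ref_ids: Iterable[str]) -> "ReferenceSet":
        return ReferenceSet(self._refs[r] for r in ref_ids)


@dataclass
class NumberedAlignment:
    """A gapped multiple alignment whose columns carry canonical labels.

    ``col_labels[j]`` is the canonical label of column ``j`` or ``None`` for
    unlabelled (variable-region) columns.
    """

    rows: dict[str, str]
    col_labels: list[str | None]

    def __post_init__(self) -> None:
        widths = {len(s) for s in self.rows.values()}
        if len(widths) > 1:
            raise ReferenceError("alignment rows have unequal lengths")
        if widths and widths != {len(self.col_labels)}:
            raise ReferenceError("col_labels length does not match alignment width")
        core = {str(i) for i in range(1, 77)}
        have = {lab for lab in self.col_labels if lab is not None}
        if not core <= have:
            raise ReferenceError("label columns must cover core positions 1-76")

    def consensus(self) -> tuple[str, list[str | None]]:
        """Column-majority consensus sequence used for numbering transfer.

        Labelled columns follow column majority (a gap-majority column is
        dropped). Unlabelled variable-region columns are kept whenever any
        row occupies them, with the base majority taken over occupying rows
        only — these columns anchor long variable arms, which would
        otherwise be free-floating insertions prone to mislabelling when an
        arm base coincides with the base at canonical 46. Returns the
        ungapped consensus and, per position, the column's canonical label
        (None for variable-region columns).
        """
        seqs = list(self.rows.values())
        cons: list[str] = []
        labels: list[str | None] = []
        for j in range(len(self.col_labels)):
            counts = Counter(s[j].upper() for s in seqs)
            base_counts = {c: n for c, n in counts.items() if c != "-"}
            if not base_counts:
                continue
            top = max(sorted(base_counts), key=lambda c: base_counts[c])
            if self.col_labels[j] is None:
                cons.append(top)
                labels.append(None)
            elif counts.get("-", 0) <= base_counts[top]:
                # tie between a base and the gap resolves toward the base
                cons.append(top)
                labels.append(self.col_labels[j])
        return "".join(cons), labels


@dataclass
class ReferenceFilterParams:
    """Coverage-based reference inclusion filter (RPM in demethylated samples)."""

    min_rpm: float = 500.0
    required_samples: int = 1

    def __post_init__(self) -> None:
        if self.min_rpm < 0:
            raise ReferenceError("min_rpm must be >= 0")
        if self.required_samples < 1:
            raise ReferenceError("required_samples must be >= 1")


# ---------------------------------------------------------------------------
# Stockholm numbered-alignment dialect
# ---------------------------------------------------------------------------
#
# The numbered alignment ships as Stockholm with two custom annotation lines:
#   #=GF CANONICAL_LABELS <space-separated labels, 5'->3'>
#   #=GC CANON            <one char per column: 'x' = labelled (consumes the
#                          next label), '.' = unlabelled variable column>
# Biopython's Stockholm reader drops unknown #=GF tags, so this small
# dialect-specific reader/writer is used instead.


def read_stockholm(path: str | Path) -> NumberedAlignment:
    labels_list: list[str] | None = None
    canon_line = ""
    rows: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip()
        if not line or line == "//" or line.startswith("# STOCKHOLM"):
            continue
        if line.startswith("#=GF CANONICAL_LABELS"):
            labels_list = line.split()[2:]
        elif line.startswith("#=GC CANON"):
            canon_line += line.split()[2]
        elif line.startswith("#"):
            continue
        else:
            name, seq = line.split()
            rows[name] = rows.get(name, "") + seq.upper().replace(".", "-")
    if labels_list is None or not canon_line:
        raise ReferenceError(f"{path}: missing CANONICAL_LABELS / CANON annotation")
    it = iter(labels_list)
    col_labels: list[str | None] = [next(it) if c == "x" else None for c in canon_line]
    return NumberedAlignment(rows=rows, col_labels=col_labels)


def write_stockholm(aln: NumberedAlignment, path: str | Path) -> None:
    labels = [lab for lab in aln.col_labels if lab is not None]
    canon = "".join("x" if lab is not None else "." for lab in aln.col_labels)
    width = max(len(n) for n in aln.rows) if aln.rows else 10
    width = max(width, len("#=GC CANON"))
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        fh.write("#=GF CANONICAL_LABELS " + " ".join(labels) + "\n")
        for name, seq in aln.rows.items():
            fh.write(f"{name:<{width}} {seq}\n")
        fh.write(f"{'#=GC CANON':<{width}} {canon}\n//\n")


def default_numbering_alignment() -> NumberedAlignment:
    """The packaged miniature numbered alignment (synthetic stand-in for a
    curated structural tRNA alignment; see data/synthetic_numbering.sto)."""
    with resources.as_file(
        resources.files("tramseq").joinpath("data").joinpath(_PACKAGED_ALIGNMENT)
    ) as p:
        return read_stockholm(p)


# ---------------------------------------------------------------------------
# Header parsing and maturation
# ---------------------------------------------------------------------------

_GTRNADB_RE = re.compile(
    r"tRNA-(?P<aa>[A-Za-z]{3}|iMet|fMet|Sup|SeC|Und)-(?P<ac>[ACGTN]{3})-(?P<copy>\d+)-(?P<var>\d+)"
)
_INTRON_RE = re.compile(r"intron:(\d+)-(\d+)")
_LOCUS_RE = re.compile(r"(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)\s*\((?P<strand>[+-])\)")


def parse_gene_header(header: str, seq: str, origin: str = "nuclear") -> TRNAGene:
    """Parse a FASTA header into a TRNAGene.

    Two dialects are recognised: GtRNAdb-style ``...tRNA-Ala-AGC-1-1...``
    tokens and a plain ``id|aa|anticodon`` fallback. Optional tokens:
    ``intron:START-END`` (1-based inclusive), ``CHROM:START-END(+)`` locus,
    and the words ``pseudo``/``lowconf``. Unparseable headers raise
    ReferenceError (callers downgrade to sequence-only references).
    """
    gene_id = header.split()[0]
    aa, ac = None, None
    m = _GTRNADB_RE.search(header)
    piped = next((tok for tok in header.split() if tok.count("|") >= 2), None)
    if m:
        aa, ac = m.group("aa"), m.group("ac")
    elif piped is not None:
        parts = piped.split("|")
        if piped == gene_id:
            # gene dialect: id|aa|anticodon
            gene_id, aa, ac = parts[0], parts[1], parts[2]
        else:
            # reference-FASTA description dialect: aa|anticodon|origin...
            aa, ac = parts[0], parts[1]
    else:
        raise ReferenceError(f"unrecognised tRNA header dialect: {header!r}")
    intron = None
    mi = _INTRON_RE.search(header)
    if mi:
        intron = (int(mi.group(1)), int(mi.group(2)))
    locus = None
    ml = _LOCUS_RE.search(header)
    if ml:
        locus = (ml.group("chrom"), int(ml.group("start")), int(ml.group("end")), ml.group("strand"))
    confidence = "high"
    low = header.lower()
    if "pseudo" in low:
        confidence = "pseudo"
    elif "lowconf" in low:
        confidence = "low"
    return TRNAGene(
        gene_id=gene_id,
        origin=origin,
        amino_acid=aa,
        anticodon=ac.upper(),
        genomic_seq=seq.upper().replace("U", "T"),
        locus=locus,
        confidence=confidence,
        intron=intron,
    )


def maturate_sequence(gene: TRNAGene) -> str:
    """Genomic -> mature sequence: strip annotated intron, append 3' CCA when
    not genomically encoded, prepend the His 5' G (canonical -1) when absent.
    Mitochondrial sequences receive CCA the same way.
    """
    seq = gene.genomic_seq
    if gene.intron is not None:
        a, b = gene.intron
        if not (1 <= a <= b <= len(seq)):
            raise ReferenceError(f"{gene.gene_id}: intron span {gene.intron} outside sequence")
        seq = seq[: a - 1] + seq[b:]
    if not seq.endswith("CCA"):
        seq += "CCA"
    if gene.amino_acid == "His" and not seq.startswith("G"):
        seq = "G" + seq
    return seq


# ---------------------------------------------------------------------------
# Reference-set construction
# ---------------------------------------------------------------------------


def _genes_from_fasta(path: str | Path, origin: str) -> list[TRNAGene]:
    genes: list[TRNAGene] = []
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ReferenceError(f"{path}: no FASTA records")
    for i, rec in enumerate(records):
        seq = str(rec.seq).upper().replace("U", "T")
        try:
            genes.append(parse_gene_header(rec.description, seq, origin=origin))
        except ReferenceError as exc:
            logger.warning("record-level header error (%s); keeping sequence-only reference", exc)
            genes.append(
                TRNAGene(
                    gene_id=rec.id or f"{origin}_{i}",
                    origin=origin,
                    amino_acid="Unk",
                    anticodon="NNN",
                    genomic_seq=seq,
                )
            )
    return genes


def build_reference_set(
    nuclear_fasta: str | Path | None = None,
    mito_fasta: str | Path | None = None,
    genes: Sequence[TRNAGene] | None = None,
) -> ReferenceSet:
    """Collapse gene predictions to one reference per distinct mature sequence.

    Identical mature sequences merge into a single ReferenceSeq carrying all
    source gene ids; mitochondrial references are flagged origin="mito".
    """
    all_genes: list[TRNAGene] = list(genes or [])
    if nuclear_fasta is not None:
        all_genes += _genes_from_fasta(nuclear_fasta, "nuclear")
    if mito_fasta is not None:
        all_genes += _genes_from_fasta(mito_fasta, "mito")
    if not all_genes:
        raise ReferenceError("no input tRNA genes")

    groups: dict[tuple[str, str, str, str], list[TRNAGene]] = {}
    for g in all_genes:
        mature = maturate_sequence(g)
        groups.setdefault((g.origin, g.amino_acid, g.anticodon, mature), []).append(g)

    refset = ReferenceSet()
    counters: dict[tuple[str, str, str], itertools.count] = {}
    for (origin, aa, ac, mature), members in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], kv[0][3])
    ):
        fam = (origin, aa, ac)
        counters.setdefault(fam, itertools.count(1))
        n = next(counters[fam])
        prefix = "mt-" if origin == "mito" else ""
        refset.add(
            ReferenceSeq(
                ref_id=f"{prefix}{aa}-{ac}-{n}",
                mature_seq=mature,
                source_gene_ids=sorted(g.gene_id for g in members),
                amino_acid=aa,
                anticodon=ac,
                origin=origin,
            )
        )
    return refset


# ---------------------------------------------------------------------------
# Canonical numbering transfer
# ---------------------------------------------------------------------------


def _profile_columns(aln: NumberedAlignment) -> list[tuple[str, float, str | None]]:
    """Per occupied column: (majority base over occupying rows, occupancy
    fraction, canonical label)."""
    seqs = list(aln.rows.values())
    cols = []
    for j, lab in enumerate(aln.col_labels):
        bases = [s[j].upper() for s in seqs if s[j] != "-"]
        if not bases:
            continue
        counts = Counter(bases)
        top = max(sorted(counts), key=lambda c: counts[c])
        cols.append((top, len(bases) / len(seqs), lab))
    return cols


_MATCH, _MISMATCH = 2.0, -1.0
_INS_OPEN, _INS_EXTEND = -6.0, -1.0
_DEL_BASE, _DEL_OCC = -0.5, -4.0
_NEG = float("-inf")


def _profile_align(seq: str, cols: list[tuple[str, float, str | None]]):
    """Global alignment of a sequence against profile columns.

    Skipping a column costs in proportion to its occupancy, so sparse
    variable-region columns are nearly free to delete while core columns
    are not — this anchors long variable arms to their own columns instead
    of letting them float as insertions next to canonical 45/46. Returns
    (score, matched) where matched[i] is the column index aligned to
    sequence position i, or None for an insertion.
    """
    n, m = len(seq), len(cols)
    del_cost = [_DEL_BASE + _DEL_OCC * occ for _, occ, _ in cols]
    S = [[_NEG] * (m + 1) for _ in range(n + 1)]
    I = [[_NEG] * (m + 1) for _ in range(n + 1)]
    ptr_s = [[0] * (m + 1) for _ in range(n + 1)]  # 1=diag, 2=del from S, 3=del from I, 4=close I
    S[0][0] = 0.0
    for j in range(1, m + 1):
        S[0][j] = S[0][j - 1] + del_cost[j - 1]
        ptr_s[0][j] = 2
    for i in range(1, n + 1):
        I[i][0] = _INS_OPEN + (i - 1) * _INS_EXTEND
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = _MATCH if seq[i - 1] == cols[j - 1][0] else _MISMATCH
            diag = max(S[i - 1][j - 1], I[i - 1][j - 1]) + sub
            del_s = S[i][j - 1] + del_cost[j - 1]
            del_i = I[i][j - 1] + del_cost[j - 1]
            best = max(diag, del_s, del_i)
            S[i][j] = best
            ptr_s[i][j] = 1 if best == diag else (2 if best == del_s else 3)
            I[i][j] = max(S[i - 1][j] + _INS_OPEN, I[i - 1][j] + _INS_EXTEND)
    matched: list[int | None] = [None] * n
    i, j = n, m
    in_insert = I[n][m] > S[n][m]
    score = max(S[n][m], I[n][m])
    while i > 0 or j > 0:
        if in_insert:
            if i > 0 and I[i][j] == I[i - 1][j] + _INS_EXTEND:
                i -= 1
            else:
                i -= 1
                in_insert = False
            continue
        move = ptr_s[i][j]
        if move == 1:
            prev_from_i = I[i - 1][j - 1] > S[i - 1][j - 1]
            matched[i - 1] = j - 1
            i, j = i - 1, j - 1
            in_insert = prev_from_i
        elif move in (2, 3):
            in_insert = move == 3
            j -= 1
        else:
            i -= 1
    return score, matched


def _letter_successor(label: str) -> str:
    m = _LABEL_RE.match(label)
    if m and not m.group(2):
        return label + "a"
    if m:
        return m.group(1) + chr(ord(m.group(2)) + 1)
    raise NumberingError(f"cannot extend label {label!r}")


def assign_canonical_numbering(
    ref: ReferenceSeq,
    aln: NumberedAlignment,
    min_score_frac: float = 0.5,
) -> dict[int, str]:
    """Transfer canonical labels to a reference via a profile alignment
    against the numbered alignment's columns.

    Matched labelled columns transfer their label directly. Reference bases
    matched to unlabelled variable-region columns, or inserted after 45,
    become "e1","e2",...; a single leading insertion becomes "-1" (His
    G-1); other insertions get letter suffixes of the preceding label
    ("20" -> "20a" -> "20b").
    """
    cols = _profile_columns(aln)
    score, matched = _profile_align(ref.mature_seq, cols)
    floor = min_score_frac * _MATCH * min(len(ref.mature_seq), len(cols))
    if score < floor:
        raise NumberingError(f"unnumberable reference {ref.ref_id}: score {score:.0f} < {floor:.0f}")
    cons_labels = [lab for _, _, lab in cols]

    cmap: dict[int, str] = {}
    prev_label: str | None = None
    e_counter = 0
    pending_lead = 0
    for i in range(len(ref.mature_seq)):
        j = matched[i]
        if j is not None and cons_labels[j] is not None:
            cmap[i] = cons_labels[j]
            prev_label = cons_labels[j]
            if _E_RE.match(prev_label):
                e_counter = int(prev_label[1:])
        else:
            if prev_label is None:
                pending_lead += 1
                if pending_lead > 1:
                    raise NumberingError(f"{ref.ref_id}: more than one unmatched 5' base")
                cmap[i] = "-1"
            elif sprinzl_key(prev_label) >= sprinzl_key("45") and sprinzl_key(prev_label) < sprinzl_key("46"):
                e_counter += 1
                cmap[i] = f"e{e_counter}"
                prev_label = cmap[i]
            else:
                cmap[i] = _letter_successor(prev_label)
                prev_label = cmap[i]

    validate_canonical_map(ref.mature_seq, cmap)
    if ref.anticodon and ref.anticodon != "NNN":
        triplet = "".join(
            ref.mature_seq[i] for i in sorted(cmap) if cmap[i] in ("34", "35", "36")
        )
        if triplet != ref.anticodon:
            raise NumberingError(
                f"{ref.ref_id}: positions 34-36 read {triplet!r}, expected anticodon {ref.anticodon!r}"
            )
    return cmap


def number_references(
    refset: ReferenceSet,
    aln: NumberedAlignment | None = None,
    min_score_frac: float = 0.5,
) -> ReferenceSet:
    """Assign canonical maps to every reference in place; returns the set."""
    if aln is None:
        aln = default_numbering_alignment()
    for ref in refset:
        ref.canonical_map = assign_canonical_numbering(ref, aln, min_score_frac)
    return refset


# ---------------------------------------------------------------------------
# Coverage filtering and SNP polishing
# ---------------------------------------------------------------------------


def filter_references_by_coverage(
    refset: ReferenceSet,
    per_sample_counts: pd.DataFrame,
    params: ReferenceFilterParams | None = None,
) -> tuple[ReferenceSet, pd.DataFrame]:
    """Keep references reaching ``min_rpm`` reads-per-million in at least
    ``required_samples`` samples; returns (kept set, dropped report).

    ``per_sample_counts``: rows ref_id, columns sample, values mapped-read
    counts from the demethylated libraries.
    """
    params = params or ReferenceFilterParams()
    totals = per_sample_counts.sum(axis=0)
    for sample, tot in totals.items():
        if tot <= 0:
            raise ReferenceError(f"sample {sample!r} has zero mapped reads")
    counts = per_sample_counts.reindex(refset.ref_ids).fillna(0.0)
    rpm = counts.div(totals, axis=1) * 1e6
    keep_mask = (rpm >= params.min_rpm).sum(axis=1) >= params.required_samples
    kept = refset.subset([r for r in refset.ref_ids if keep_mask[r]])
    dropped = pd.DataFrame(
        {"ref_id": [r for r in refset.ref_ids if not keep_mask[r]]}
    )
    dropped["max_rpm"] = [rpm.loc[r].max() for r in dropped["ref_id"]]
    return kept, dropped


def polish_reference_snps(
    refset: ReferenceSet,
    pileups: Mapping[str, "object"],
    min_af: float = 0.8,
    min_cov: int = 50,
) -> tuple[ReferenceSet, pd.DataFrame]:
    """Substitute reference bases at high-frequency SNP sites.

    A site is rewritten when a single alternative base accounts for at least
    ``min_af`` of the (base-call) coverage with at least ``min_cov`` coverage
    in the pooled demethylated pileups. Substitutions only, so canonical maps
    are preserved. The conservative default allele fraction keeps
    modification-induced mismatch sites (typically well below 0.8 and
    demethylation-sensitive) from being rewritten into the reference.
    """
    log_rows = []
    polished = ReferenceSet()
    for ref in refset:
        seq = list(ref.mature_seq)
        stats = pileups.get(ref.ref_id)
        if stats is not None:
            bc = stats.base_counts  # (len, 4) array of observed-base counts
            for i, old in enumerate(ref.mature_seq):
                cov = int(bc[i].sum())
                if cov < min_cov:
                    continue
                alt_idx = max(range(4), key=lambda k: bc[i][k])
                alt = BASES[alt_idx]
                af = bc[i][alt_idx] / cov
                if alt != old and af >= min_af:
                    seq[i] = alt
                    log_rows.append(
                        {"ref_id": ref.ref_id, "position": i, "old": old, "new": alt, "af": round(float(af), 4)}
                    )
        polished.add(
            ReferenceSeq(
                ref_id=ref.ref_id,
                mature_seq="".join(seq),
                source_gene_ids=list(ref.source_gene_ids),
                amino_acid=ref.amino_acid,
                anticodon=ref.anticodon,
                origin=ref.origin,
                canonical_map=dict(ref.canonical_map),
            )
        )
    return polished, pd.DataFrame(log_rows, columns=["ref_id", "position", "old", "new", "af"])


# ---------------------------------------------------------------------------
# Reference I/O
# ---------------------------------------------------------------------------


def write_reference_fasta(refset: ReferenceSet, fasta_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Write references as FASTA plus a TSV sidecar of canonical labels."""
    with open(fasta_path, "w") as fh:
        for ref in refset:
            fh.write(
                f">{ref.ref_id} {ref.amino_acid}|{ref.anticodon}|{ref.origin}"
                f"|copies={len(ref.source_gene_ids)}\n{ref.mature_seq}\n"
            )
    if sidecar_path is not None:
        rows = [
            {"ref_id": ref.ref_id, "index": i, "canonical_label": ref.canonical_map.get(i, "")}
            for ref in refset
            for i in range(len(ref.mature_seq))
        ]
        pd.DataFrame(rows).to_csv(sidecar_path, sep="\t", index=False)


def read_reference_fasta(fasta_path: str | Path, sidecar_path: str | Path | None = None) -> ReferenceSet:
    """Reload a reference set written by :func:`write_reference_fasta`."""
    refset = ReferenceSet()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        parts = rec.description.split(None, 1)
        aa, ac, origin = "Unk", "NNN", "nuclear"
        if len(parts) == 2 and parts[1].count("|") >= 2:
            fields = parts[1].split("|")
            aa, ac, origin = fields[0], fields[1], fields[2]
        refset.add(
            ReferenceSeq(
                ref_id=rec.id,
                mature_seq=str(rec.seq).upper(),
                source_gene_ids=[rec.id],
                amino_acid=aa,
                anticodon=ac,
                origin=origin,
            )
        )
    if sidecar_path is not None:
        side = pd.read_csv(sidecar_path, sep="\t", dtype={"canonical_label": str})
        for ref_id, grp in side.groupby("ref_id"):
            if ref_id in refset:
                refset[ref_id].canonical_map = dict(
                    zip(grp["index"].astype(int), grp["canonical_label"])
                )
    return refset
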