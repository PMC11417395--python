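"""Synthetic tRNA sequencing data with known ground truth.

The generator is the test harness for the whole pipeline. It emulates the
phenomena the analysis must cope with:

* multiple identical and near-identical isodecoder gene copies, some in
  tandem repetitive arrays and some isolated in the genome;
* per-site modification effects on reverse transcription — misincorporation
  and premature stops — that demethylation (DM libraries) abolishes at
  sensitive sites (m1A/m1G/m3C/m2,2G-like) but not at resistant ones
  (inosine/acp3U/bulky-modification-like);
* bisulfite conversion (BS libraries) with incomplete efficiency, so the
  C-retention rate at a site with methylation fraction m and conversion
  efficiency e tends to m + (1-m)(1-e);
* the library read layout [3N][insert][6N][adapter] with UMIs, uniform
  sequencing errors, untemplated 5' additions, and PCR duplication.

Reverse-transcription events compose multiplicatively along the 3'->5' walk:
a 5' site is only observed by molecules not already truncated at a more 3'
site, which is what makes downstream stop-fraction denominators correct.
Untemplated 5' additions are applied to run-off (non-truncated) cDNAs,
modelling terminal transferase activity at the template 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .preprocess import FastqRecord, ReadLayout
from .reference import (
    CANONICAL_BACKBONE,
    NumberedAlignment,
    ReferenceSet,
    TRNAGene,
    build_reference_set,
    maturate_sequence,
)

BASES = "ACGT"

#: anticodons drawn from, in order, when building families
_ANTICODON_POOL = [
    "GAA", "GCC", "CTG", "TTG", "GTC", "CTT", "TTT", "CAT", "TGC", "AGC",
    "TCG", "GTA", "CAA", "AAC", "TGT", "AGT", "GCT", "CAG", "TCC", "GTG",
    "CCA", "TAC", "CGT", "TAG",
]

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Sup",
}


class SimError(ValueError):
    """Raised for infeasible or inconsistent simulation specs."""


def anticodon_to_aa(anticodon: str) -> str:
    codon = str(Seq(anticodon).reverse_complement())
    return _AA3[str(Seq(codon).translate())]


# ---------------------------------------------------------------------------
# Backbone variants and the packaged numbering alignment
# ---------------------------------------------------------------------------


def backbone_variant(
    anticodon: str,
    substitutions: dict[int, str] | None = None,
    d_loop_insert: str = "",
    var_arm_insert: str = "",
    his_g: bool = False,
) -> tuple[str, list[str]]:
    """Build a tRNA sequence from the canonical 76-nt backbone.

    ``substitutions`` are in core coordinates (0-based index into the
    backbone). ``d_loop_insert`` goes after canonical 20 (labels 20a, 20b,
    ...), ``var_arm_insert`` after canonical 45 (labels e1, e2, ...), and
    ``his_g`` prepends the His G at canonical -1. Returns the sequence and
    its canonical label per position (the numbering ground truth).
    """
    core = list(CANONICAL_BACKBONE)
    core[33:36] = list(anticodon)
    for i, b in (substitutions or {}).items():
        core[i] = b
    seq: list[str] = []
    labels: list[str] = []
    if his_g:
        seq.append("G")
        labels.append("-1")
    for i, b in enumerate(core):
        seq.append(b)
        labels.append(str(i + 1))
        if i == 19:
            for k, ins in enumerate(d_loop_insert):
                seq.append(ins)
                labels.append("20" + chr(ord("a") + k))
        if i == 44:
            for k, ins in enumerate(var_arm_insert):
                seq.append(ins)
                labels.append(f"e{k + 1}")
    return "".join(seq), labels


#: column layout of the packaged numbering alignment
ALIGN_COL_LABELS: list[str | None] = (
    ["-1"]
    + [str(i) for i in range(1, 21)]
    + ["20a", "20b"]
    + [str(i) for i in range(21, 46)]
    + [None] * 13
    + [str(i) for i in range(46, 77)]
)


def build_numbering_alignment() -> NumberedAlignment:
    """Deterministic miniature numbered alignment (the source of the
    packaged data/synthetic_numbering.sto, a synthetic stand-in for a
    curated structural tRNA alignment)."""
    mutable = [i for i in range(76) if i not in range(33, 36) and i < 70]
    rows: dict[str, str] = {}
    specs: list[tuple[str, dict]] = []
    for k, ac in enumerate(_ANTICODON_POOL[:16]):
        subs = {}
        for j in range(2 + k % 3):
            pos = mutable[(7 * k + 11 * j + 3) % len(mutable)]
            subs[pos] = BASES[(k + j + 1) % 4] if BASES[(k + j + 1) % 4] != CANONICAL_BACKBONE[pos] else BASES[(k + j + 2) % 4]
        specs.append((f"trna{k:02d}-{ac}", {"anticodon": ac, "substitutions": subs}))
    specs.append(("trna16-dloop1", {"anticodon": "TGC", "d_loop_insert": "T"}))
    specs.append(("trna17-dloop2", {"anticodon": "AGC", "d_loop_insert": "TT"}))
    specs.append(("trna18-ser", {"anticodon": "GCT", "var_arm_insert": "GGTTCGACTCC"}))
    specs.append(("trna19-leu", {"anticodon": "CAG", "var_arm_insert": "GGTTCGACTCCGG"}))
    specs.append(("trna20-his", {"anticodon": "GTG", "his_g": True}))

    label_to_col = {lab: j for j, lab in enumerate(ALIGN_COL_LABELS) if lab is not None}
    unlabelled_cols = [j for j, lab in enumerate(ALIGN_COL_LABELS) if lab is None]
    for name, kw in specs:
        seq, labels = backbone_variant(**kw)
        row = ["-"] * len(ALIGN_COL_LABELS)
        for base, lab in zip(seq, labels):
            if lab.startswith("e"):
                row[unlabelled_cols[int(lab[1:]) - 1]] = base
            else:
                row[label_to_col[lab]] = base
        rows[name] = "".join(row)
    return NumberedAlignment(rows=rows, col_labels=list(ALIGN_COL_LABELS))


# ---------------------------------------------------------------------------
# Simulation spec
# ---------------------------------------------------------------------------


@dataclass
class ModSite:
    """One modification site and its RT behaviour.

    ``target`` is a ref_id, a family id ("fam0"), or "*" for every reference
    carrying the label. ``forced_base`` fixes the misincorporated base
    (inosine-like sites read as G); otherwise a random non-reference base is
    incorporated.
    """

    target: str
    label: str
    misincorporation_prob: float = 0.0
    stop_prob: float = 0.0
    demethylation_sensitive: bool = True
    forced_base: str | None = None


@dataclass
class M5CSite:
    """A cytosine with the given methylation fraction (per molecule)."""

    target: str
    label: str
    methylation_fraction: float


@dataclass
class SimSpec:
    """Study conditions for a synthetic experiment."""

    n_families: int = 5
    copies_per_family: tuple[int, int] = (1, 3)
    intra_family_diffs: tuple[int, int] = (1, 3)
    cross_family_min_diff: int = 6
    repetitive_fraction: float = 0.0
    n_mito: int = 0
    abundance: dict[str, float] | None = None
    mod_sites: list[ModSite] = field(default_factory=list)
    m5c_sites: list[M5CSite] = field(default_factory=list)
    bs_conversion_efficiency: float = 0.99
    seq_error_rate: float = 0.001
    untemplated5_prob: float = 0.7
    pcr_dup_rate: float = 0.0
    n_reads: int = 10_000
    seed: int = 0
    layout: ReadLayout = field(default_factory=ReadLayout)

    def __post_init__(self) -> None:
        for s in self.mod_sites:
            if not (0 <= s.misincorporation_prob <= 1 and 0 <= s.stop_prob <= 1):
                raise SimError(f"mod site {s.target}:{s.label}: probabilities outside [0,1]")
        for s in self.m5c_sites:
            if not 0 <= s.methylation_fraction <= 1:
                raise SimError(f"m5c site {s.target}:{s.label}: fraction outside [0,1]")
        for p in (self.bs_conversion_efficiency, self.seq_error_rate,
                  self.untemplated5_prob, self.pcr_dup_rate, self.repetitive_fraction):
            if not 0 <= p <= 1:
                raise SimError("probabilities must lie in [0,1]")
        if self.abundance is not None:
            tot = sum(self.abundance.values())
            if abs(tot - 1.0) > 1e-9:
                raise SimError(f"abundance sums to {tot}, expected 1")

    def family_features(self, f: int) -> dict:
        """Deterministic structural variety across families."""
        kw: dict = {}
        if f % 4 == 2:
            kw["d_loop_insert"] = "TA"[: 1 + f % 2]
        if f % 5 == 3:
            kw["var_arm_insert"] = "GGTTCGACTCC"
        return kw


# ---------------------------------------------------------------------------
# Reference / genome simulation
# ---------------------------------------------------------------------------

_MUTABLE_CORE = [i for i in range(76) if i not in (33, 34, 35) and i < 70]


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW")["editDistance"]


def simulate_reference(spec: SimSpec) -> tuple[ReferenceSet, pd.DataFrame, dict]:
    """Generate gene copies, their genomic placement, and the reference set.

    Families are built by mutating the cloverleaf backbone: family centres
    get enough substitutions that any cross-family pair of copies differs by
    at least ``cross_family_min_diff`` edits while intra-family pairs stay
    within ``max(intra_family_diffs)`` (rejection-sampled with bounded
    retries). Repetitive families are laid out as tandem arrays within
    10 kb; everything else is spaced >= 50 kb apart.

    Returns (numbered ReferenceSet, BED-style gene table, truth dict with
    family assignments, canonical maps and the expected similarity
    clustering).
    """
    rng = np.random.default_rng([spec.seed, 101])
    intra_lo, intra_hi = spec.intra_family_diffs
    n_center_subs = spec.cross_family_min_diff + 2 * intra_hi
    required_center_gap = spec.cross_family_min_diff + 2 * intra_hi

    # positions named by modification/methylation sites stay unmutated so the
    # declared site (and, for m5C, its cytosine) exists in every copy
    protected = set()
    for s in list(spec.mod_sites) + list(spec.m5c_sites):
        if s.label.lstrip("-").isdigit() and s.label != "-1":
            protected.add(int(s.label) - 1)
    mutable = [i for i in _MUTABLE_CORE if i not in protected]

    anticodons = list(_ANTICODON_POOL)
    if spec.n_families + spec.n_mito > len(anticodons):
        anticodons = anticodons * (1 + (spec.n_families + spec.n_mito) // len(anticodons))

    centers: list[tuple[str, list[str], dict]] = []
    for f in range(spec.n_families):
        feat = spec.family_features(f)
        for _attempt in range(100):
            pos = rng.choice(mutable, size=min(n_center_subs, len(mutable)), replace=False)
            subs = {}
            for i in pos:
                alts = [b for b in BASES if b != CANONICAL_BACKBONE[i]]
                subs[int(i)] = alts[rng.integers(3)]
            seq, labels = backbone_variant(anticodons[f], substitutions=subs, **feat)
            if all(_edit_distance(seq, c[0]) >= required_center_gap for c in centers):
                centers.append((seq, labels, subs))
                break
        else:
            raise SimError("could not satisfy cross-family difference constraint")

    genes: list[TRNAGene] = []
    gene_family: dict[str, str] = {}
    truth_maps: dict[str, dict[int, str]] = {}
    seq_family: dict[str, str] = {}
    seq_labels: dict[str, list[str]] = {}
    rows = []
    cursor = 10_000
    for f, (center_seq, center_labels, center_subs) in enumerate(centers):
        fam = f"fam{f}"
        feat = spec.family_features(f)
        n_copies = int(rng.integers(spec.copies_per_family[0], spec.copies_per_family[1] + 1))
        variant_pool = rng.choice(mutable, size=max(intra_hi, 1), replace=False)
        repetitive = rng.random() < spec.repetitive_fraction
        copy_seqs = []
        for c in range(n_copies):
            if c == 0 or intra_hi == 0:
                seq, labels = center_seq, center_labels
            else:
                d = int(rng.integers(intra_lo, intra_hi + 1))
                subs = dict(center_subs)
                for i in rng.choice(variant_pool, size=min(d, len(variant_pool)), replace=False):
                    alts = [b for b in BASES if b != center_subs.get(int(i), CANONICAL_BACKBONE[int(i)])]
                    subs[int(i)] = alts[rng.integers(3)]
                seq, labels = backbone_variant(anticodons[f], substitutions=subs, **feat)
            copy_seqs.append((seq, labels))
        for c, (seq, labels) in enumerate(copy_seqs):
            gene_id = f"{fam}-copy{c}"
            genomic = seq[:-3]  # the genome does not encode the 3' CCA
            if repetitive:
                start = cursor + c * 300
            else:
                start = cursor
                cursor += 60_000
            genes.append(
                TRNAGene(
                    gene_id=gene_id,
                    origin="nuclear",
                    amino_acid=anticodon_to_aa(anticodons[f]),
                    anticodon=anticodons[f],
                    genomic_seq=genomic,
                    locus=("chr1", start, start + len(genomic), "+"),
                )
            )
            rows.append({"chrom": "chr1", "start": start, "end": start + len(genomic),
                         "name": gene_id, "score": 0, "strand": "+"})
            gene_family[gene_id] = fam
            seq_family[seq] = fam
            seq_labels[seq] = labels
        if repetitive:
            cursor += 60_000

    for m in range(spec.n_mito):
        ac = anticodons[spec.n_families + m]
        pos = rng.choice(mutable, size=n_center_subs, replace=False)
        subs = {int(i): [b for b in BASES if b != CANONICAL_BACKBONE[i]][rng.integers(3)] for i in pos}
        seq, labels = backbone_variant(ac, substitutions=subs)
        gene_id = f"mt-copy{m}"
        genes.append(
            TRNAGene(gene_id=gene_id, origin="mito", amino_acid=anticodon_to_aa(ac),
                     anticodon=ac, genomic_seq=seq[:-3])
        )
        gene_family[gene_id] = f"mt{m}"
        seq_family[seq] = f"mt{m}"
        seq_labels[seq] = labels

    refset = build_reference_set(genes=genes)
    ref_family: dict[str, str] = {}
    for ref in refset:
        ref_family[ref.ref_id] = seq_family[ref.mature_seq]
        labels = seq_labels[ref.mature_seq]
        ref.canonical_map = {i: lab for i, lab in enumerate(labels)}
        truth_maps[ref.ref_id] = dict(ref.canonical_map)

    expected_clusters: dict[str, list[str]] = {}
    for ref_id, fam in ref_family.items():
        expected_clusters.setdefault(fam, []).append(ref_id)
    bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    truth = {
        "ref_family": ref_family,
        "gene_family": gene_family,
        "canonical_maps": truth_maps,
        "expected_clusters": expected_clusters,
    }
    return refset, bed, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

_LIB_CODE = {"mock": 1, "dm": 2, "bs": 3}


def _resolve_sites(spec: SimSpec, refset: ReferenceSet, ref_family: dict[str, str]) -> tuple[dict, dict]:
    """Map mod/m5c sites to per-reference positions; validate resolvability."""
    mod_by_ref: dict[str, list[tuple[int, ModSite]]] = {r.ref_id: [] for r in refset}
    m5c_by_ref: dict[str, dict[int, float]] = {r.ref_id: {} for r in refset}

    def targets(t: str) -> list[str]:
        if t == "*":
            return [r.ref_id for r in refset]
        hits = [r.ref_id for r in refset if r.ref_id == t or ref_family.get(r.ref_id) == t]
        if not hits:
            raise SimError(f"site target {t!r} matches no reference")
        return hits

    for site in spec.mod_sites:
        explicit = site.target != "*"
        for rid in targets(site.target):
            idx = refset[rid].index_of(site.label)
            if idx is None:
                if explicit:
                    raise SimError(f"label {site.label!r} missing from reference {rid}")
                continue
            mod_by_ref[rid].append((idx, site))
    for site in spec.m5c_sites:
        explicit = site.target != "*"
        for rid in targets(site.target):
            idx = refset[rid].index_of(site.label)
            ok = idx is not None and refset[rid].mature_seq[idx] == "C"
            if not ok:
                if explicit:
                    raise SimError(f"m5C site {site.target}:{site.label}: no C at that label in {rid}")
                continue
            m5c_by_ref[rid][idx] = site.methylation_fraction
    for rid in mod_by_ref:
        mod_by_ref[rid].sort(key=lambda t: -t[0])  # 3' -> 5' walk order
    return mod_by_ref, m5c_by_ref


def simulate_reads(
    refset: ReferenceSet,
    spec: SimSpec,
    library: str,
    ref_family: dict[str, str] | None = None,
) -> tuple[list[FastqRecord], pd.DataFrame]:
    """Simulate one FASTQ library ("mock", "dm" or "bs") with per-read truth.

    DM zeroes both RT-event probabilities at demethylation-sensitive sites;
    BS libraries are demethylated first, so sensitive sites are silent there
    too, and every unmethylated C converts to T with the conversion
    efficiency.
    """
    if library not in _LIB_CODE:
        raise SimError(f"unknown library type {library!r}")
    ref_family = ref_family or {}
    mod_by_ref, m5c_by_ref = _resolve_sites(spec, refset, ref_family)
    rng = np.random.default_rng([spec.seed, _LIB_CODE[library]])

    ref_ids = refset.ref_ids
    if spec.abundance is not None:
        missing = set(spec.abundance) - set(ref_ids)
        if missing:
            raise SimError(f"abundance names unknown references: {sorted(missing)}")
        probs = np.array([spec.abundance.get(r, 0.0) for r in ref_ids])
    else:
        probs = np.full(len(ref_ids), 1.0 / len(ref_ids))

    n_dups = int(round(spec.n_reads * spec.pcr_dup_rate))
    n_molecules = spec.n_reads - n_dups
    choices = rng.choice(len(ref_ids), size=n_molecules, p=probs)
    layout = spec.layout
    adapter = layout.adapter3

    seqs = {r.ref_id: r.mature_seq for r in refset}
    c_positions = {rid: [i for i, b in enumerate(s) if b == "C"] for rid, s in seqs.items()}

    records: list[FastqRecord] = []
    truth_rows = []
    for m in range(n_molecules):
        rid = ref_ids[choices[m]]
        bases = list(seqs[rid])
        if library == "bs":
            m5c = m5c_by_ref[rid]
            cpos = c_positions[rid]
            draws = rng.random(2 * len(cpos))
            for k, i in enumerate(cpos):
                methylated = draws[2 * k] < m5c.get(i, 0.0)
                if not methylated and draws[2 * k + 1] < spec.bs_conversion_efficiency:
                    bases[i] = "T"
        start = 0
        stopped_at = -1
        n_mis = 0
        for idx, site in mod_by_ref[rid]:
            if library in ("dm", "bs") and site.demethylation_sensitive:
                continue
            if site.stop_prob and rng.random() < site.stop_prob:
                start = idx + 1
                stopped_at = idx
                break
            if site.misincorporation_prob and rng.random() < site.misincorporation_prob:
                alt = site.forced_base or [b for b in BASES if b != bases[idx]][rng.integers(3)]
                bases[idx] = alt
                n_mis += 1
        insert = bases[start:]
        if spec.seq_error_rate > 0:
            err = np.nonzero(rng.random(len(insert)) < spec.seq_error_rate)[0]
            for i in err:
                insert[i] = [b for b in BASES if b != insert[i]][rng.integers(3)]
        untemplated = start == 0 and rng.random() < spec.untemplated5_prob
        if untemplated:
            insert = [BASES[rng.integers(4)]] + insert
        umi = "".join(BASES[k] for k in rng.integers(0, 4, layout.umi5_len + layout.umi3_len))
        full = umi[: layout.umi5_len] + "".join(insert) + umi[layout.umi5_len :] + adapter
        read_id = f"{library}.{m:06d}"
        records.append(FastqRecord(read_id, full, "I" * len(full)))
        truth_rows.append({
            "read_id": read_id, "molecule_id": m, "ref_id": rid, "insert_start": start,
            "stopped_at": stopped_at, "n_misincorporated": n_mis, "umi": umi,
            "untemplated5": untemplated, "duplicate_of": "",
        })
    if n_dups:
        src = rng.integers(0, n_molecules, size=n_dups)
        for k, s in enumerate(src):
            orig = records[s]
            t = dict(truth_rows[s])
            read_id = f"{library}.{s:06d}.d{k}"
            records.append(FastqRecord(read_id, orig.seq, orig.qual))
            t.update({"read_id": read_id, "duplicate_of": orig.read_id})
            truth_rows.append(t)
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Genome-context scenario
# ---------------------------------------------------------------------------


def simulate_context_scenario(
    n_early: int = 113,
    n_late: int = 31,
    seed: int = 0,
    copies_early: tuple[int, int] = (8, 25),
    copies_late: tuple[int, int] = (1, 3),
    array_spacing: int = 300,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Genomic layout of early- vs late-expressed isodecoders.

    Early isodecoders (maternal-like) are laid out as tandem gene arrays;
    late isodecoders as isolated, scattered copies. Returns
    (BED gene table, isodecoder table with group labels, abundance fractions
    per stage with a >= 4-fold increase only for the late group).
    """
    rng = np.random.default_rng([seed, 55])
    bed_rows, iso_rows, ab_rows = [], [], []
    cursor = 10_000
    for g, (n_iso, group, crange) in enumerate(
        [(n_early, "early", copies_early), (n_late, "late", copies_late)]
    ):
        for k in range(n_iso):
            iso = f"{group}-iso{k}"
            n_copies = int(rng.integers(crange[0], crange[1] + 1))
            for c in range(n_copies):
                start = cursor + c * array_spacing if group == "early" else cursor
                if group == "late":
                    cursor += 60_000
                bed_rows.append({"chrom": "chr1", "start": start, "end": start + 73,
                                 "name": f"{iso}-copy{c}", "score": 0, "strand": "+"})
            if group == "early":
                cursor += 60_000
            iso_rows.append({"isodecoder": iso, "group": group, "n_copies": n_copies})
            if group == "early":
                f_early = float(rng.uniform(0.003, 0.01))
                f_late = f_early * float(rng.uniform(0.5, 2.0))
            else:
                # expressed above the inclusion threshold at the late stage,
                # rising at least 5-fold from the early stage
                f_late = float(rng.uniform(0.003, 0.01))
                f_early = f_late / float(rng.uniform(5.0, 20.0))
            ab_rows.append({"isodecoder": iso, "early": f_early, "late": f_late})
    bed = pd.DataFrame(bed_rows)
    iso = pd.DataFrame(iso_rows)
    abundance = pd.DataFrame(ab_rows).set_index("isodecoder")
    gene_iso = {r["name"]: r["name"].rsplit("-copy", 1)[0] for r in bed_rows}
    iso["gene_ids"] = [
        [n for n, i in gene_iso.items() if i == iso_id] for iso_id in iso["isodecoder"]
    ]
    return bed, iso, abundance


def write_bed(bed: pd.DataFrame, path: str | Path) -> None:
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"])
    return bed
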