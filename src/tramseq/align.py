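"""Read-to-reference alignment for small tRNA reference sets.

The aligner is exhaustive over references: tRNA reference sets are at most a
few hundred short sequences, so every reference is scanned for the best
end-free placement of the read (read fully aligned, reference overhangs
free) and every co-optimal reference hit is reported. The edit-distance
kernel is edlib's banded bit-parallel DP in infix ("HW") mode.

Bisulfite mode scores a read T aligned to a reference C as a match
(asymmetric C->T tolerance, implemented by lowercasing reference Cs and
declaring the equalities C==c and T==c); the observed read bases are kept,
so C/T retention can be counted from the pileup afterwards.

Within one reference, ties among co-optimal placements keep the 5'-most
start (and, at equal start, the longest reference window so terminal bases
map as mismatches rather than insertions); this makes read-start counts,
and hence RT-stop fractions, deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pysam

from .preprocess import ProcessedRead, ReadLayout, trim_untemplated_5prime
from .reference import BASES, BASE_INDEX, ReferenceSet

logger = logging.getLogger("tramseq.align")

_BS_EQUALITIES = [("C", "c"), ("T", "c")]

Ops = tuple[tuple[str, int], ...]


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-reference hit.

    ``ops`` is a run-length edit script over {'=', 'X', 'I', 'D', 'S'} that
    consumes the full (post-trim) insert; 'S' marks 5' soft-clipped read
    bases that consume no reference.
    """

    read_id: str
    ref_id: str
    ref_start: int
    ops: Ops
    n_edits: int
    n_best_hits: int
    bisulfite: bool = False

    def read_length(self) -> int:
        return sum(n for op, n in self.ops if op in "=XIS")

    def ref_span(self) -> int:
        return sum(n for op, n in self.ops if op in "=XD")


def _parse_edlib_cigar(cigar: str) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return ops


def _merge_runs(ops: Iterable[tuple[str, int]]) -> Ops:
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if n == 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return tuple(merged)


def _bs_target(seq: str) -> str:
    return seq.replace("C", "c")


def align_read(
    read_id: str,
    insert: str,
    refset: ReferenceSet,
    max_edits: int = 3,
    bisulfite: bool = False,
) -> list[AlignmentRecord]:
    """All co-optimal hits of one insert against the reference set.

    Returns every reference achieving the minimum edit distance <= max_edits
    under end-free placement, one record per reference (5'-most co-optimal
    placement), with ``n_best_hits`` set on each. Empty list = unmapped.
    """
    insert = insert.upper()
    kwargs = {"mode": "HW", "task": "locations", "k": max_edits}
    if bisulfite:
        kwargs["additionalEqualities"] = _BS_EQUALITIES
    hits: list[tuple[int, str, list[tuple[int, int]]]] = []
    best = max_edits + 1
    for ref in refset:
        target = _bs_target(ref.mature_seq) if bisulfite else ref.mature_seq
        res = edlib.align(insert, target, **kwargs)
        d = res["editDistance"]
        if d < 0 or d > max_edits:
            continue
        if d < best:
            best = d
            hits = []
        if d == best:
            hits.append((d, ref.ref_id, res["locations"]))
    if not hits:
        return []
    records = []
    for d, ref_id, locations in sorted(hits, key=lambda h: h[1]):
        start = min(s if s is not None else 0 for s, _ in locations)
        end = max(e for s, e in locations if (s if s is not None else 0) == start)
        target = refset[ref_id].mature_seq
        window = target[start : end + 1]
        if bisulfite:
            path = edlib.align(
                insert, _bs_target(window), mode="NW", task="path",
                additionalEqualities=_BS_EQUALITIES,
            )
        else:
            path = edlib.align(insert, window, mode="NW", task="path")
        ops = _parse_edlib_cigar(path["cigar"])
        # read bases inserted 5' of the mapped region are soft-clips
        if ops and ops[0][0] == "I":
            ops[0] = ("S", ops[0][1])
        records.append(
            AlignmentRecord(
                read_id=read_id,
                ref_id=ref_id,
                ref_start=start,
                ops=_merge_runs(ops),
                n_edits=d,
                n_best_hits=len(hits),
                bisulfite=bisulfite,
            )
        )
    return records


def align_reads(
    reads: Sequence[ProcessedRead],
    refset: ReferenceSet,
    max_edits: int = 3,
    bisulfite: bool = False,
    layout: ReadLayout | None = None,
    trim_untemplated: bool = True,
) -> tuple[dict[str, list[AlignmentRecord]], dict[str, str], list[ProcessedRead]]:
    """Align processed reads; returns (hits per read, final insert per read,
    unmapped reads).

    When ``trim_untemplated`` is set, reads whose best hit starts with
    soft-clipped or mismatched 5' bases are trimmed (up to the layout cap)
    and realigned, so untemplated additions by the RT do not shift
    read-start positions.
    """
    layout = layout or ReadLayout()
    hits_by_read: dict[str, list[AlignmentRecord]] = {}
    inserts: dict[str, str] = {}
    unmapped: list[ProcessedRead] = []
    for read in reads:
        records = align_read(read.read_id, read.insert, refset, max_edits, bisulfite)
        if records and trim_untemplated:
            trimmed, _ = trim_untemplated_5prime(read, records[0], layout)
            if len(trimmed.insert) != len(read.insert):
                records = align_read(read.read_id, trimmed.insert, refset, max_edits, bisulfite)
                read = trimmed
        if records:
            hits_by_read[read.read_id] = records
            inserts[read.read_id] = read.insert
        else:
            unmapped.append(read)
    return hits_by_read, inserts, unmapped


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------


_ASCII_TO_BASE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _ASCII_TO_BASE[ord(_b)] = _i


class PositionStats:
    """Per-reference per-position counts from a set of alignments."""

    def __init__(self, length: int):
        self.base_counts = np.zeros((length, 4), dtype=np.int64)
        self.deletion_count = np.zeros(length, dtype=np.int64)
        self.read_start_count = np.zeros(length, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.deletion_count)

    @property
    def coverage(self) -> np.ndarray:
        return self.base_counts.sum(axis=1) + self.deletion_count

    def __add__(self, other: "PositionStats") -> "PositionStats":
        if len(self) != len(other):
            raise ValueError("cannot add PositionStats of different lengths")
        out = PositionStats(len(self))
        out.base_counts = self.base_counts + other.base_counts
        out.deletion_count = self.deletion_count + other.deletion_count
        out.read_start_count = self.read_start_count + other.read_start_count
        return out


def pileup(
    records: Iterable[AlignmentRecord],
    refset: ReferenceSet,
    reads: Mapping[str, str],
) -> dict[str, PositionStats]:
    """Build per-reference position statistics from alignment records.

    ``reads`` maps read_id -> insert sequence (as aligned). The multimapper
    assignment policy is the caller's: pass all co-optimal records for
    all-best counting, or uniquely-assigned records for assigned counting.
    """
    stats = {ref.ref_id: PositionStats(len(ref.mature_seq)) for ref in refset}
    for rec in records:
        st = stats[rec.ref_id]
        seq = reads[rec.read_id].upper()
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        q = 0
        p = rec.ref_start
        first_mapped = None
        for op, n in rec.ops:
            if op == "S" or op == "I":
                q += n
            elif op in "=X":
                if first_mapped is None:
                    first_mapped = p
                cols = _ASCII_TO_BASE[codes[q : q + n]]
                valid = cols >= 0  # non-ACGT calls add nothing
                rows = np.arange(p, p + n)[valid]
                st.base_counts[rows, cols[valid]] += 1
                q += n
                p += n
            elif op == "D":
                if first_mapped is None:
                    first_mapped = p
                st.deletion_count[p : p + n] += 1
                p += n
            else:
                raise ValueError(f"unknown op {op!r}")
        if p > len(st):
            raise ValueError(f"{rec.read_id}: alignment overruns reference {rec.ref_id}")
        if first_mapped is not None:
            st.read_start_count[first_mapped] += 1
    return stats


def mapped_counts(records_by_read: Mapping[str, list[AlignmentRecord]]) -> dict[str, int]:
    """Reads per reference counting each read once per co-optimal hit."""
    counts: dict[str, int] = {}
    for records in records_by_read.values():
        for rec in records:
            counts[rec.ref_id] = counts.get(rec.ref_id, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# SAM import/export
# ---------------------------------------------------------------------------

_OP_TO_CIGAR = {"=": 7, "X": 8, "I": 1, "D": 2, "S": 4}
_CIGAR_TO_OP = {0: "M", 1: "I", 2: "D", 4: "S", 7: "=", 8: "X"}


def _md_tag(ops: Ops, ref_seq: str, ref_start: int) -> str:
    md = []
    match_run = 0
    p = ref_start
    for op, n in ops:
        if op == "=":
            match_run += n
            p += n
        elif op == "X":
            for k in range(n):
                md.append(str(match_run))
                md.append(ref_seq[p + k])
                match_run = 0
            p += n
        elif op == "D":
            md.append(str(match_run))
            md.append("^" + ref_seq[p : p + n])
            match_run = 0
            p += n
    md.append(str(match_run))
    return "".join(md)


def write_sam(
    records: Iterable[AlignmentRecord],
    refset: ReferenceSet,
    path: str | Path,
    reads: Mapping[str, str],
) -> None:
    """Write alignment records as SAM with @SQ headers, NH/NM/MD tags and a
    ZB flag for bisulfite-mode alignments."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": ref.ref_id, "LN": len(ref.mature_seq)} for ref in refset],
    }
    tids = {ref.ref_id: i for i, ref in enumerate(refset)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.read_id
            seg.flag = 0
            seg.reference_id = tids[rec.ref_id]
            seg.reference_start = rec.ref_start
            seg.mapping_quality = 255
            seg.cigartuples = [(_OP_TO_CIGAR[op], n) for op, n in rec.ops]
            seq = reads[rec.read_id]
            seg.query_sequence = seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            ref_seq = refset[rec.ref_id].mature_seq
            if rec.ref_start + rec.ref_span() > len(ref_seq):
                raise ValueError(f"{rec.read_id}: CIGAR overruns reference {rec.ref_id}")
            seg.set_tag("NH", rec.n_best_hits)
            seg.set_tag("NM", rec.n_edits)
            seg.set_tag("MD", _md_tag(rec.ops, ref_seq, rec.ref_start))
            seg.set_tag("ZB", 1 if rec.bisulfite else 0)
            out.write(seg)


def read_sam(path: str | Path, refset: ReferenceSet) -> tuple[list[AlignmentRecord], dict[str, str]]:
    """Read SAM into alignment records; returns (records, read sequences).

    External cigars using M are resolved into '='/'X' runs against the
    reference sequence. @SQ lines must be consistent with the reference set.
    """
    records: list[AlignmentRecord] = []
    seqs: dict[str, str] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for sq in sam.header.get("SQ", []):
            name = sq["SN"]
            if name not in refset:
                raise ValueError(f"@SQ {name} not in reference set")
            if sq["LN"] != len(refset[name].mature_seq):
                raise ValueError(f"@SQ {name} length mismatch with reference set")
        for seg in sam:
            if seg.is_unmapped or seg.query_sequence is None:
                continue
            ref_id = seg.reference_name
            ref_seq = refset[ref_id].mature_seq
            ops: list[tuple[str, int]] = []
            q = 0
            p = seg.reference_start
            read_seq = seg.query_sequence.upper()
            for code, n in seg.cigartuples:
                op = _CIGAR_TO_OP.get(code)
                if op is None:
                    raise ValueError(f"{seg.query_name}: unsupported CIGAR op {code}")
                if op == "M":
                    if p + n > len(ref_seq):
                        raise ValueError(f"{seg.query_name}: CIGAR overruns {ref_id}")
                    for k in range(n):
                        ops.append(("=" if read_seq[q + k] == ref_seq[p + k] else "X", 1))
                    q += n
                    p += n
                elif op in "=X":
                    ops.append((op, n))
                    q += n
                    p += n
                elif op in "IS":
                    ops.append((op, n))
                    q += n
                else:  # D
                    ops.append((op, n))
                    p += n
            if p > len(ref_seq):
                raise ValueError(f"{seg.query_name}: POS/CIGAR overruns reference {ref_id}")
            n_edits = seg.get_tag("NM") if seg.has_tag("NM") else sum(
                n for op, n in ops if op in "XID"
            )
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    ref_id=ref_id,
                    ref_start=seg.reference_start,
                    ops=_merge_runs(ops),
                    n_edits=int(n_edits),
                    n_best_hits=int(seg.get_tag("NH")) if seg.has_tag("NH") else 1,
                    bisulfite=bool(seg.get_tag("ZB")) if seg.has_tag("ZB") else False,
                )
            )
            seqs[seg.query_name] = read_seq
    return records, seqs


def group_by_read(records: Iterable[AlignmentRecord]) -> dict[str, list[AlignmentRecord]]:
    grouped: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.read_id, []).append(rec)
    return grouped
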