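"""FASTQ preprocessing: insert/UMI extraction, filtering, deduplication.

The sequencing library is built by 3'-adapter ligation followed by reverse
transcription and cDNA circularization, which places the RT primer's three
5' randomers in front of the insert in the sequenced strand. A read is
therefore laid out as::

    [umi5 (3 nt)][tRNA insert][umi3 (6 nt)][3' adapter ...]

The two randomer blocks are concatenated into a 9-nt unique molecular
identifier (UMI) used to collapse PCR duplicates.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

REJECT_REASONS = ("no_adapter", "too_short", "too_long", "low_quality")


@dataclass
class ReadLayout:
    """Library read layout and filtering parameters."""

    umi5_len: int = 3
    umi3_len: int = 6
    adapter3: str = "CTGTAGGCACCATCAAT"
    max_untemplated5: int = 2
    min_insert: int = 20
    max_insert: int = 300
    min_mean_q: float = 20.0
    min_adapter_overlap: int = 10

    def __post_init__(self) -> None:
        if self.umi5_len < 0 or self.umi3_len < 0:
            raise ValueError("UMI lengths must be >= 0")
        if not self.adapter3:
            raise ValueError("adapter3 must be non-empty")

    @property
    def umi_len(self) -> int:
        return self.umi5_len + self.umi3_len


@dataclass
class ProcessedRead:
    """A read reduced to its insert, with the UMI and mean insert quality."""

    read_id: str
    insert: str
    umi: str
    mean_q: float


@dataclass
class RejectedRead:
    read_id: str
    reason: str


@dataclass
class FastqRecord:
    read_id: str
    seq: str
    qual: str


def _mean_phred(qual: str) -> float:
    if not qual:
        return 0.0
    return sum(ord(c) - 33 for c in qual) / len(qual)


def find_adapter(seq: str, adapter: str, start: int, min_overlap: int) -> int | None:
    """Leftmost position >= start where a prefix of ``adapter`` matches,
    allowing 1 mismatch per 10 compared adapter bases. Returns None when the
    adapter is absent (a full-length insert without adapter is unusable
    because the 3' UMI cannot be delimited)."""
    n = len(seq)
    for j in range(start, n - min(min_overlap, len(adapter)) + 1):
        span = min(len(adapter), n - j)
        allowed = span // 10
        mismatches = 0
        ok = True
        for k in range(span):
            if seq[j + k] != adapter[k]:
                mismatches += 1
                if mismatches > allowed:
                    ok = False
                    break
        if ok:
            return j
    return None


def extract_insert(read: FastqRecord, layout: ReadLayout | None = None) -> ProcessedRead | RejectedRead:
    """Parse one read into (insert, UMI) per the library layout, or reject it.

    Reject reasons: ``no_adapter`` (3' adapter not located), ``too_short`` /
    ``too_long`` (insert outside [min_insert, max_insert]), ``low_quality``
    (mean insert Phred below min_mean_q).
    """
    layout = layout or ReadLayout()
    seq, qual = read.seq.upper(), read.qual
    if len(seq) < layout.umi_len + layout.min_insert:
        return RejectedRead(read.read_id, "too_short")
    j = find_adapter(seq, layout.adapter3, layout.umi_len, layout.min_adapter_overlap)
    if j is None:
        return RejectedRead(read.read_id, "no_adapter")
    insert_end = j - layout.umi3_len
    if insert_end - layout.umi5_len < layout.min_insert:
        return RejectedRead(read.read_id, "too_short")
    insert = seq[layout.umi5_len : insert_end]
    if len(insert) > layout.max_insert:
        return RejectedRead(read.read_id, "too_long")
    umi = seq[: layout.umi5_len] + seq[insert_end:j]
    mean_q = _mean_phred(qual[layout.umi5_len : insert_end])
    if mean_q < layout.min_mean_q:
        return RejectedRead(read.read_id, "low_quality")
    return ProcessedRead(read.read_id, insert, umi, mean_q)


def deduplicate(reads: Iterable[ProcessedRead]) -> tuple[list[ProcessedRead], dict]:
    """Collapse PCR duplicates by (insert sequence, UMI).

    One representative per group is kept: highest mean quality, ties broken
    by lexicographically smallest read id. The dedup key is alignment-free —
    tRNA inserts are short and fully sequenced, so the full insert plus UMI
    identifies the molecule without committing to one mapping position.
    """
    groups: dict[tuple[str, str], list[ProcessedRead]] = {}
    for r in reads:
        groups.setdefault((r.insert, r.umi), []).append(r)
    survivors = []
    hist: Counter[int] = Counter()
    n_in = 0
    for key in sorted(groups):
        members = groups[key]
        n_in += len(members)
        hist[len(members)] += 1
        survivors.append(min(members, key=lambda r: (-r.mean_q, r.read_id)))
    stats = {
        "input_reads": n_in,
        "unique_molecules": len(survivors),
        "duplicates_removed": n_in - len(survivors),
        "umi_family_size_hist": dict(sorted(hist.items())),
    }
    return survivors, stats


def trim_untemplated_5prime(
    processed: ProcessedRead,
    best_alignment,
    layout: ReadLayout | None = None,
):
    """Remove up to ``max_untemplated5`` untemplated bases from the insert's
    5' end, guided by the best alignment.

    Reverse transcriptases such as TGIRT add non-templated nucleotides when
    running off the template 5' end; after alignment these appear as leading
    soft-clipped bases (insert starts before the reference 5' end) or
    leading mismatches. Trimming never removes matching bases. Returns
    ``(trimmed ProcessedRead, adjusted AlignmentRecord)``.
    """
    layout = layout or ReadLayout()
    cap = layout.max_untemplated5
    ops = list(best_alignment.ops)
    ref_start = best_alignment.ref_start
    n_edits = best_alignment.n_edits
    trim = 0
    while ops and trim < cap:
        op, length = ops[0]
        if op == "S":
            take = min(length, cap - trim)
            trim += take
            if take == length:
                ops.pop(0)
            else:
                ops[0] = (op, length - take)
            n_edits -= take
        elif op == "X":
            take = min(length, cap - trim)
            trim += take
            ref_start += take
            n_edits -= take
            if take == length:
                ops.pop(0)
            else:
                ops[0] = (op, length - take)
        else:
            break
    if trim == 0:
        return processed, best_alignment
    trimmed = ProcessedRead(
        read_id=processed.read_id,
        insert=processed.insert[trim:],
        umi=processed.umi,
        mean_q=processed.mean_q,
    )
    from dataclasses import replace  # local import avoids cycle at module load

    record = replace(best_alignment, ops=ops, ref_start=ref_start, n_edits=max(n_edits, 0))
    return trimmed, record


# ---------------------------------------------------------------------------
# FASTQ I/O (gzip-transparent)
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    with _open_text(path) as fh:
        while True:
            header = fh.readline().rstrip()
            if not header:
                return
            seq = fh.readline().rstrip()
            fh.readline()
            qual = fh.readline().rstrip()
            yield FastqRecord(header[1:].split()[0], seq, qual)


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")


def preprocess_fastq(
    in_path: str | Path,
    layout: ReadLayout | None = None,
    rejects_path: str | Path | None = None,
) -> tuple[list[ProcessedRead], dict]:
    """Extract inserts from a FASTQ file and deduplicate; returns survivors
    and a stats dict (extraction counts by reason + dedup stats)."""
    layout = layout or ReadLayout()
    processed: list[ProcessedRead] = []
    rejects: list[tuple[FastqRecord, str]] = []
    n_total = 0
    for rec in read_fastq(in_path):
        n_total += 1
        out = extract_insert(rec, layout)
        if isinstance(out, ProcessedRead):
            processed.append(out)
        else:
            rejects.append((rec, out.reason))
    if rejects_path is not None:
        write_fastq(
            (FastqRecord(f"{r.read_id} reason={reason}", r.seq, r.qual) for r, reason in rejects),
            rejects_path,
        )
    survivors, dedup_stats = deduplicate(processed)
    reason_counts = Counter(reason for _, reason in rejects)
    stats = {
        "total_reads": n_total,
        "extracted": len(processed),
        "rejected": {k: reason_counts.get(k, 0) for k in REJECT_REASONS},
        **dedup_stats,
    }
    return survivors, stats


def write_stats(stats: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(stats, indent=2) + "\n")
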