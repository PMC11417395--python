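import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from tramseq.reference import ReferenceSeq, ReferenceSet, default_numbering_alignment
from tramseq.simulate import backbone_variant


def make_ref(ref_id: str, seq: str, labels=None, **kw) -> ReferenceSeq:
    ref = ReferenceSeq(ref_id=ref_id, mature_seq=seq, source_gene_ids=[ref_id], **kw)
    if labels is not None:
        ref.canonical_map = {i: lab for i, lab in enumerate(labels)}
    else:
        ref.canonical_map = {i: str(i + 1) for i in range(len(seq))}
    return ref


@pytest.fixture(scope="session")
def numbering_alignment():
    return default_numbering_alignment()


@pytest.fixture()
def backbone_refset():
    """Three well-separated backbone variants with truth numbering."""
    refs = []
    for rid, ac, subs in [
        ("Phe-GAA-1", "GAA", {}),
        ("Gly-GCC-1", "GCC", {4: "T", 22: "A", 47: "A", 60: "T", 67: "C"}),
        ("Asp-GTC-1", "GTC", {2: "A", 12: "C", 28: "T", 43: "C", 55: "A", 70: "T"}),
    ]:
        seq, labels = backbone_variant(ac, substitutions=subs)
        refs.append(make_ref(rid, seq, labels, anticodon=ac, amino_acid=rid.split("-")[0]))
    return ReferenceSet(refs)
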