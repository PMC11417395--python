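"""Reference building, maturation, canonical numbering, filtering, polish."""

import numpy as np
import pandas as pd
import pytest

from tramseq.align import PositionStats
from tramseq.reference import (
    NumberingError,
    ReferenceError,
    ReferenceFilterParams,
    ReferenceSeq,
    ReferenceSet,
    TRNAGene,
    assign_canonical_numbering,
    build_reference_set,
    filter_references_by_coverage,
    maturate_sequence,
    parse_gene_header,
    polish_reference_snps,
    read_stockholm,
    sprinzl_key,
    validate_canonical_map,
    write_stockholm,
)
from tramseq.simulate import backbone_variant

from conftest import make_ref


def gene(gene_id, seq, aa="Gly", ac="GCC", origin="nuclear", intron=None):
    return TRNAGene(gene_id=gene_id, origin=origin, amino_acid=aa, anticodon=ac,
                    genomic_seq=seq, intron=intron)


BODY = backbone_variant("GCC")[0][:-3]  # genomic form (no CCA)


class TestBuildReferenceSet:
    def test_identical_mature_sequences_collapse(self):
        refset = build_reference_set(genes=[gene("g1", BODY), gene("g2", BODY)])
        assert len(refset) == 1
        (ref,) = list(refset)
        assert ref.source_gene_ids == ["g1", "g2"]

    def test_mito_references_stay_single_copy(self):
        from itertools import product

        triplets = ["".join(p) for p in product("ACGT", repeat=3)][:22]
        genes = [gene(f"mt{i}", BODY[:40] + triplets[i] + BODY[43:], origin="mito")
                 for i in range(22)]
        refset = build_reference_set(genes=genes)
        mito = [r for r in refset if r.origin == "mito"]
        assert len(mito) == 22
        assert all(len(r.source_gene_ids) == 1 for r in mito)

    def test_distinct_sequences_brute_force_dedup(self):
        variants = [BODY, BODY, BODY[:10] + "A" + BODY[11:], BODY[:10] + "A" + BODY[11:],
                    BODY[:20] + "T" + BODY[21:]]
        genes = [gene(f"g{i}", v) for i, v in enumerate(variants)]
        refset = build_reference_set(genes=genes)
        assert len(refset) == len({maturate_sequence(g) for g in genes}) == 3
        all_sources = sorted(sum((r.source_gene_ids for r in refset), []))
        assert all_sources == [f"g{i}" for i in range(5)]

    def test_collapse_is_idempotent(self):
        refset = build_reference_set(genes=[gene("g1", BODY), gene("g2", BODY)])
        again = build_reference_set(
            genes=[gene(r.ref_id, r.mature_seq[:-3]) for r in refset]
        )
        assert sorted(r.mature_seq for r in again) == sorted(r.mature_seq for r in refset)

    def test_empty_input_is_a_hard_error(self):
        with pytest.raises(ReferenceError):
            build_reference_set(genes=[])


class TestMaturation:
    def test_cca_appended_when_not_encoded(self):
        assert maturate_sequence(gene("g", BODY)).endswith("CCA")
        assert maturate_sequence(gene("g", BODY)) == BODY + "CCA"

    def test_encoded_cca_not_duplicated(self):
        assert maturate_sequence(gene("g", BODY + "CCA")) == BODY + "CCA"

    def test_his_gets_5prime_g(self):
        his = gene("h", "A" + BODY[1:], aa="His", ac="GTG")
        assert maturate_sequence(his) == "G" + "A" + BODY[1:] + "CCA"

    def test_intron_removed_length_arithmetic(self):
        precursor = BODY[:37] + "TTTTTTTTTTTTTTTTTTTTTT" + BODY[37:]
        g = gene("g", precursor, intron=(38, 59))
        mature = maturate_sequence(g)
        assert len(mature) == len(precursor) - 22 + 3
        assert mature == BODY + "CCA"


class TestHeaderParsing:
    def test_gtrnadb_dialect(self):
        g = parse_gene_header("Danio_rerio_tRNA-Asp-GTC-2-1 chr4:100-172(+)", BODY)
        assert (g.amino_acid, g.anticodon) == ("Asp", "GTC")
        assert g.locus == ("chr4", 100, 172, "+")

    def test_pipe_dialect_and_intron(self):
        g = parse_gene_header("myid|Leu|CAA intron:38-59", BODY)
        assert (g.amino_acid, g.anticodon, g.intron) == ("Leu", "CAA", (38, 59))

    def test_malformed_header_raises_with_header_echoed(self):
        with pytest.raises(ReferenceError, match="some junk"):
            parse_gene_header("some junk", BODY)


class TestCanonicalNumbering:
    def test_backbone_identity_transfer(self, numbering_alignment):
        seq, labels = backbone_variant("GTC")
        ref = make_ref("r", seq, anticodon="GTC")
        cmap = assign_canonical_numbering(ref, numbering_alignment)
        assert [cmap[i] for i in range(len(seq))] == labels

    def test_variable_arm_gets_e_labels(self, numbering_alignment):
        seq, labels = backbone_variant("GCT", var_arm_insert="GGTTCGACTCC")
        ref = make_ref("ser", seq, anticodon="GCT")
        cmap = assign_canonical_numbering(ref, numbering_alignment)
        assert "e2" in cmap.values()
        assert [cmap[i] for i in range(len(seq))] == labels

    def test_dloop_insertion_labelled_20a(self, numbering_alignment):
        seq, labels = backbone_variant("TGC", d_loop_insert="T")
        ref = make_ref("d", seq, anticodon="TGC")
        cmap = assign_canonical_numbering(ref, numbering_alignment)
        idx = labels.index("20a")
        assert cmap[idx] == "20a"

    def test_his_minus_one(self, numbering_alignment):
        seq, _ = backbone_variant("GTG", his_g=True)
        ref = make_ref("h", seq, anticodon="GTG")
        cmap = assign_canonical_numbering(ref, numbering_alignment)
        assert cmap[0] == "-1"

    def test_anticodon_must_land_on_34_36(self, numbering_alignment):
        seq, _ = backbone_variant("GTC")
        ref = make_ref("bad", seq, anticodon="AAA")  # claims a different anticodon
        with pytest.raises(NumberingError):
            assign_canonical_numbering(ref, numbering_alignment)

    def test_unnumberable_reference_error(self, numbering_alignment):
        ref = make_ref("junk", "ACGT" * 19, anticodon="NNN")
        with pytest.raises(NumberingError, match="junk"):
            assign_canonical_numbering(ref, numbering_alignment, min_score_frac=0.9)

    def test_numbering_round_trip_on_mutated_variants(self, numbering_alignment):
        """Labels recovered from the alignment match the generating truth on
        >= 99% of positions across mutated structural variants."""
        rng = np.random.default_rng(11)
        total = agree = 0
        for k in range(12):
            subs = {}
            for i in rng.choice([i for i in range(76) if i not in (33, 34, 35)], 6, replace=False):
                subs[int(i)] = "ACGT"[rng.integers(4)]
            kw = {}
            if k % 3 == 1:
                kw["d_loop_insert"] = "TA"[: 1 + k % 2]
            if k % 4 == 2:
                kw["var_arm_insert"] = "GGTTCGACT"
            seq, labels = backbone_variant("GAA", substitutions=subs, **kw)
            ref = make_ref(f"v{k}", seq, anticodon=None)
            ref.anticodon = "NNN"
            cmap = assign_canonical_numbering(ref, numbering_alignment)
            got = [cmap[i] for i in range(len(seq))]
            agree += sum(a == b for a, b in zip(got, labels))
            total += len(labels)
        assert agree / total >= 0.99

    def test_sprinzl_order_keys(self):
        order = ["-1", "1", "20", "20a", "20b", "21", "45", "e1", "e2", "46", "76"]
        keys = [sprinzl_key(x) for x in order]
        assert keys == sorted(keys)

    def test_validate_rejects_unordered_map(self):
        with pytest.raises(ReferenceError):
            validate_canonical_map("ACG", {0: "2", 1: "1", 2: "3"})


class TestCoverageFilter:
    def counts(self, **cols):
        return pd.DataFrame(cols, index=["ref1"])

    def test_rpm_threshold_is_inclusive(self):
        refset = ReferenceSet([make_ref("ref1", BODY + "CCA")])
        pad = pd.DataFrame({"s1": [999_400], "s2": [999_500]}, index=["pad"])
        # 600 reads in a million-read sample -> 600 RPM, kept
        counts = pd.concat([self.counts(s1=600, s2=500), pad])
        kept, dropped = filter_references_by_coverage(refset, counts)
        assert "ref1" in kept and dropped.empty

    def test_boundary_499_dropped_500_kept(self):
        refset = ReferenceSet([make_ref("ref1", BODY + "CCA")])
        pad = pd.DataFrame({"s1": [999_501], "s2": [999_501]}, index=["pad"])
        counts = pd.concat([self.counts(s1=499, s2=499), pad])
        kept, dropped = filter_references_by_coverage(refset, counts)
        assert len(kept) == 0 and list(dropped["ref_id"]) == ["ref1"]
        pad = pd.DataFrame({"s1": [999_501], "s2": [999_500]}, index=["pad"])
        counts = pd.concat([self.counts(s1=499, s2=500), pad])
        kept, _ = filter_references_by_coverage(refset, counts)
        assert "ref1" in kept  # 500 RPM in exactly one sample suffices

    def test_zero_count_reference_dropped(self):
        refset = ReferenceSet([make_ref("ref1", BODY + "CCA"), make_ref("ref2", BODY[:-1] + "TCCA")])
        counts = pd.DataFrame({"s1": [10_000, 0]}, index=["ref1", "ref2"])
        kept, dropped = filter_references_by_coverage(refset, counts)
        assert kept.ref_ids == ["ref1"]
        assert dropped.loc[0, "max_rpm"] == 0

    def test_filter_monotone_in_min_rpm(self):
        rng = np.random.default_rng(0)
        refs = [make_ref(f"r{i}", BODY[:10] + "ACGT"[i % 4] + BODY[11:] + "CCA") for i in range(8)]
        refset = ReferenceSet(refs)
        counts = pd.DataFrame(
            {s: rng.integers(0, 2000, size=8) for s in ("a", "b")},
            index=[r.ref_id for r in refs],
        )
        kept_sets = []
        for t in (100.0, 400.0, 800.0):
            kept, _ = filter_references_by_coverage(refset, counts, ReferenceFilterParams(min_rpm=t))
            kept_sets.append(set(kept.ref_ids))
        assert kept_sets[2] <= kept_sets[1] <= kept_sets[0]

    def test_zero_total_sample_is_an_error(self):
        refset = ReferenceSet([make_ref("ref1", BODY + "CCA")])
        counts = pd.DataFrame({"bad_sample": [0]}, index=["ref1"])
        with pytest.raises(ReferenceError, match="bad_sample"):
            filter_references_by_coverage(refset, counts)


class TestSnpPolish:
    def pileup_for(self, seq, pos, alt, frac, cov):
        st = PositionStats(len(seq))
        for i, b in enumerate(seq):
            st.base_counts[i, "ACGT".index(b)] = cov
        n_alt = int(round(frac * cov))
        st.base_counts[pos, "ACGT".index(seq[pos])] = cov - n_alt
        st.base_counts[pos, "ACGT".index(alt)] = n_alt
        return st

    def test_high_frequency_snp_substituted_and_logged(self):
        seq = BODY + "CCA"
        assert seq[30] == backbone_variant("GCC")[0][30]
        ref = make_ref("r", seq)
        alt = "G" if seq[30] != "G" else "T"
        piles = {"r": self.pileup_for(seq, 30, alt, 0.95, 200)}
        polished, log = polish_reference_snps(ReferenceSet([ref]), piles)
        assert polished["r"].mature_seq[30] == alt
        assert log.iloc[0].to_dict() == {
            "ref_id": "r", "position": 30, "old": seq[30], "new": alt, "af": 0.95
        }
        assert polished["r"].canonical_map == ref.canonical_map

    @pytest.mark.parametrize("frac", [0.6, 0.4])
    def test_sub_threshold_sites_untouched(self, frac):
        """Modification-level mismatch fractions (< 0.8) must never be
        rewritten into the reference."""
        seq = BODY + "CCA"
        ref = make_ref("r", seq)
        alt = "G" if seq[30] != "G" else "T"
        piles = {"r": self.pileup_for(seq, 30, alt, frac, 500)}
        polished, log = polish_reference_snps(ReferenceSet([ref]), piles)
        assert polished["r"].mature_seq == seq and log.empty

    def test_low_coverage_sites_untouched(self):
        seq = BODY + "CCA"
        ref = make_ref("r", seq)
        alt = "G" if seq[30] != "G" else "T"
        piles = {"r": self.pileup_for(seq, 30, alt, 0.95, 20)}
        polished, log = polish_reference_snps(ReferenceSet([ref]), piles, min_cov=50)
        assert polished["r"].mature_seq == seq and log.empty


class TestStockholmDialect:
    def test_round_trip(self, tmp_path, numbering_alignment):
        path = tmp_path / "aln.sto"
        write_stockholm(numbering_alignment, path)
        back = read_stockholm(path)
        assert back.rows == numbering_alignment.rows
        assert back.col_labels == numbering_alignment.col_labels

    def test_missing_annotation_rejected(self, tmp_path):
        path = tmp_path / "bad.sto"
        path.write_text("# STOCKHOLM 1.0\nseq1 ACGT\n//\n")
        with pytest.raises(ReferenceError):
            read_stockholm(path)
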