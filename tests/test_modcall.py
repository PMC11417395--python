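"""Misincorporation, RT-stop and C-retention profiles; site classification."""

import numpy as np
import pandas as pd
import pytest

from tramseq.align import PositionStats, align_reads
from tramseq.cluster import Cluster, ClusterSet, cluster_by_similarity
from tramseq.modcall import (
    c_retention_profile,
    classify_sites,
    misincorporation_profile,
    profile_matrix,
    retention_per_reference,
    rt_stop_profile,
)
from tramseq.preprocess import extract_insert
from tramseq.quantify import assign_multimappers
from tramseq.reference import BASE_INDEX, ReferenceSet
from tramseq.simulate import ModSite, M5CSite, SimSpec, backbone_variant, simulate_reads, simulate_reference

from conftest import make_ref


def stats_for(seq, cov):
    """Error-free full coverage pileup."""
    st = PositionStats(len(seq))
    for i, b in enumerate(seq):
        st.base_counts[i, BASE_INDEX[b]] = cov
    st.read_start_count[0] = cov
    return st


def run_library(spec, refset, truth, library):
    reads, _ = simulate_reads(refset, spec, library, truth["ref_family"])
    processed = [extract_insert(r, spec.layout) for r in reads]
    hits, inserts, _ = align_reads(processed, refset, bisulfite=(library == "bs"))
    assigned = assign_multimappers(hits, seed=1)
    from tramseq.align import pileup

    return {f"{library}1": pileup(assigned, refset, inserts)}


class TestMisincorporation:
    def test_unmodified_error_free_is_zero_everywhere(self):
        seq, labels = backbone_variant("GAA")
        ref = make_ref("a", seq, labels)
        refset = ReferenceSet([ref])
        clusters = ClusterSet([Cluster("c", ["a"])])
        piles = {"s1": {"a": stats_for(seq, 100)}}
        prof = misincorporation_profile(piles, clusters, refset)
        assert (prof["value"] == 0).all()

    def test_intra_cluster_variants_are_not_mismatches(self):
        """Reads matching their own member reference at a polymorphic
        position contribute zero mismatch there."""
        seq1, labels = backbone_variant("CTG")
        seq2, _ = backbone_variant("TTG")
        refs = ReferenceSet([
            make_ref("q1", seq1, labels, anticodon="CTG"),
            make_ref("q2", seq2, labels, anticodon="TTG"),
        ])
        clusters = ClusterSet([Cluster("c", ["q1", "q2"])])
        piles = {"s1": {"q1": stats_for(seq1, 50), "q2": stats_for(seq2, 80)}}
        prof = misincorporation_profile(piles, clusters, refs)
        at34 = prof[prof["canonical_label"] == "34"].iloc[0]
        assert at34["value"] == 0.0 and at34["coverage"] == 130

    def test_deletions_count_toward_mismatch(self):
        seq, labels = backbone_variant("GAA")
        ref = make_ref("a", seq, labels)
        st = stats_for(seq, 100)
        st.base_counts[30, BASE_INDEX[seq[30]]] -= 10
        st.deletion_count[30] = 10
        prof = misincorporation_profile(
            {"s1": {"a": st}}, ClusterSet([Cluster("c", ["a"])]), ReferenceSet([ref])
        )
        row = prof[prof["canonical_label"] == "31"].iloc[0]
        assert row["value"] == pytest.approx(0.10)

    def test_cluster_rate_is_coverage_weighted_member_mean(self):
        seq1, labels = backbone_variant("CTG")
        seq2, _ = backbone_variant("TTG")
        refs = ReferenceSet([
            make_ref("q1", seq1, labels, anticodon="CTG"),
            make_ref("q2", seq2, labels, anticodon="TTG"),
        ])
        st1, st2 = stats_for(seq1, 200), stats_for(seq2, 50)
        # 20% mismatch on member 1 at position 57 (label 58), 4% on member 2
        for st, n in ((st1, 40), (st2, 2)):
            st.base_counts[57, BASE_INDEX[seq1[57]]] -= n
            st.base_counts[57, (BASE_INDEX[seq1[57]] + 1) % 4] += n
        prof = misincorporation_profile(
            {"s1": {"q1": st1, "q2": st2}}, ClusterSet([Cluster("c", ["q1", "q2"])]), refs
        )
        row = prof[prof["canonical_label"] == "58"].iloc[0]
        w = (200 * 0.20 + 50 * 0.04) / 250  # coverage-weighted mean
        assert row["value"] == pytest.approx(w) == pytest.approx(42 / 250)

    def test_low_coverage_is_missing_not_zero(self):
        seq, labels = backbone_variant("GAA")
        ref = make_ref("a", seq, labels)
        prof = misincorporation_profile(
            {"s1": {"a": stats_for(seq, 5)}}, ClusterSet([Cluster("c", ["a"])]),
            ReferenceSet([ref]), min_cov=20,
        )
        assert prof["value"].isna().all()


class TestRtStops:
    def test_full_length_reads_have_zero_stops(self):
        seq, labels = backbone_variant("GAA")
        ref = make_ref("a", seq, labels)
        prof = rt_stop_profile(
            {"s1": {"a": stats_for(seq, 100)}}, ClusterSet([Cluster("c", ["a"])]), ReferenceSet([ref])
        )
        internal = prof[prof["canonical_label"] != str(len(seq))]
        assert (internal["value"].dropna() == 0).all()

    def test_simulated_stop_recovered_with_reads_starting_downstream(self):
        spec = SimSpec(
            n_families=1, copies_per_family=(1, 1), n_reads=3000, seed=13,
            mod_sites=[ModSite("fam0", "37", stop_prob=0.5, demethylation_sensitive=False)],
        )
        refset, _, truth = simulate_reference(spec)
        piles = run_library(spec, refset, truth, "mock")
        clusters = cluster_by_similarity(refset)
        prof = rt_stop_profile(piles, clusters, refset)
        stop37 = prof[prof["canonical_label"] == "37"]["value"].iloc[0]
        assert stop37 == pytest.approx(0.5, abs=0.03)
        ref = list(refset)[0]
        st = piles["mock1"][ref.ref_id]
        i38 = ref.index_of("38")
        assert st.read_start_count[i38] > 1000  # truncated reads begin at 38

    def test_mixed_signature_site_recovers_both_truths(self):
        spec = SimSpec(
            n_families=1, copies_per_family=(1, 1), n_reads=4000, seed=19,
            mod_sites=[ModSite("fam0", "37", misincorporation_prob=0.3, stop_prob=0.4,
                               demethylation_sensitive=False)],
        )
        refset, _, truth = simulate_reference(spec)
        piles = run_library(spec, refset, truth, "mock")
        clusters = cluster_by_similarity(refset)
        stop = rt_stop_profile(piles, clusters, refset)
        mis = misincorporation_profile(piles, clusters, refset)
        assert stop[stop["canonical_label"] == "37"]["value"].iloc[0] == pytest.approx(0.4, abs=0.03)
        # misincorporation applies to molecules that were not truncated
        assert mis[mis["canonical_label"] == "37"]["value"].iloc[0] == pytest.approx(0.3, abs=0.03)


class TestCRetention:
    def test_full_conversion_gives_zero_retention(self):
        seq, labels = backbone_variant("GAA")
        ref = make_ref("a", seq, labels)
        converted = PositionStats(len(seq))
        for i, b in enumerate(seq):
            obs = "T" if b == "C" else b
            converted.base_counts[i, BASE_INDEX[obs]] = 100
        prof = c_retention_profile(
            {"s1": {"a": converted}}, ClusterSet([Cluster("c", ["a"])]), ReferenceSet([ref])
        )
        assert (prof["value"] == 0).all()
        single = retention_per_reference(converted, seq)
        assert np.nanmax(single) == 0.0

    def test_retention_closed_form_small(self):
        m, e = 0.5, 0.99
        spec = SimSpec(
            n_families=1, copies_per_family=(1, 1), n_reads=4000, seed=23,
            m5c_sites=[M5CSite("fam0", "49", m)], bs_conversion_efficiency=e,
        )
        refset, _, truth = simulate_reference(spec)
        piles = run_library(spec, refset, truth, "bs")
        clusters = cluster_by_similarity(refset)
        prof = c_retention_profile(piles, clusters, refset)
        got = prof[prof["canonical_label"] == "49"]["value"].iloc[0]
        assert got == pytest.approx(m + (1 - m) * (1 - e), abs=0.03)

    def test_cluster_denominator_inflation_hand_computed(self):
        """Member with a reference T at the label adds its Ts to the
        denominator: cluster retention 60/(60+40+50) = 0.4 while the
        C-member alone retains 60/100 = 0.6."""
        seq_c, labels = backbone_variant("GAA")
        i = seq_c.index("C", 40)
        seq_t = seq_c[:i] + "T" + seq_c[i + 1 :]
        refs = ReferenceSet([make_ref("mc", seq_c, labels), make_ref("mt", seq_t, labels)])
        st_c = PositionStats(len(seq_c))
        st_c.base_counts[i, BASE_INDEX["C"]] = 60
        st_c.base_counts[i, BASE_INDEX["T"]] = 40
        st_t = PositionStats(len(seq_t))
        st_t.base_counts[i, BASE_INDEX["T"]] = 50
        clusters = ClusterSet([Cluster("c", ["mc", "mt"])])
        prof = c_retention_profile({"s1": {"mc": st_c, "mt": st_t}}, clusters, refs)
        row = prof[prof["canonical_label"] == labels[i]].iloc[0]
        assert row["value"] == pytest.approx(60 / 150)
        single = retention_per_reference(st_c, seq_c)
        assert single[i] == pytest.approx(0.6)
        assert row["value"] < single[i]

    def test_non_ct_bases_excluded(self):
        seq, labels = backbone_variant("GAA")
        i = seq.index("C", 40)
        st = PositionStats(len(seq))
        st.base_counts[i, BASE_INDEX["C"]] = 30
        st.base_counts[i, BASE_INDEX["T"]] = 30
        st.base_counts[i, BASE_INDEX["G"]] = 40  # misincorporation, not conversion
        single = retention_per_reference(st, seq)
        assert single[i] == pytest.approx(0.5)


class TestClassification:
    def profile(self, rows, sample="s1"):
        return pd.DataFrame([
            {"cluster_id": c, "canonical_label": l, "sample": sample, "metric": "misincorporation",
             "value": v, "coverage": 1000, "mismatch_count": int(v * 1000),
             "ref_bases": rb, "top_mismatch_base": tb}
            for c, l, v, rb, tb in rows
        ])

    def test_sensitive_resistant_and_inosine(self):
        mock = self.profile([
            ("cl1", "58", 0.90, "A", "T"),
            ("cl1", "34", 0.85, "A", "G"),
            ("cl2", "20", 0.40, "T", "G"),
        ])
        dm = self.profile([
            ("cl1", "58", 0.02, "A", "T"),
            ("cl1", "34", 0.85, "A", "G"),
            ("cl2", "20", 0.38, "T", "G"),
        ])
        sites = classify_sites(mock, dm).set_index(["cluster_id", "canonical_label"])
        assert sites.loc[("cl1", "58"), "classification"] == "demethylation_sensitive"
        assert sites.loc[("cl1", "34"), "classification"] == "demethylation_resistant"
        assert bool(sites.loc[("cl1", "34"), "inosine_consistent"])
        assert sites.loc[("cl2", "20"), "classification"] == "demethylation_resistant"
        assert not bool(sites.loc[("cl2", "20"), "inosine_consistent"])

    def test_below_threshold_sites_not_reported(self):
        mock = self.profile([("cl1", "58", 0.10, "A", "T"), ("cl1", "9", 0.14, "G", "A")])
        dm = self.profile([("cl1", "58", 0.01, "A", "T"), ("cl1", "9", 0.01, "G", "A")])
        assert classify_sites(mock, dm).empty

    def test_profile_matrix_sprinzl_ordering(self):
        prof = self.profile([("cl1", "9", 0.2, "G", "A"), ("cl1", "e2", 0.3, "C", "T"),
                             ("cl1", "58", 0.4, "A", "T"), ("cl1", "20a", 0.1, "T", "G")])
        mat = profile_matrix(prof)
        assert list(mat.columns) == ["9", "20a", "e2", "58"]


class TestEstimatorConsistency:
    def test_estimates_within_binomial_bounds(self):
        """|estimate - p| <= 3 sqrt(p(1-p)/cov) for simulated sites across
        probabilities (one replicate per probability; the bound is 3 sigma)."""
        for p, seed in [(0.2, 41), (0.5, 42), (0.9, 43)]:
            spec = SimSpec(
                n_families=1, copies_per_family=(1, 1), n_reads=2500, seed=seed,
                mod_sites=[ModSite("fam0", "58", misincorporation_prob=p)],
            )
            refset, _, truth = simulate_reference(spec)
            piles = run_library(spec, refset, truth, "mock")
            clusters = cluster_by_similarity(refset)
            prof = misincorporation_profile(piles, clusters, refset)
            row = prof[prof["canonical_label"] == "58"].iloc[0]
            bound = 3 * np.sqrt(p * (1 - p) / row["coverage"])
            assert abs(row["value"] - p) <= bound + 1e-3
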