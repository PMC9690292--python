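import numpy as np
import pytest

from rgacnv.cnv_genes import (
    GeneCnvEvent,
    associate,
    counted_calls,
    event_counts_per_sample,
    gene_status,
    percentage,
    shared_matrix,
    sharing_histogram,
    size_location_summaries,
)
from rgacnv.intervals import GenomicInterval
from rgacnv.io import CnvCall, GeneRecord


def call(start, end, sample="s1", cnv_type="deletion", chrom="chrA01", cid=None):
    return CnvCall(
        call_id=cid or f"{sample}:{start}-{end}:{cnv_type}",
        sample=sample,
        interval=GenomicInterval(chrom, start, end),
        cnv_type=cnv_type,
        normalized_rd=0.5,
        e_values=(1e-9, 0, 1e-9, 0),
        q0=0.0,
    )


def gene(gene_id, start, end, chrom="chrA01", rank=0):
    return GeneRecord(gene_id, GenomicInterval(chrom, start, end), rank)


class TestAssociate:
    def test_half_coverage_boundary_is_inclusive(self):
        g = gene("g1", 0, 1000)
        assert len(associate([call(0, 500)], [g])) == 1
        assert associate([call(0, 499)], [g]) == []

    def test_single_call_rule_no_summing(self):
        """Two same-type calls each covering 30% of a gene do not combine."""
        g = gene("g1", 0, 1000)
        calls = [call(0, 300, cid="a"), call(400, 700, cid="b")]
        assert associate(calls, [g]) == []

    def test_duplicate_events_collapse_with_all_supporting_ids(self):
        g = gene("g1", 0, 1000)
        calls = [call(0, 1000, cid="a"), call(0, 1000, cid="b")]
        (ev,) = associate(calls, [g])
        assert ev.supporting_calls == ("a", "b")

    def test_type_and_sample_separate_events(self):
        g = gene("g1", 0, 1000)
        calls = [
            call(0, 1000, sample="s1", cnv_type="deletion"),
            call(0, 1000, sample="s1", cnv_type="duplication"),
            call(0, 1000, sample="s2", cnv_type="deletion"),
        ]
        events = associate(calls, [g])
        assert {(e.sample, e.cnv_type) for e in events} == {
            ("s1", "deletion"),
            ("s1", "duplication"),
            ("s2", "deletion"),
        }

    def test_raising_frac_never_adds_events(self):
        rng = np.random.default_rng(5)
        genes = [gene(f"g{i}", i * 2000, i * 2000 + 1000) for i in range(30)]
        calls = [
            call(int(s), int(s) + int(l), cid=str(i))
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 60000, 200), rng.integers(100, 3000, 200))
            )
        ]
        counts = [len(associate(calls, genes, frac=f)) for f in (0.1, 0.3, 0.5, 0.8, 1.0)]
        assert counts == sorted(counts, reverse=True)


class TestGeneStatus:
    def test_three_way_partition(self):
        events = [
            GeneCnvEvent("g1", "s1", "deletion", ("a",)),
            GeneCnvEvent("g1", "s2", "duplication", ("b",)),
            GeneCnvEvent("g2", "s1", "deletion", ("c",)),
            GeneCnvEvent("g2", "s3", "deletion", ("d",)),
            GeneCnvEvent("g3", "s1", "duplication", ("e",)),
        ]
        assert gene_status(events) == {
            "g1": "both",
            "g2": "deletion",
            "g3": "duplication",
        }

    def test_same_sample_both_types_is_both(self):
        events = [
            GeneCnvEvent("g1", "s1", "deletion", ("a",)),
            GeneCnvEvent("g1", "s1", "duplication", ("b",)),
        ]
        assert gene_status(events) == {"g1": "both"}


class TestEventTable:
    def test_percentage_arithmetic(self):
        assert percentage(48, 85) == 56.47
        assert percentage(37, 85) == 43.53
        assert percentage(0, 0) == 0.0

    def test_counts_and_totals(self):
        genes = [gene("g1", 0, 1000), gene("g2", 2000, 3000, rank=1)]
        calls = [
            call(0, 1000, sample="s1", cnv_type="deletion", cid="a"),
            call(2000, 3000, sample="s1", cnv_type="duplication", cid="b"),
            call(2000, 3000, sample="s2", cnv_type="deletion", cid="c"),
            # a call supporting no gene is not counted
            call(5000, 6000, sample="s2", cnv_type="deletion", cid="d"),
        ]
        events = associate(calls, genes)
        table = event_counts_per_sample(events, calls, samples=["s1", "s2"])
        s1 = table[table["sample"] == "s1"].iloc[0]
        assert (s1["deletion"], s1["duplication"], s1["total"]) == (1, 1, 2)
        assert s1["deletion_pct"] == 50.0
        total = table[table["sample"] == "Total"].iloc[0]
        assert total["total"] == 3
        assert total["deletion"] == table["deletion"].iloc[:-1].sum()
        # g2 is deleted in s2 and duplicated in s1 -> status both;
        # the supporting calls count in each sample's Both column
        assert s1["both"] == 1
        assert total["both"] == 2

    def test_call_spanning_two_genes_counts_once(self):
        genes = [gene("g1", 0, 1000), gene("g2", 1000, 2000, rank=1)]
        calls = [call(0, 2000, cid="a")]
        events = associate(calls, genes)
        assert len(events) == 2
        table = event_counts_per_sample(events, calls, samples=["s1"])
        assert table[table["sample"] == "s1"].iloc[0]["deletion"] == 1

    def test_sample_with_no_events_reports_zero(self):
        table = event_counts_per_sample([], [], samples=["s1"])
        row = table.iloc[0]
        assert row["total"] == 0 and row["deletion_pct"] == 0.0


class TestSharedMatrix:
    def test_same_type_rule_and_symmetry(self):
        events = [
            GeneCnvEvent("g1", "s1", "deletion", ("a",)),
            GeneCnvEvent("g1", "s2", "deletion", ("b",)),
            GeneCnvEvent("g2", "s1", "deletion", ("c",)),
            GeneCnvEvent("g2", "s2", "duplication", ("d",)),
        ]
        mat = shared_matrix(events, samples=["s1", "s2", "s3"])
        assert mat.loc["s1", "s2"] == 1  # g2 differs in type, not counted
        assert mat.loc["s2", "s1"] == 1
        assert mat.loc["s1", "s3"] == 0
        assert np.isnan(mat.loc["s1", "s1"])

    def test_symmetry_on_random_fixture(self):
        rng = np.random.default_rng(8)
        events = [
            GeneCnvEvent(
                f"g{rng.integers(0, 20)}",
                f"s{rng.integers(0, 5)}",
                str(rng.choice(["deletion", "duplication"])),
                (str(i),),
            )
            for i in range(200)
        ]
        mat = shared_matrix(events)
        arr = mat.to_numpy()
        assert np.allclose(arr, arr.T, equal_nan=True)


class TestSharingHistogram:
    def test_counts_and_percentages(self):
        events = [
            GeneCnvEvent("g1", "s1", "deletion", ("a",)),
            GeneCnvEvent("g2", "s1", "deletion", ("b",)),
            GeneCnvEvent("g2", "s2", "duplication", ("c",)),
        ]
        hist = sharing_histogram(events, n_samples=3)
        assert hist["rgas"].tolist() == [1, 1, 0]
        assert hist["rgas"].sum() == 2  # equals genes with ≥1 event
        assert hist["pct"].tolist() == [50.0, 50.0, 0.0]

    def test_all_private(self):
        events = [GeneCnvEvent(f"g{i}", "s1", "deletion", (str(i),)) for i in range(5)]
        hist = sharing_histogram(events, n_samples=2)
        assert hist["pct"].tolist() == [100.0, 0.0]


class TestSizeLocation:
    def test_bins_means_and_subgenomes(self):
        calls = [
            call(0, 2000, cid="a"),  # 2 kb -> [1000,5000)
            call(0, 999, cid="b", chrom="chrC01"),  # 999 bp -> [50,1000)
            call(0, 10000, cid="c", sample="s2", chrom="scaffold_1"),
        ]
        s = size_location_summaries(calls)
        bins = dict(zip(s["size_bins"]["size_bin"], s["size_bins"]["count"]))
        assert bins == {"50-1000": 1, "1000-5000": 1, "5000-10000": 0, ">=10000": 1}
        mean = s["mean_size_kb_per_sample"]
        assert mean[mean["sample"] == "s1"]["mean_size_kb"].iloc[0] == 1.50
        assert mean[mean["sample"] == "s2"]["mean_size_kb"].iloc[0] == 10.00
        # scaffold call is excluded from sub-genome tallies only
        sub = s["by_subgenome"].set_index("subgenome")
        assert sub.loc["A", "total"] == 1 and sub.loc["C", "total"] == 1
        assert s["pct_gt_1kb"] == percentage(2, 3)

    def test_boundary_sizes_are_closed_left(self):
        calls = [call(0, 1000, cid="a"), call(0, 5000, cid="b"), call(0, 50, cid="c")]
        s = size_location_summaries(calls)
        bins = dict(zip(s["size_bins"]["size_bin"], s["size_bins"]["count"]))
        assert bins == {"50-1000": 1, "1000-5000": 1, "5000-10000": 1, ">=10000": 0}


def test_counted_calls_are_supporting_calls_only():
    genes = [gene("g1", 0, 1000)]
    calls = [call(0, 1000, cid="a"), call(5000, 6000, cid="b")]
    events = associate(calls, genes)
    assert [c.call_id for c in counted_calls(events, calls)] == ["a"]
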