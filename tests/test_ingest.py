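"""Counting rules: length/identity filters, priority, ties, fractional siRNA."""

import numpy as np
import pytest

from tedynamics import (
    AlignmentRecord,
    ExemplarDB,
    ExemplarRecord,
    LibraryCounts,
    SiRNALibrary,
    ValidationError,
    count_genomic_hits,
    count_sirna_hits,
    paired_context,
    read_counts_table,
    write_counts_table,
)


@pytest.fixture
def tiny_db():
    return ExemplarDB(
        [
            ExemplarRecord("teA", "DNA", "DTA", 3000),
            ExemplarRecord("teB", "RNA", "RLC", 6000),
            ExemplarRecord("teC", "RNA", "RLG", 9000),
        ]
    )


def aln(read, target_set="UTE", target="teA", length=60, score=50.0, identity=0.95, mm=0):
    return AlignmentRecord(
        read_id=read,
        target_set=target_set,
        target_id=target,
        alignment_length=length,
        score=score,
        identity=identity,
        mismatches=mm,
    )


class TestGenomicCounting:
    def test_short_alignments_are_excluded(self, tiny_db):
        counts, stats = count_genomic_hits([aln("r1", length=25)], tiny_db)
        assert counts.hits["teA"] == 0
        assert counts.total_ute_hits == 0
        assert stats.dropped_short == 1

    def test_boundary_31bp_counts_30bp_does_not(self, tiny_db):
        counts, _ = count_genomic_hits(
            [aln("r1", length=31), aln("r2", length=30)], tiny_db
        )
        assert counts.hits["teA"] == 1

    def test_equal_best_across_exemplars_discards_read(self, tiny_db):
        counts, stats = count_genomic_hits(
            [aln("r1", target="teA"), aln("r1", target="teB")], tiny_db
        )
        assert counts.total_ute_hits == 0
        assert stats.discarded_ties == 1

    def test_multiple_positions_in_one_exemplar_count_once(self, tiny_db):
        counts, _ = count_genomic_hits(
            [aln("r1", target="teA"), aln("r1", target="teA", length=80)], tiny_db
        )
        assert counts.hits["teA"] == 1

    def test_knob_priority_over_ute(self, tiny_db):
        counts, _ = count_genomic_hits(
            [aln("r1", target="teA"), aln("r1", target_set="KnobC", target="knob1")],
            tiny_db,
        )
        assert counts.knob_hits == 1
        assert counts.hits["teA"] == 0

    def test_ute_priority_over_fgs(self, tiny_db):
        counts, _ = count_genomic_hits(
            [aln("r1", target="teA"), aln("r1", target_set="FGS", target="gene1")],
            tiny_db,
        )
        assert counts.hits["teA"] == 1
        assert counts.fgs_hits == 0

    def test_identity_thresholds_per_database(self, tiny_db):
        # 0.85 passes the 0.80 TE threshold but fails the 0.90 gene threshold
        counts, _ = count_genomic_hits(
            [
                aln("r1", target="teA", identity=0.85),
                aln("r2", target_set="FGS", target="g", identity=0.85),
                aln("r3", target_set="FGS", target="g", identity=0.95),
            ],
            tiny_db,
        )
        assert counts.hits["teA"] == 1
        assert counts.fgs_hits == 1

    def test_unknown_exemplar_raises(self, tiny_db):
        with pytest.raises(ValidationError):
            count_genomic_hits([aln("r1", target="nope")], tiny_db)

    def test_classification_invariant_to_record_order(self, tiny_db):
        records = [
            aln("r1", target="teA", score=50),
            aln("r1", target="teB", score=40),
            aln("r1", target_set="FGS", target="g"),
            aln("r2", target="teC"),
        ]
        fwd, _ = count_genomic_hits(records, tiny_db)
        rev, _ = count_genomic_hits(records[::-1], tiny_db)
        assert fwd.hits == rev.hits
        assert fwd.fgs_hits == rev.fgs_hits


class TestSiRNACounting:
    def test_multi_target_read_split_fractionally(self, tiny_db):
        records = [
            aln(f"r1", target=t, length=24)
            for t in ("teA", "teB", "teC")
        ] + [aln("r1", target="teA", length=24)]  # duplicate target counted once
        lib = count_sirna_hits(records, tiny_db, 24)
        assert lib.counts["teA"] == pytest.approx(1 / 3)
        assert lib.total_sirna_hits == pytest.approx(1.0)

    def test_mismatched_read_excluded(self, tiny_db):
        lib = count_sirna_hits([aln("r1", mm=1, length=22)], tiny_db, 22)
        assert lib.total_sirna_hits == 0

    def test_unique_reads_conserve_total(self, tiny_db):
        records = [aln(f"r{i}", target="teA", length=22) for i in range(10)]
        lib = count_sirna_hits(records, tiny_db, 22)
        assert lib.counts["teA"] == 10
        assert lib.total_sirna_hits == 10

    def test_bad_size_class_rejected(self, tiny_db):
        with pytest.raises(ValidationError):
            count_sirna_hits([], tiny_db, 23)


class TestPairedContext:
    def test_four_way_split(self, tiny_db):
        pairs = [
            (("UTE", "teA"), ("UTE", "teB")),
            (("UTE", "teA"), ("FGS", None)),
            (("UTE", "teA"), ("KnobC", None)),
            (("UTE", "teA"), ("unassigned", None)),
        ]
        ctx = paired_context(pairs, tiny_db)
        row = ctx.fractions("teA")
        assert row["fraction_te_other"] == 0.25
        assert row["fraction_fgs"] == 0.25
        assert row["fraction_knob"] == 0.25
        assert row["fraction_unassigned"] == 0.25
        assert row["denominator"] == 4

    def test_fractions_sum_to_one_when_denominator_positive(self, tiny_db):
        pairs = [
            (("UTE", "teB"), ("FGS", None)),
            (("UTE", "teB"), ("UTE", "teC")),
            (("UTE", "teC"), ("KnobC", None)),
        ]
        ctx = paired_context(pairs, tiny_db)
        sums = ctx.table.loc[ctx.table["denominator"] > 0,
                             [c for c in ctx.table.columns if c.startswith("fraction")]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_zero_denominator_reports_missing_not_zero(self, tiny_db):
        ctx = paired_context([], tiny_db)
        assert np.isnan(ctx.fractions("teA")["fraction_fgs"])

    def test_same_exemplar_pair_excluded_entirely(self, tiny_db):
        ctx = paired_context([(("UTE", "teA"), ("UTE", "teA"))], tiny_db)
        assert ctx.fractions("teA")["denominator"] == 0


class TestCountsTableRoundTrip:
    def test_genomic_round_trip(self, tmp_path):
        obj = LibraryCounts(
            accession_id="B73",
            hits={"teA": 10.0, "teB": 0.0},
            fgs_hits=55.0,
            knob_hits=7.0,
            mean_read_length=101.5,
            n_reads_total=100.0,
        )
        path = tmp_path / "c.tsv"
        write_counts_table(obj, path)
        back = read_counts_table(path)
        assert back == obj

    def test_sirna_fractions_preserved(self, tmp_path):
        obj = SiRNALibrary("PT", 22, {"teA": 1 / 3, "teB": 2 / 7})
        path = tmp_path / "s.tsv"
        write_counts_table(obj, path)
        back = read_counts_table(path)
        assert back.counts["teA"] == pytest.approx(1 / 3, abs=1e-12)
        assert back.counts["teB"] == pytest.approx(2 / 7, abs=1e-12)

    def test_duplicate_exemplar_row_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "#type=sirna\n#accession=X\n#size_class=22\n"
            "exemplar_id\thits\nteA\t1.0\nteA\t2.0\n"
        )
        with pytest.raises(ValidationError, match="teA"):
            read_counts_table(path)

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text(
            "#type=sirna\n#accession=X\n#size_class=22\n"
            "exemplar_id\thits\nteA\t-1.0\n"
        )
        with pytest.raises(ValidationError):
            read_counts_table(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#type=sirna\n#accession=X\n#size_class=22\nwrong\tcols\n")
        with pytest.raises(ValidationError):
            read_counts_table(path)


def test_sam_ingestion_round_trip(tmp_path, tiny_db):
    """A minimal SAM is parsed into records that count correctly."""
    sam = tmp_path / "mini.sam"
    sam.write_text(
        "@HD\tVN:1.6\n"
        "@SQ\tSN:teA\tLN:3000\n"
        "@SQ\tSN:teB\tLN:6000\n"
        "r1\t0\tteA\t100\t60\t60M\t*\t0\t0\t" + "A" * 60 + "\t*\tNM:i:2\tAS:i:55\n"
        "r2\t0\tteB\t200\t60\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\tNM:i:0\tAS:i:20\n"
    )
    from tedynamics import read_sam_alignments

    records = read_sam_alignments(sam, "UTE")
    assert len(records) == 2
    r1 = next(r for r in records if r.read_id == "r1")
    assert r1.alignment_length == 60
    assert r1.identity == pytest.approx(58 / 60)
    assert r1.score == 55.0
    counts, _ = count_genomic_hits(records, tiny_db)
    assert counts.hits["teA"] == 1  # r2 fails the >30 bp rule
    assert counts.hits["teB"] == 0
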