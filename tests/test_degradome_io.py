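import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pare_decay.degradome_io import (
    SignatureMatrix,
    TagPlacement,
    TranscriptAnnotation,
    filter_blocklist,
    filter_low_frequency,
    read_annotation,
    read_counts,
    read_signatures,
    read_tag_placements,
    read_transcripts,
    summarize_tags,
    write_counts,
    write_signatures,
)


class TestReadTranscripts:
    def test_two_records_with_rna_normalization(self, tmp_path):
        p = tmp_path / "t.fasta"
        p.write_text(">t1\nacgt\n>t2\nGGTTAACC\n")
        seqs = read_transcripts(p)
        assert seqs == {"t1": "ACGU", "t2": "GGUUAACC"}

    def test_duplicate_id_names_offender(self, tmp_path):
        p = tmp_path / "t.fasta"
        p.write_text(">t1\nACGU\n>t1\nACGU\n")
        with pytest.raises(ValueError, match="t1"):
            read_transcripts(p)

    def test_empty_record_rejected(self, tmp_path):
        p = tmp_path / "t.fasta"
        p.write_text(">t1\n\n>t2\nACGU\n")
        with pytest.raises(ValueError, match="t1"):
            read_transcripts(p)


class TestAnnotation:
    def test_utr_lengths_from_tsv_row(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(
            "transcript_id\tlength\tcds_start\tcds_end\tn_introns\nt1\t1000\t201\t700\t3\n"
        )
        ann = read_annotation(p)["t1"]
        assert (ann.utr5_length, ann.utr3_length, ann.n_introns) == (200, 300, 3)

    def test_cds_outside_length_rejected(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(
            "transcript_id\tlength\tcds_start\tcds_end\tn_introns\nt1\t500\t201\t700\t3\n"
        )
        with pytest.raises(ValueError):
            read_annotation(p)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("transcript_id\tlength\tcds_start\tn_introns\nt1\t500\t201\t3\n")
        with pytest.raises(ValueError, match="cds_end"):
            read_annotation(p)

    def test_gff3_matches_equivalent_tsv(self, tmp_path):
        # two-exon mRNA on +, one on -; CDS projected to transcript space
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\t.\tgene\t1\t1000\t.\t+\t.\tID=g1\n"
            "chr1\t.\tmRNA\t101\t600\t.\t+\t.\tID=m1;Parent=g1\n"
            "chr1\t.\texon\t101\t300\t.\t+\t.\tID=m1.e1;Parent=m1\n"
            "chr1\t.\texon\t401\t600\t.\t+\t.\tID=m1.e2;Parent=m1\n"
            "chr1\t.\tCDS\t151\t300\t.\t+\t0\tID=m1.c1;Parent=m1\n"
            "chr1\t.\tCDS\t401\t500\t.\t+\t0\tID=m1.c2;Parent=m1\n"
            "chr1\t.\tgene\t2000\t3000\t.\t-\t.\tID=g2\n"
            "chr1\t.\tmRNA\t2001\t2400\t.\t-\t.\tID=m2;Parent=g2\n"
            "chr1\t.\texon\t2001\t2400\t.\t-\t.\tID=m2.e1;Parent=m2\n"
            "chr1\t.\tCDS\t2101\t2300\t.\t-\t0\tID=m2.c1;Parent=m2\n"
        )
        tsv = tmp_path / "a.tsv"
        # m1: length 200+200=400; cds 151 -> offset 51; cds end 500 -> 200+100=300
        # m2 (minus): length 400; cds_start = 2400-2300+1=101; cds_end = 2400-2101+1=300
        tsv.write_text(
            "transcript_id\tlength\tcds_start\tcds_end\tn_introns\n"
            "m1\t400\t51\t300\t1\nm2\t400\t101\t300\t0\n"
        )
        from_gff = read_annotation(gff)
        from_tsv = read_annotation(tsv)
        for tid in ("m1", "m2"):
            g, t = from_gff[tid], from_tsv[tid]
            assert (g.length, g.cds_start, g.cds_end, g.n_introns) == (
                t.length, t.cds_start, t.cds_end, t.n_introns,
            )

    @pytest.mark.parametrize(
        "pos,region", [(1, "utr5"), (200, "utr5"), (201, "cds"), (700, "cds"), (701, "utr3")]
    )
    def test_region_boundaries_inclusive_for_cds(self, pos, region):
        ann = TranscriptAnnotation("t", 1000, 201, 700, 0)
        assert ann.region_of(pos) == region


class TestSummarizeTags:
    def test_multimapped_tag_divided_equally(self):
        tags = [TagPlacement("x", (("t1", 10), ("t2", 20)), 10)]
        m = summarize_tags(tags, "DW")
        assert m.counts["t1"][10] == 5.0 and m.counts["t2"][20] == 5.0

    def test_unique_tag_keeps_full_count(self):
        m = summarize_tags([TagPlacement("x", (("t1", 7),), 3)], "DW")
        assert m.counts["t1"][7] == 3.0

    def test_unknown_transcript_rejected(self):
        tags = [TagPlacement("x", (("t9", 1),), 1)]
        with pytest.raises(ValueError, match="t9"):
            summarize_tags(tags, "DW", known_transcripts=["t1"])

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=1000),  # read count
                st.integers(min_value=1, max_value=5),  # n placements
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_read_mass_conserved_for_any_multiplicity(self, specs):
        tags = [
            TagPlacement(f"tag{i}", tuple((f"t{j}", j + 1) for j in range(k)), float(c))
            for i, (c, k) in enumerate(specs)
        ]
        m = summarize_tags(tags, "DW")
        assert m.total_mapped == pytest.approx(sum(c for c, _ in specs), rel=1e-12)


class TestFilters:
    def _matrix(self, entries):
        m = SignatureMatrix("DW")
        for tid, pos, c in entries:
            m.add(tid, pos, c)
        return m

    def test_default_drops_five_keeps_six(self):
        m = self._matrix([("t1", 1, 5), ("t1", 2, 6)])
        out = filter_low_frequency(m)
        assert out.counts == {"t1": {2: 6.0}}

    def test_min_count_zero_keeps_positive_entries(self):
        m = self._matrix([("t1", 1, 0.5), ("t1", 2, 3)])
        out = filter_low_frequency(m, 0)
        assert out.counts == {"t1": {1: 0.5, 2: 3.0}}

    def test_all_low_gives_empty_matrix(self):
        m = self._matrix([("t1", 1, 5), ("t2", 2, 1)])
        out = filter_low_frequency(m)
        assert out.counts == {} and out.total_mapped == 0.0

    def test_negative_min_count_rejected(self):
        with pytest.raises(ValueError):
            filter_low_frequency(SignatureMatrix("DW"), -1)

    def test_blocklist_cases(self):
        m = self._matrix([("t1", 1, 10), ("t2", 1, 10)])
        assert filter_blocklist(m, []).counts == m.counts
        assert filter_blocklist(m, ["t1", "t2"]).counts == {}
        assert set(filter_blocklist(m, ["t2"]).counts) == {"t1"}

    def test_filters_idempotent_and_commute(self, rng):
        m = self._matrix(
            [(f"t{i}", p, float(c)) for i in range(20)
             for p, c in zip(rng.integers(1, 100, 5), rng.integers(0, 20, 5))]
        )
        block = {"t3", "t7", "t11"}
        a = filter_blocklist(filter_low_frequency(m), block)
        b = filter_low_frequency(filter_blocklist(m, block))
        assert a.counts == b.counts
        assert filter_low_frequency(a).counts == a.counts


class TestTables:
    def test_signature_roundtrip_exact(self, tmp_path, rng):
        m = SignatureMatrix("DW")
        for i in range(50):
            m.add(f"t{i}", int(rng.integers(1, 2000)), float(rng.random() * 100))
        write_signatures([m], tmp_path / "s.tsv")
        back = read_signatures(tmp_path / "s.tsv")["DW"]
        assert back.counts == m.counts

    def test_counts_roundtrip_exact(self, tmp_path, rng):
        counts = {"RW": {f"t{i}": float(rng.random() * 50) for i in range(30)}}
        write_counts(counts, tmp_path / "c.tsv")
        assert read_counts(tmp_path / "c.tsv") == counts

    def test_tag_placements_inconsistent_read_count_rejected(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text(
            "tag_id\ttranscript_id\tposition\tread_count\nx\tt1\t1\t5\nx\tt2\t3\t6\n"
        )
        with pytest.raises(ValueError, match="x"):
            read_tag_placements(p)

    def test_tag_placements_grouped(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text(
            "tag_id\ttranscript_id\tposition\tread_count\n"
            "x\tt1\t1\t6\nx\tt2\t3\t6\ny\tt1\t9\t2\n"
        )
        tags = {t.tag_id: t for t in read_tag_placements(p)}
        assert len(tags["x"].placements) == 2 and tags["x"].read_count == 6.0
        assert tags["y"].placements == (("t1", 9),)
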