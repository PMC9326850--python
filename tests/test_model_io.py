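"""Domain types and format I/O: FASTA, SAM, PAF, AGP, link TSV."""

import numpy as np
import pandas as pd
import pytest

from ltscaf import model_io
from ltscaf.model_io import (Contig, Gap, Library, Link, Placement,
                             SuperContig, read_agp, read_alignments,
                             read_contigs, write_scaffolds)

# dijr oracle for inward (PE) pairs: +1 iff the two reads' strands are
# consistent with both contigs forward, i.e. exactly one read reversed
STRAND_CASES = [
    (False, True, +1),   # forward / reverse -> consistent
    (True, False, +1),
    (False, False, -1),
    (True, True, -1),
]


def sam_text(pairs):
    """Minimal SAM with contigs A (1 kb) and B (2 kb)."""
    lines = ["@HD\tVN:1.6\t{}".format("SO:unsorted"),
             "@SQ\tSN:A\tLN:1000", "@SQ\tSN:B\tLN:2000"]
    for qname, recs in pairs:
        for (ref, pos, reverse, read1, mate_ref, mate_pos, mate_rev) in recs:
            flag = 1 | (64 if read1 else 128)
            if reverse:
                flag |= 16
            if mate_rev:
                flag |= 32
            lines.append("\t".join(map(str, [
                qname, flag, ref, pos + 1, 60, "50M",
                "=" if mate_ref == ref else mate_ref, mate_pos + 1, 0,
                "A" * 50, "*"])))
    return "\n".join(lines) + "\n"


@pytest.fixture
def libraries():
    return {"pe1": Library("pe1", "PE", 500, 50, read_length=50),
            "tg1": Library("tg1", "TGS")}


@pytest.fixture
def contigs():
    return {"A": Contig("A", 1000), "B": Contig("B", 2000)}


class TestReadContigs:
    def test_lengths_and_order(self, write_fasta):
        path = write_fasta([("one extra words", "ACGTACGTAC"),
                            ("two", "A" * 20)])
        contigs = read_contigs(path)
        assert [c.length for c in contigs.values()] == [10, 20]
        assert list(contigs) == ["one", "two"]

    def test_lowercase_uppercased(self, write_fasta):
        contigs = read_contigs(write_fasta([("x", "acgtn")]))
        assert contigs["x"].sequence == "ACGTN"
        assert contigs["x"].length == 5

    def test_duplicate_id_is_error(self, write_fasta):
        path = write_fasta([("dup", "ACGT"), ("dup", "TTTT")])
        with pytest.raises(ValueError, match="dup"):
            read_contigs(path)

    def test_empty_file_is_error(self, write_fasta):
        with pytest.raises(ValueError):
            read_contigs(write_fasta([]))


class TestReadSamPaired:
    @pytest.mark.parametrize("rev1,rev2,expected_d", STRAND_CASES)
    def test_pair_orientation_convention(self, tmp_path, libraries, contigs,
                                         rev1, rev2, expected_d):
        pairs = [("r1", [("A", 100, rev1, True, "B", 500, rev2),
                         ("B", 500, rev2, False, "A", 100, rev1)])]
        path = tmp_path / "p.sam"
        path.write_text(sam_text(pairs))
        data = read_alignments(path, libraries, contigs, library_id="pe1")
        assert len(data.paired_links) == 1
        assert data.paired_links["d"].iloc[0] == expected_d

    def test_same_contig_pair_routed_to_inserts(self, tmp_path, libraries,
                                                contigs):
        pairs = [("r1", [("A", 100, False, True, "A", 550, True),
                         ("A", 550, True, False, "A", 100, False)])]
        path = tmp_path / "p.sam"
        path.write_text(sam_text(pairs))
        data = read_alignments(path, libraries, contigs, library_id="pe1")
        assert len(data.paired_links) == 0
        assert len(data.insert_obs) == 1
        # outer span: from 100 to 550+50
        assert data.insert_obs["insert"].iloc[0] == 500

    def test_outer_end_coordinates(self, tmp_path, libraries, contigs):
        # forward read outer end = start (0-based); reverse = end
        pairs = [("r1", [("A", 100, False, True, "B", 500, True),
                         ("B", 500, True, False, "A", 100, False)])]
        path = tmp_path / "p.sam"
        path.write_text(sam_text(pairs))
        link = read_alignments(path, libraries, contigs,
                               library_id="pe1").paired_links.iloc[0]
        assert (link["i"], link["j"]) == ("A", "B")
        assert link["s_i"] == 100
        assert link["s_j"] == 550

    def test_unknown_library_is_error(self, tmp_path, libraries, contigs):
        path = tmp_path / "p.sam"
        path.write_text(sam_text([]))
        with pytest.raises(ValueError, match="library"):
            read_alignments(path, libraries, contigs, library_id="nope")

    def test_coverage_track_accumulates(self, tmp_path, libraries, contigs):
        pairs = [("r1", [("A", 100, False, True, "B", 500, True),
                         ("B", 500, True, False, "A", 100, False)])]
        path = tmp_path / "p.sam"
        path.write_text(sam_text(pairs))
        cov = read_alignments(path, libraries, contigs,
                              library_id="pe1").coverage
        assert cov["A"].sum() > 0 and cov["B"].sum() > 0


class TestReadPafTgs:
    def test_tgs_link_fields(self, tmp_path, libraries, contigs):
        lines = [
            "\t".join(map(str, ["read1", 5000, 1000, 1900, "+", "A", 1000,
                                200, 1100, 800, 900, 60])),
            "\t".join(map(str, ["read1", 5000, 4000, 4800, "+", "B", 2000,
                                300, 1100, 700, 800, 60])),
        ]
        path = tmp_path / "t.paf"
        path.write_text("\n".join(lines) + "\n")
        data = read_alignments(path, libraries, contigs, library_id="tg1")
        assert len(data.tgs_links) == 1
        row = data.tgs_links.iloc[0]
        assert (row["qs_i"], row["cs_i"]) == (1000, 200)
        assert (row["qs_j"], row["cs_j"]) == (4000, 300)
        assert row["d"] == 1

    def test_short_alignment_excluded(self, tmp_path, libraries, contigs):
        lines = [
            "\t".join(map(str, ["read1", 5000, 1000, 1900, "+", "A", 1000,
                                200, 1100, 800, 900, 60])),
            "\t".join(map(str, ["read1", 5000, 4000, 4300, "+", "B", 2000,
                                300, 600, 250, 300, 60])),
        ]
        path = tmp_path / "t.paf"
        path.write_text("\n".join(lines) + "\n")
        data = read_alignments(path, libraries, contigs, library_id="tg1",
                               min_tgs_aln=500)
        assert len(data.tgs_links) == 0


class TestLinkRecord:
    def test_distinct_contigs_required(self):
        with pytest.raises(ValueError):
            Link("r", "A", "A", 1, "pe1", s_i=1, s_j=2)

    def test_exactly_one_coordinate_set(self):
        with pytest.raises(ValueError):
            Link("r", "A", "B", 1, "pe1")
        with pytest.raises(ValueError):
            Link("r", "A", "B", 1, "pe1", s_i=1, qs_i=2)


class TestLinksTsvRoundTrip:
    def test_round_trip(self, tmp_path):
        paired = pd.DataFrame([("r1", "A", "B", 1, 10, 20, 1, -1, "pe1")],
                              columns=model_io.PAIRED_COLUMNS)
        tgs = pd.DataFrame([("t1", "A", "B", 1, 100, 400, 5, 7, 50, 60, 1, 1,
                             5000, "tg1")], columns=model_io.TGS_COLUMNS)
        path = tmp_path / "links.tsv"
        model_io.write_links_tsv(path, paired, tgs)
        p2, t2, _ = model_io.read_links_tsv(path)
        pd.testing.assert_frame_equal(p2, paired)
        pd.testing.assert_frame_equal(t2, tgs)


class TestWriteScaffolds:
    def _sc(self):
        return SuperContig(
            id="s1",
            placements=[Placement("A", 1, 0, 100),
                        Placement("B", -1, 150, 100)],
            gaps=[Gap(size=50, ci_low=40, ci_high=60, n_clusters=3)])

    def _contigs(self):
        rng = np.random.default_rng(5)
        return {c: Contig(c, 100, "".join(rng.choice(list("ACGT"), 100)))
                for c in "AB"}

    def test_fasta_and_agp(self, tmp_path):
        contigs = self._contigs()
        write_scaffolds([self._sc()], contigs, tmp_path / "s.fasta",
                        tmp_path / "s.agp", tmp_path / "g.tsv")
        from Bio import SeqIO
        rec = next(SeqIO.parse(str(tmp_path / "s.fasta"), "fasta"))
        assert len(rec.seq) == 250
        assert str(rec.seq[100:150]) == "N" * 50
        rows = [l.split("\t") for l in
                (tmp_path / "s.agp").read_text().splitlines()
                if not l.startswith("#")]
        assert [r[4] for r in rows] == ["W", "N", "W"]
        # AGP is 1-based inclusive
        assert rows[0][1:3] == ["1", "100"]
        assert rows[1][1:3] == ["101", "150"]
        gap_report = (tmp_path / "g.tsv").read_text().splitlines()
        assert gap_report[1].split("\t")[:4] == ["s1", "A", "B", "50"]

    def test_agp_round_trip(self, tmp_path):
        contigs = self._contigs()
        sc = self._sc()
        write_scaffolds([sc], contigs, tmp_path / "s.fasta",
                        tmp_path / "s.agp", tmp_path / "g.tsv")
        back = read_agp(tmp_path / "s.agp", contigs)
        assert len(back) == 1
        got = back[0]
        assert [(p.contig, p.orientation, p.start, p.length)
                for p in got.placements] == \
            [(p.contig, p.orientation, p.start, p.length)
             for p in sc.placements]
        assert [int(g.size) for g in got.gaps] == [50]

    def test_empty_scaffold_set(self, tmp_path):
        write_scaffolds([], {}, tmp_path / "s.fasta", tmp_path / "s.agp",
                        tmp_path / "g.tsv")
        assert (tmp_path / "s.fasta").exists()
        assert "scaffold" in (tmp_path / "g.tsv").read_text()

    def test_malformed_agp_names_line(self, tmp_path):
        (tmp_path / "bad.agp").write_text("s1\t1\t100\n")
        with pytest.raises(ValueError, match="bad.agp:1"):
            read_agp(tmp_path / "bad.agp")
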