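from pathlib import Path

import pytest

from caslink.annotation_io import (
    AnnotationParseError,
    GeneRecord,
    Replicon,
    filter_incomplete,
    read_genbank,
    read_ptt,
    write_genbank,
    write_ptt,
)

GBK_MINIMAL = """LOCUS       TESTCHR1                 900 bp    DNA     linear   BCT 01-JAN-2000
DEFINITION  GTEST replicon TESTCHR1.
ACCESSION   TESTCHR1
FEATURES             Location/Qualifiers
     CDS             10..108
                     /locus_tag="t_0001"
                     /protein_id="PX1"
                     /product="alpha"
                     /translation="MKVLATTLGACDEFGHIKLMNPQRSTVWYAAA"
     CDS             complement(200..298)
                     /locus_tag="t_0002"
                     /protein_id="PX2"
                     /product="beta"
                     /translation="MACDEFGHIKLMNPQRSTVWYAAAAKVLATT"
     CDS             400..498
                     /locus_tag="t_0003"
                     /pseudo
                     /product="gamma fragment"
ORIGIN
"""


@pytest.fixture()
def gbk_file(tmp_path):
    path = tmp_path / "test.gbk"
    path.write_text(GBK_MINIMAL + _origin_block(900) + "//\n")
    return path


def _origin_block(n):
    lines = []
    seq = "n" * n
    for i in range(0, n, 60):
        chunk = seq[i : i + 60]
        parts = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {parts}")
    return "\n".join(lines) + "\n"


class TestReadGenbank:
    def test_cds_features_mapped_in_coordinate_order(self, gbk_file):
        (rep,) = read_genbank(gbk_file)
        assert rep.genome_id == "GTEST"
        assert rep.replicon_id == "TESTCHR1"
        assert len(rep) == 3
        assert [g.locus_tag for g in rep.genes] == ["t_0001", "t_0002", "t_0003"]
        g = rep.genes[0]
        assert (g.start, g.end, g.strand) == (10, 108, "+")
        assert g.protein_seq.startswith("MKVLA")
        assert rep.genes[1].strand == "-"

    def test_pseudo_qualifier_maps_to_flag(self, gbk_file):
        (rep,) = read_genbank(gbk_file)
        pseudo = rep.genes[2]
        assert pseudo.is_pseudo
        assert pseudo.protein_seq is None

    def test_explicit_genome_id_wins(self, gbk_file):
        (rep,) = read_genbank(gbk_file, genome_id="OVERRIDE")
        assert rep.genome_id == "OVERRIDE"

    def test_malformed_file_raises_parse_error(self, tmp_path):
        bad = tmp_path / "bad.gbk"
        bad.write_text("this is not genbank\n")
        with pytest.raises(AnnotationParseError):
            read_genbank(bad)


class TestRoundTrips:
    def test_genbank_roundtrip_identical(self, small_collection):
        cdir, _ = small_collection
        for gbk in sorted(Path(cdir, "genomes").glob("*.gbk"))[:2]:
            (rep,) = read_genbank(gbk, genome_id=gbk.stem)
            out = gbk.parent / (gbk.stem + ".rt.gbk")
            write_genbank([rep], out)
            (rep2,) = read_genbank(out, genome_id=gbk.stem)
            assert rep == rep2
            out.unlink()

    def test_ptt_roundtrip_identical(self, small_collection, tmp_path):
        cdir, _ = small_collection
        ptt = sorted(Path(cdir, "genomes").glob("*.ptt"))[0]
        rep = read_ptt(ptt, ptt.with_suffix(".faa"), genome_id=ptt.stem)
        write_ptt(rep, tmp_path / "x.ptt", tmp_path / "x.faa")
        rep2 = read_ptt(tmp_path / "x.ptt", tmp_path / "x.faa", genome_id=ptt.stem)
        assert rep == rep2

    def test_cross_format_equivalence(self, small_collection):
        cdir, _ = small_collection
        for gbk in sorted(Path(cdir, "genomes").glob("*.gbk")):
            via_gbk = read_genbank(gbk, genome_id=gbk.stem)[0]
            via_ptt = read_ptt(
                gbk.with_suffix(".ptt"), gbk.with_suffix(".faa"), genome_id=gbk.stem
            )
            assert via_gbk == via_ptt

    def test_parsed_table_matches_generator_truth(self, small_collection):
        cdir, gt = small_collection
        genes = gt.genes
        for gbk in sorted(Path(cdir, "genomes").glob("*.gbk")):
            (rep,) = read_genbank(gbk, genome_id=gbk.stem)
            sub = genes[genes.genome_id == gbk.stem].reset_index(drop=True)
            assert len(rep) == len(sub)
            for g, row in zip(rep.genes, sub.itertuples()):
                assert g.protein_id == row.protein_id
                assert (g.start, g.end, g.strand) == (row.start, row.end, row.strand)
                assert g.index == row.index
                assert g.is_partial == bool(row.is_partial)


class TestReadPtt:
    def test_column_mapping(self, tmp_path):
        ptt = tmp_path / "g.ptt"
        faa = tmp_path / "g.faa"
        ptt.write_text(
            "Gx chr1 - 5000 bp\n1 proteins\n"
            "Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct\n"
            "190..255\t+\t21\t16127995\tthrL\tb0001\t-\t-\tthr operon leader\n"
        )
        faa.write_text(">16127995 b0001\nMKRISTTITTTITITTGNGAG\n")
        rep = read_ptt(ptt, faa)
        g = rep.genes[0]
        assert (g.start, g.end, g.strand) == (190, 255, "+")
        assert g.protein_id == "16127995"
        assert g.protein_seq == "MKRISTTITTTITITTGNGAG"
        assert rep.length_bp == 5000

    def test_missing_fasta_entry_warns_and_keeps_row(self, tmp_path, caplog):
        ptt = tmp_path / "g.ptt"
        faa = tmp_path / "g.faa"
        ptt.write_text(
            "Gx chr1 - 5000 bp\n1 proteins\n"
            "Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct\n"
            "10..99\t+\t29\tP1\t-\tl1\t-\t-\tthing\n"
        )
        faa.write_text("")
        with caplog.at_level("WARNING"):
            rep = read_ptt(ptt, faa)
        assert rep.genes[0].protein_seq is None
        assert any("absent from the FASTA" in m or "absent" in m for m in caplog.messages)

    def test_duplicate_pid_rejected(self, tmp_path):
        ptt = tmp_path / "g.ptt"
        faa = tmp_path / "g.faa"
        ptt.write_text(
            "Gx chr1 - 5000 bp\n2 proteins\n"
            "Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct\n"
            "10..99\t+\t29\tP1\t-\tl1\t-\t-\tx\n"
            "200..299\t+\t32\tP1\t-\tl2\t-\t-\ty\n"
        )
        faa.write_text(">P1 l1\nMKV\n")
        with pytest.raises(AnnotationParseError, match="duplicate PID"):
            read_ptt(ptt, faa)

    def test_missing_header_rejected(self, tmp_path):
        ptt = tmp_path / "g.ptt"
        ptt.write_text("only one line\n")
        (tmp_path / "g.faa").write_text("")
        with pytest.raises(AnnotationParseError):
            read_ptt(ptt, tmp_path / "g.faa")


class TestReplicon:
    def test_sorted_invariant_enforced(self):
        g1 = GeneRecord("a", "p1", 100, 199, "+", "x", "MKV", index=0)
        g2 = GeneRecord("b", "p2", 10, 99, "+", "y", "MKV", index=1)
        with pytest.raises(ValueError, match="not sorted"):
            Replicon("g", "r", 500, "linear", (g1, g2))

    def test_coordinates_must_fit_linear_replicon(self):
        g = GeneRecord("a", "p1", 100, 999, "+", "x", "MKV", index=0)
        with pytest.raises(ValueError):
            Replicon("g", "r", 500, "linear", (g,))

    def test_origin_spanning_gene_needs_flag(self):
        with pytest.raises(ValueError, match="start"):
            GeneRecord("a", "p1", 400, 20, "+", "x", "MKV")
        g = GeneRecord("a", "p1", 400, 20, "+", "x", "MKV", wraps_origin=True)
        assert g.wraps_origin


class TestFilterIncomplete:
    def _gene(self, i, **kw):
        defaults = dict(
            locus_tag=f"l{i}",
            protein_id=f"p{i}",
            start=i * 100,
            end=i * 100 + 50,
            strand="+",
            product="x",
            protein_seq="MKVLA",
            index=i,
        )
        defaults.update(kw)
        return GeneRecord(**defaults)

    def test_clean_input_passes_through(self):
        genes = [self._gene(i) for i in range(10)]
        kept, rep = filter_incomplete(genes)
        assert kept == genes
        assert rep.n_removed == 0

    def test_partial_records_removed_and_counted(self):
        genes = [self._gene(i, is_partial=(i < 3)) for i in range(10)]
        kept, rep = filter_incomplete(genes)
        assert len(kept) == 7
        assert rep.n_partial == 3
        assert [g.locus_tag for g in kept] == [f"l{i}" for i in range(3, 10)]

    def test_pseudo_and_missing_seq_removed(self):
        genes = [
            self._gene(0),
            self._gene(1, is_pseudo=True, protein_seq=None),
            self._gene(2, protein_seq=None),
        ]
        kept, rep = filter_incomplete(genes)
        assert len(kept) == 1
        assert rep.n_pseudo == 1 and rep.n_missing_seq == 1

    def test_removed_count_matches_generator_truth(self, small_collection):
        cdir, gt = small_collection
        n_partial_truth = int(gt.genes["is_partial"].sum())
        total_removed = 0
        for gbk in sorted(Path(cdir, "genomes").glob("*.gbk")):
            (rep,) = read_genbank(gbk, genome_id=gbk.stem)
            _, frep = filter_incomplete(list(rep.genes))
            total_removed += frep.n_removed
        assert total_removed == n_partial_truth
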