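import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rippmine.formats_io import (
    FormatError,
    GeneFeature,
    GenomeRecord,
    ProteinRecord,
    from_gff3_coords,
    read_annotations,
    read_fasta,
    read_network,
    to_gff3_coords,
    write_fasta,
    write_gff3,
    write_network,
)
from rippmine.ssn import SimilarityEdge, SsnGraph, SsnParams


class TestReadFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nTVGG\n")
        (rec,) = read_fasta(p, molecule="protein")
        assert rec.id == "a" and rec.length == 4

    def test_duplicate_id(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">a\nAC\n>a\nGG\n")
        with pytest.raises(FormatError, match="'a'"):
            read_fasta(p, molecule="protein")

    def test_mixed_case_normalized(self, tmp_path):
        p = tmp_path / "m.fasta"
        p.write_text(">x\nTvGg\n>y\nmKlV\nwY\n>z\nacdef\n")
        recs = read_fasta(p, molecule="protein")
        assert [r.sequence for r in recs] == ["TVGG", "MKLVWY", "ACDEF"]
        assert [r.length for r in recs] == [4, 6, 5]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.fasta"
        p.write_text("")
        with pytest.raises(FormatError):
            read_fasta(p)

    def test_illegal_character_position(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\nMKJ\n")
        with pytest.raises(FormatError, match="position 2"):
            read_fasta(p, molecule="protein")

    def test_dna_autodetected(self, tmp_path):
        p = tmp_path / "d.fasta"
        p.write_text(">g\nACGTACGTN\n")
        (rec,) = read_fasta(p)
        assert isinstance(rec, GenomeRecord)

    def test_protein_with_x_allowed(self):
        rec = ProteinRecord(id="u", sequence="MKXV")
        assert rec.length == 4


class TestFastaRoundTrip:
    @given(
        seqs=st.lists(
            st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX", min_size=1, max_size=150),
            min_size=1,
            max_size=6,
        ),
        data=st.data(),
    )
    @settings(max_examples=25, deadline=None)
    def test_write_read_identity(self, seqs, data, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("fasta_rt")
        recs = [ProteinRecord(id=f"r{i}", sequence=s) for i, s in enumerate(seqs)]
        path = tmp / "rt.fasta"
        write_fasta(recs, path)
        back = read_fasta(path, molecule="protein")
        assert [(r.id, r.sequence) for r in back] == [(r.id, r.sequence) for r in recs]


class TestAnnotations:
    def test_gff3_coordinate_conversion(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "c1\tsrc\tCDS\t1\t9\t.\t+\t0\tID=f1;product=thing\n"
            "##FASTA\n>c1\n" + "ATGAAATAG" + "A" * 21 + "\n"
        )
        g = read_annotations(p, "gff3+fasta")
        f = g.features[0]
        assert (f.start, f.end, f.strand) == (0, 9, "+")
        assert f.product == "thing"

    def test_genbank_complement(self, tmp_path):
        gb = (
            "LOCUS       test                      20 bp    DNA     linear   BCT 01-JAN-2000\n"
            "DEFINITION  test.\n"
            "ACCESSION   test\n"
            "FEATURES             Location/Qualifiers\n"
            "     CDS             complement(4..9)\n"
            '                     /locus_tag="f1"\n'
            "ORIGIN\n"
            "        1 acgtacgtac gtacgtacgt\n"
            "//\n"
        )
        p = tmp_path / "t.gb"
        p.write_text(gb)
        g = read_annotations(p, "genbank")
        f = g.features[0]
        assert (f.start, f.end, f.strand) == (3, 9, "-")

    def test_feature_beyond_contig(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\nc1\tsrc\tCDS\t1\t999\t.\t+\t0\tID=f1\n"
            "##FASTA\n>c1\nACGTACGT\n"
        )
        with pytest.raises(FormatError, match="beyond"):
            read_annotations(p, "gff3+fasta")

    def test_unknown_strand(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\nc1\tsrc\tCDS\t1\t6\t.\t?\t0\tID=f1\n"
            "##FASTA\n>c1\nACGTACGTACGT\n"
        )
        with pytest.raises(FormatError, match="strand"):
            read_annotations(p, "gff3+fasta")

    def test_gff3_write_read_identity(self, tmp_path):
        genome = GenomeRecord(
            id="gx",
            sequence="ATGAAATAG" + "ACGT" * 10,
            features=[
                GeneFeature("f1", 0, 9, "+", "CDS", "prod a b", "MK"),
                GeneFeature("f2", 12, 24, "-", "CDS", "", "AAA"),
            ],
        )
        path = tmp_path / "g.gff3"
        write_gff3(genome, path)
        back = read_annotations(path, "gff3+fasta")
        assert back.id == genome.id and back.sequence == genome.sequence
        assert [
            (f.feature_id, f.start, f.end, f.strand, f.product) for f in back.features
        ] == [(f.feature_id, f.start, f.end, f.strand, f.product) for f in genome.features]

    def test_length_flag_for_sloppy_cds(self):
        f = GeneFeature("f", 0, 10, "+", "CDS")
        assert f.length_flag
        f2 = GeneFeature("f", 0, 9, "+", "CDS")
        assert not f2.length_flag


class TestCoordinateInvolution:
    @given(st.integers(0, 10**7), st.integers(1, 10**7))
    @settings(max_examples=50, deadline=None)
    def test_involution(self, start, span):
        end = start + span
        assert from_gff3_coords(*to_gff3_coords(start, end)) == (start, end)


def _toy_graph(n_nodes=4, edges=()):
    nodes = {
        f"n{i}": ProteinRecord(id=f"n{i}", sequence="M" * 10) for i in range(n_nodes)
    }
    return SsnGraph(nodes=nodes, edges=list(edges), params=SsnParams())


class TestNetworkIO:
    @pytest.mark.parametrize("dialect", ["edge-list", "graphml"])
    def test_two_node_one_edge(self, tmp_path, dialect):
        e = SimilarityEdge(
            a="n0", b="n1", bitscore=123.456789, evalue=1.25e-90, pct_identity=87.654321
        )
        g = _toy_graph(2, [e])
        path = tmp_path / "net"
        write_network(g, path, dialect=dialect)
        node_ids, edges = read_network(path, dialect=dialect)
        assert node_ids == ["n0", "n1"]
        (back,) = edges
        # writes are at 6 significant digits
        assert back.pct_identity == pytest.approx(e.pct_identity, rel=1e-5)
        assert back.bitscore == pytest.approx(e.bitscore, rel=1e-5)
        assert back.evalue == pytest.approx(e.evalue, rel=1e-5)

    @pytest.mark.parametrize("dialect", ["edge-list", "graphml"])
    def test_empty_graph_roundtrip(self, tmp_path, dialect):
        g = _toy_graph(0)
        path = tmp_path / "empty"
        write_network(g, path, dialect=dialect)
        node_ids, edges = read_network(path, dialect=dialect)
        assert node_ids == [] and edges == []

    @pytest.mark.parametrize("dialect", ["edge-list", "graphml"])
    def test_isolated_nodes_preserved(self, tmp_path, dialect):
        g = _toy_graph(3)
        path = tmp_path / "iso"
        write_network(g, path, dialect=dialect)
        node_ids, edges = read_network(path, dialect=dialect)
        if dialect == "edge-list":
            assert node_ids == ["n0", "n1", "n2"]
        else:
            assert node_ids == ["n0", "n1", "n2"] and edges == []

    def test_many_cluster_synthetic_roundtrip(self, tmp_path):
        # 118 clusters of 3 nodes each, one edge chain per cluster
        import random

        rng = random.Random(5)
        nodes, edges = {}, []
        for c in range(118):
            ids = [f"c{c}_n{i}" for i in range(3)]
            for i in ids:
                nodes[i] = ProteinRecord(id=i, sequence="M" * 5)
            for a, b in zip(ids, ids[1:]):
                edges.append(
                    SimilarityEdge(
                        a=a, b=b,
                        bitscore=rng.uniform(100, 900),
                        evalue=rng.uniform(0, 1e-80),
                        pct_identity=rng.uniform(40, 100),
                    )
                )
        g = SsnGraph(nodes=nodes, edges=edges, params=SsnParams())
        path = tmp_path / "big.tsv"
        write_network(g, path, dialect="edge-list")
        node_ids, back_edges = read_network(path)
        assert sorted(node_ids) == sorted(nodes)
        orig = {(e.a, e.b): e for e in edges}
        assert len(back_edges) == len(edges)
        for be in back_edges:
            oe = orig[(be.a, be.b)]
            assert be.pct_identity == pytest.approx(oe.pct_identity, rel=1e-5)
            assert be.evalue == pytest.approx(oe.evalue, rel=1e-5)
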