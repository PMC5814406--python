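"""Circular genome model: coordinates, sequence utilities, feature map."""

import pytest
from hypothesis import given, settings, strategies as st

from mitomirscan import (
    FeatureMap,
    MitoGenome,
    MtFeature,
    features_overlapping,
    interconvert,
    load_features,
    load_reference,
    reverse_complement,
    subsequence,
)
from mitomirscan.mtgenome import SequenceAlphabetError


class TestBundledReference:
    def test_identity(self, genome):
        assert genome.accession == "NC_001807.4"
        assert genome.length == 16571
        assert genome.circular
        assert set(genome.sequence) <= set("ACGT")

    def test_feature_counts(self, feature_map):
        counts = feature_map.class_counts()
        assert counts["protein_coding"] == 13
        assert counts["tRNA"] == 22
        assert counts["rRNA"] == 2
        assert counts["non_coding"] == 4  # CR + HVR1-3

    def test_hypervariable_regions(self, feature_map):
        hvr1 = feature_map.by_name("MT-HVR1")
        assert (hvr1.start, hvr1.end) == (16024, 16383)
        hvr2 = feature_map.by_name("MT-HVR2")
        assert (hvr2.start, hvr2.end) == (57, 372)
        hvr3 = feature_map.by_name("MT-HVR3")
        assert (hvr3.start, hvr3.end) == (438, 574)

    def test_control_region_wraps_origin(self, feature_map):
        cr = feature_map.by_name("MT-CR")
        assert cr.wraps_origin
        assert cr.start == 16024

    def test_gene_overlaps_present(self, feature_map):
        atp8 = feature_map.by_name("MT-ATP8")
        atp6 = feature_map.by_name("MT-ATP6")
        assert atp8.end >= atp6.start  # ATP8/ATP6 overlap
        nd4l = feature_map.by_name("MT-ND4L")
        nd4 = feature_map.by_name("MT-ND4")
        assert nd4l.end >= nd4.start  # ND4L/ND4 overlap


class TestLoadReference:
    def test_fasta(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">toy\nACGT\n")
        g = load_reference(p)
        assert g.length == 4
        assert g.accession == "toy"

    def test_empty_fasta_is_error(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(ValueError, match="no sequence records"):
            load_reference(p)

    def test_record_selection(self, tmp_path):
        p = tmp_path / "multi.fa"
        p.write_text(">a\nAAAA\n>b\nCCCCCC\n")
        assert load_reference(p).accession == "a"
        assert load_reference(p, record_id="b").length == 6
        with pytest.raises(ValueError, match="not found"):
            load_reference(p, record_id="zzz")

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            MitoGenome(accession="x", sequence="")


class TestSubsequence:
    def test_wrapping(self):
        g = MitoGenome(accession="t", sequence="ACGTAC", circular=True)
        assert subsequence(g, 5, 2) == "ACAC"

    def test_forward(self):
        g = MitoGenome(accession="t", sequence="ACGTAC", circular=True)
        assert subsequence(g, 2, 4) == "CGT"

    def test_hvr1_length(self, genome):
        assert len(subsequence(genome, 16024, 16383)) == 360

    def test_wrap_on_linear_genome_is_error(self, genome):
        linear = MitoGenome(
            accession=genome.accession, sequence=genome.sequence, circular=False
        )
        with pytest.raises(ValueError, match="not circular"):
            subsequence(linear, genome.length, 1)

    def test_out_of_bounds(self):
        g = MitoGenome(accession="t", sequence="ACGT", circular=True)
        with pytest.raises(ValueError):
            subsequence(g, 0, 2)
        with pytest.raises(ValueError):
            subsequence(g, 1, 5)

    @given(
        seq=st.text(alphabet="ACGT", min_size=2, max_size=50),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_split_point_gives_rotation(self, seq, data):
        g = MitoGenome(accession="t", sequence=seq, circular=True)
        k = data.draw(st.integers(min_value=1, max_value=len(seq) - 1))
        rot = subsequence(g, k + 1, k)
        assert len(rot) == len(seq)
        assert rot in seq + seq  # a rotation of the genome


class TestSequenceUtilities:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GGAGTG", "CACTCC"),
            ("", ""),
            ("ggagug", "CACUCC"),  # RNA stays RNA
            ("ACGGTN", "NACCGT"),
        ],
    )
    def test_reverse_complement(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_reverse_complement_rejects_garbage(self):
        with pytest.raises(SequenceAlphabetError):
            reverse_complement("ACGX")
        with pytest.raises(SequenceAlphabetError):
            reverse_complement("ATU")  # mixed alphabets

    @given(st.text(alphabet="ACGTN", max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_reverse_complement_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq.upper()

    @pytest.mark.parametrize(
        "seq,direction,expected",
        [
            ("ggagug", "rna_to_dna", "GGAGTG"),
            ("GAGGTA", "dna_to_rna", "GAGGUA"),
        ],
    )
    def test_interconvert(self, seq, direction, expected):
        assert interconvert(seq, direction) == expected

    def test_interconvert_rejects_garbage(self):
        with pytest.raises(SequenceAlphabetError):
            interconvert("ggxgug", "rna_to_dna")
        with pytest.raises(ValueError):
            interconvert("ACGT", "sideways")

    @given(st.text(alphabet="ACGT", max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_interconvert_round_trip(self, seq):
        there = interconvert(seq, "dna_to_rna")
        assert interconvert(there, "rna_to_dna") == seq.upper()


def _brute_force_overlaps(fm, start, end):
    """Per-base membership check, independent of the interval arithmetic."""
    L = fm.genome_length
    if start > end:
        query = set(range(start, L + 1)) | set(range(1, end + 1))
    else:
        query = set(range(start, end + 1))
    hits = []
    for f in fm.features:
        cells = set()
        for s, e in f.segments(L):
            cells |= set(range(s, e + 1))
        if cells & query:
            hits.append(f)
    return sorted(hits, key=lambda f: (f.start, f.name))


class TestFeaturesOverlapping:
    def test_hvr1_query(self, feature_map):
        names = [f.name for f in features_overlapping(feature_map, 16055, 16060)]
        assert "MT-HVR1" in names

    def test_control_region_query(self, feature_map):
        names = [f.name for f in features_overlapping(feature_map, 41, 46)]
        assert "MT-CR" in names

    def test_empty_map(self):
        fm = FeatureMap(features=[], genome_length=100)
        assert features_overlapping(fm, 10, 20) == []

    def test_wrapping_query_hits_origin_feature(self, feature_map):
        names = [f.name for f in features_overlapping(feature_map, 16570, 3)]
        assert "MT-CR" in names

    @given(data=st.data())
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force(self, data):
        L = data.draw(st.integers(min_value=10, max_value=2000))
        n = data.draw(st.integers(min_value=0, max_value=100))
        feats = []
        for i in range(n):
            s = data.draw(st.integers(min_value=1, max_value=L))
            e = data.draw(st.integers(min_value=1, max_value=L))
            feats.append(
                MtFeature(name=f"F{i}", feature_class="tRNA", start=s, end=e)
            )
        fm = FeatureMap(features=feats, genome_length=L)
        qs = data.draw(st.integers(min_value=1, max_value=L))
        qe = data.draw(st.integers(min_value=1, max_value=L))
        got = features_overlapping(fm, qs, qe)
        want = _brute_force_overlaps(fm, qs, qe)
        assert [f.name for f in got] == [f.name for f in want]


class TestLoadFeaturesValidation:
    def test_out_of_bounds_feature(self, tmp_path, genome):
        p = tmp_path / "f.tsv"
        p.write_text(
            "name\tclass\tstart\tend\tstrand\tdescription\n"
            "BAD\ttRNA\t1\t99999\tL\toops\n"
        )
        with pytest.raises(ValueError, match="exceeds genome length"):
            load_features(p, genome)

    def test_unknown_class_token(self, tmp_path, genome):
        p = tmp_path / "f.tsv"
        p.write_text(
            "name\tclass\tstart\tend\tstrand\tdescription\n"
            "BAD\tplasmid\t1\t10\tL\toops\n"
        )
        with pytest.raises(ValueError, match="unknown feature class"):
            load_features(p, genome)

    def test_genbank_ingestion(self, tmp_path):
        gb = """LOCUS       TOY                       40 bp    DNA     circular PRI 01-JAN-2000
DEFINITION  toy record.
ACCESSION   TOY1
FEATURES             Location/Qualifiers
     CDS             5..16
                     /gene="G1"
                     /product="protein one"
     tRNA            complement(20..30)
                     /gene="T1"
                     /product="tRNA-Xxx"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
"""
        gpath = tmp_path / "toy.gb"
        gpath.write_text(gb)
        g = load_reference(gpath)
        assert g.length == 40
        fm = load_features(gpath, g)
        cds = fm.by_name("G1")
        assert (cds.start, cds.end, cds.feature_class) == (5, 16, "protein_coding")
        trna = fm.by_name("T1")
        assert trna.strand == "H"
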