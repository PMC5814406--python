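"""Hit annotation, per-miRNA tables, strand/region summaries, exports."""

import pytest

from mitomirscan import (
    MiRNA,
    MitoGenome,
    SeedHit,
    SeedSpec,
    annotate_hit,
    build_hit_table,
    extract_seed,
    plant_sites,
    summarize_hits,
)
from mitomirscan.annotate import (
    AnnotatedHit,
    HitTable,
    hit_table_to_frame,
    write_bed6,
    write_table2_report,
)
from mitomirscan.synthetic import PlantSpec, generate_genome


def hit(start, end, strand="forward", mirna="toy"):
    return SeedHit(mirna_id=mirna, start=start, end=end, strand=strand,
                   matched_pattern="ACGTAC")


class TestAnnotateHit:
    def test_hvr1_site(self, feature_map):
        ann = annotate_hit(hit(16055, 16060), feature_map)
        assert ann.mt_gene_area == "MT-HVR1"
        assert ann.functional_area == "non_coding"

    def test_control_region_site(self, feature_map):
        ann = annotate_hit(hit(41, 46), feature_map)
        assert ann.mt_gene_area == "MT-CR"
        assert ann.functional_area == "non_coding"

    def test_gene_overlap_lists_both(self, feature_map):
        # inside the ATP8/ATP6 dual-coding stretch
        ann = annotate_hit(hit(8530, 8535), feature_map)
        assert "MT-ATP8" in ann.all_overlaps and "MT-ATP6" in ann.all_overlaps
        assert ann.ambiguous  # full containment in both genes is a tie
        assert ann.mt_gene_area == "MT-ATP8"  # earlier start breaks the tie
        assert ann.functional_area == "coding"

    def test_gene_outranks_noncoding(self, feature_map):
        # tRNA-Phe sits inside no HVR but after the control region's wrap end
        ann = annotate_hit(hit(600, 605), feature_map)
        assert ann.mt_gene_area == "MT-TF"
        assert ann.functional_area == "coding"

    def test_primary_is_among_overlaps(self, feature_map):
        for h in (hit(16055, 16060), hit(8530, 8535), hit(600, 605)):
            ann = annotate_hit(h, feature_map)
            assert ann.mt_gene_area in ann.all_overlaps

    def test_intergenic_flagged(self, feature_map):
        # 5892..5903 lies between tRNA-Tyr and COI in the standard annotation
        ann = annotate_hit(hit(5895, 5900), feature_map)
        assert ann.mt_gene_area == "intergenic"
        assert ann.functional_area == "non_coding"
        assert ann.ambiguous

    def test_annotation_is_pure(self, feature_map):
        h = hit(16055, 16060)
        assert annotate_hit(h, feature_map) == annotate_hit(h, feature_map)


class TestBuildHitTable:
    def test_planted_sites_counted(self, feature_map):
        mir = MiRNA(id="syn-mir", sequence="uggagugugacaaugguguuug")
        base = generate_genome(16571, gc_fraction=0.0, rng_seed=5)  # A/T only
        seed = extract_seed(mir)
        genome, truth = plant_sites(
            base, seed, PlantSpec(mirna_id="syn-mir", n_forward=3), rng_seed=1
        )
        table = build_hit_table([mir], genome, feature_map, SeedSpec())
        planted = {(h.start, h.end, h.strand) for h in truth.planted}
        got = {(r.hit.start, r.hit.end, r.hit.strand) for r in table.rows}
        assert planted <= got
        assert table.counts["syn-mir"] >= 3

    def test_zero_hit_mirnas_kept(self, genome, feature_map, mirnas_by_id):
        mir = mirnas_by_id["miR-107"]
        table = build_hit_table(
            [mir], genome, feature_map, SeedSpec(match_mode="parallel")
        )
        assert table.counts == {"miR-107": 0}
        assert table.rows == []

    def test_empty_mirna_list_is_error(self, genome, feature_map):
        with pytest.raises(ValueError, match="empty"):
            build_hit_table([], genome, feature_map, SeedSpec())

    def test_counts_match_rows(self, genome, feature_map, mirnas):
        table = build_hit_table(
            mirnas, genome, feature_map, SeedSpec(match_mode="parallel")
        )
        for mid, n in table.counts.items():
            assert n == len(table.rows_for(mid))

    def test_override_changes_one_mirna_only(self, genome, feature_map, mirnas_by_id):
        mirs = [mirnas_by_id["miR-378"], mirnas_by_id["miR-122-5p"]]
        base_spec = SeedSpec(match_mode="parallel")
        ov = {"miR-378": SeedSpec(window_start=3, window_end=8, match_mode="parallel")}
        t0 = build_hit_table(mirs, genome, feature_map, base_spec)
        t1 = build_hit_table(mirs, genome, feature_map, base_spec, overrides=ov)
        assert t0.counts["miR-122-5p"] == t1.counts["miR-122-5p"]
        assert t0.counts["miR-378"] != t1.counts["miR-378"]


class TestSummaries:
    def _table(self, n_fwd, n_rev):
        rows = []
        for i in range(n_fwd):
            rows.append(AnnotatedHit(hit(10 + i, 15 + i), "MT-CR", "non_coding", "", ("MT-CR",)))
        for i in range(n_rev):
            rows.append(
                AnnotatedHit(hit(100 + i, 105 + i, strand="reverse"), "MT-ND1",
                             "coding", "", ("MT-ND1",))
            )
        return HitTable(rows=rows, counts={"toy": n_fwd + n_rev}, genome_length=16571)

    def test_light_strand_fraction(self):
        s = summarize_hits(self._table(38, 12))
        assert s.light_strand_fraction == pytest.approx(0.76)
        assert s.light_strand_sites == 38
        assert s.heavy_strand_sites == 12

    def test_empty_table_flagged(self):
        s = summarize_hits(HitTable(rows=[], counts={}, genome_length=100))
        assert s.total_sites == 0
        assert s.light_strand_fraction is None

    def test_region_tallies_conserve_total(self):
        s = summarize_hits(self._table(5, 7))
        assert sum(s.per_region.values()) == s.total_sites == 12
        assert s.per_region == {"MT-CR": 5, "MT-ND1": 7}

    def test_site_counts_partition_mirnas(self):
        t = HitTable(rows=[], counts={"a": 2, "b": 0, "c": 1}, genome_length=10)
        s = summarize_hits(t)
        assert s.n_mirnas_with_sites + s.n_mirnas_without_sites == 3
        assert s.n_mirnas_without_sites == 1


class TestExports:
    def test_bed6_wrapping_hit_split(self, tmp_path):
        rows = [AnnotatedHit(hit(10, 2), "MT-CR", "non_coding", "", ("MT-CR",))]
        t = HitTable(rows=rows, counts={"toy": 1}, genome_length=12)
        out = tmp_path / "hits.bed"
        write_bed6(t, out, chrom="chrM")
        lines = out.read_text().splitlines()
        assert lines == ["chrM\t9\t12\ttoy_0_wrapA\t0\t+", "chrM\t0\t2\ttoy_0_wrapB\t0\t+"]

    def test_bed6_zero_based_half_open(self, tmp_path):
        rows = [AnnotatedHit(hit(5, 10, strand="reverse"), "MT-CR", "non_coding", "", ("MT-CR",))]
        t = HitTable(rows=rows, counts={"toy": 1}, genome_length=100)
        out = tmp_path / "hits.bed"
        write_bed6(t, out)
        assert out.read_text().split("\t")[1:3] == ["4", "10"]
        assert out.read_text().strip().endswith("-")

    def test_report_includes_zero_count_mirnas(self, tmp_path):
        t = HitTable(rows=[], counts={"miR-x": 0}, genome_length=10)
        out = tmp_path / "rep.tsv"
        write_table2_report(t, out)
        assert "miR-x\t0" in out.read_text()

    def test_frame_roundtrip(self, feature_map):
        rows = [annotate_hit(hit(41, 46), feature_map)]
        t = HitTable(rows=rows, counts={"toy": 1}, genome_length=16571)
        df = hit_table_to_frame(t)
        assert list(df["mt_gene_area"]) == ["MT-CR"]
        assert list(df["display_range"]) == ["41-46"]
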