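"""Gene-region models, scan-unit assembly, and ATG-relative coordinates."""

import numpy as np
import pytest

from cismotif.genome import (
    ALL_REGION_KINDS,
    AnnotationError,
    GenomeError,
    RegionKind,
    atg_relative_position,
    build_scan_unit,
    flanking_cds_bounds,
    load_gene_models,
    load_genome,
    reverse_complement,
)

from conftest import make_unit, minus_gene, plus_gene


class TestLoadGenome:
    def test_single_record(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n")
        g = load_genome(p)
        assert g.lengths == {"chr1": 4}

    def test_lowercase_soft_mask_uppercased(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nacgt\n")
        assert load_genome(p).chromosomes["chr1"] == "ACGT"

    def test_invalid_character_names_position(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACXGT\n")
        with pytest.raises(GenomeError, match="position 3"):
            load_genome(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text("")
        with pytest.raises(GenomeError):
            load_genome(p)

    def test_wrapped_multi_record(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">a\nACGTAC\nGTNN\n>b\nTTTT\n")
        g = load_genome(p)
        assert g.lengths == {"a": 10, "b": 4}


GFF_HEADER = "##gff-version 3\n"


def write_gff(tmp_path, body):
    p = tmp_path / "m.gff3"
    p.write_text(GFF_HEADER + body)
    return p


class TestLoadGeneModels:
    def test_single_exon_gene_three_regions(self, tmp_path):
        body = "\n".join(
            [
                "chr1\t.\tgene\t101\t150\t.\t+\t.\tID=g1;Name=N1;description=kinase",
                "chr1\t.\tmRNA\t101\t150\t.\t+\t.\tID=t1;Parent=g1",
                "chr1\t.\texon\t101\t150\t.\t+\t.\tID=e1;Parent=t1",
                "chr1\t.\tCDS\t111\t140\t.\t+\t0\tID=c1;Parent=t1",
            ]
        )
        genes = load_gene_models(write_gff(tmp_path, body))
        (g,) = genes
        t = g.transcripts[0]
        kinds = [r.kind for r in t.regions]
        assert kinds == [RegionKind.UTR5, RegionKind.CDS, RegionKind.UTR3]
        assert [r.length for r in t.regions] == [10, 30, 10]
        assert t.atg_genomic == 111
        assert g.name == "N1" and g.description == "kinase"

    def test_two_exon_transcript_derives_intron(self, tmp_path):
        body = "\n".join(
            [
                "chr1\t.\tgene\t1\t150\t.\t+\t.\tID=g1",
                "chr1\t.\tmRNA\t1\t150\t.\t+\t.\tID=t1;Parent=g1",
                "chr1\t.\texon\t1\t50\t.\t+\t.\tID=e1;Parent=t1",
                "chr1\t.\texon\t101\t150\t.\t+\t.\tID=e2;Parent=t1",
                "chr1\t.\tCDS\t1\t50\t.\t+\t0\tID=c1;Parent=t1",
                "chr1\t.\tCDS\t101\t150\t.\t+\t0\tID=c2;Parent=t1",
            ]
        )
        (g,) = load_gene_models(write_gff(tmp_path, body))
        introns = [r for r in g.transcripts[0].regions if r.kind is RegionKind.INTRON]
        assert [(r.start, r.end, r.length) for r in introns] == [(51, 100, 50)]

    def test_two_isoforms(self, tmp_path):
        body = "\n".join(
            [
                "chr1\t.\tgene\t1\t100\t.\t+\t.\tID=g1",
                "chr1\t.\tmRNA\t1\t100\t.\t+\t.\tID=t1;Parent=g1",
                "chr1\t.\texon\t1\t100\t.\t+\t.\tID=e1;Parent=t1",
                "chr1\t.\tCDS\t1\t99\t.\t+\t0\tID=c1;Parent=t1",
                "chr1\t.\tmRNA\t1\t100\t.\t+\t.\tID=t2;Parent=g1",
                "chr1\t.\texon\t1\t40\t.\t+\t.\tID=e2;Parent=t2",
                "chr1\t.\texon\t61\t100\t.\t+\t.\tID=e3;Parent=t2",
                "chr1\t.\tCDS\t1\t40\t.\t+\t0\tID=c2;Parent=t2",
                "chr1\t.\tCDS\t61\t100\t.\t+\t0\tID=c3;Parent=t2",
            ]
        )
        (g,) = load_gene_models(write_gff(tmp_path, body))
        assert len(g.transcripts) == 2

    def test_unknown_parent_rejected(self, tmp_path):
        body = "\n".join(
            [
                "chr1\t.\tgene\t1\t100\t.\t+\t.\tID=g1",
                "chr1\t.\tmRNA\t1\t100\t.\t+\t.\tID=t1;Parent=nope",
            ]
        )
        with pytest.raises(AnnotationError, match="unknown gene Parent"):
            load_gene_models(write_gff(tmp_path, body))

    def test_feature_beyond_chromosome_rejected(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\n" + "A" * 50 + "\n")
        body = "\n".join(
            [
                "chr1\t.\tgene\t1\t100\t.\t+\t.\tID=g1",
                "chr1\t.\tmRNA\t1\t100\t.\t+\t.\tID=t1;Parent=g1",
                "chr1\t.\texon\t1\t100\t.\t+\t.\tID=e1;Parent=t1",
                "chr1\t.\tCDS\t1\t100\t.\t+\t0\tID=c1;Parent=t1",
            ]
        )
        with pytest.raises(AnnotationError, match="beyond chromosome"):
            load_gene_models(write_gff(tmp_path, body), load_genome(fa))

    def test_minus_strand_region_order_is_five_to_three(self, tmp_path):
        body = "\n".join(
            [
                "chr1\t.\tgene\t101\t150\t.\t-\t.\tID=g1",
                "chr1\t.\tmRNA\t101\t150\t.\t-\t.\tID=t1;Parent=g1",
                "chr1\t.\texon\t101\t150\t.\t-\t.\tID=e1;Parent=t1",
                "chr1\t.\tCDS\t111\t140\t.\t-\t0\tID=c1;Parent=t1",
            ]
        )
        (g,) = load_gene_models(write_gff(tmp_path, body))
        t = g.transcripts[0]
        assert [r.kind for r in t.regions] == [
            RegionKind.UTR5,
            RegionKind.CDS,
            RegionKind.UTR3,
        ]
        # on the minus strand the 5' UTR sits at the high-coordinate end
        assert t.regions[0].start == 141
        assert t.atg_genomic == 140


class TestBuildScanUnit:
    def test_intergenic_truncated_at_flanking_cds(self, toy_genome):
        # upstream gap of 300 bp to the flanking CDS; 500 bp requested
        gene = plus_gene(utr5=(401, 410), cds=(411, 440), utr3=(441, 450))
        unit = build_scan_unit(
            gene, "GENE1.1", toy_genome,
            selected_kinds={RegionKind.INTERGENIC5},
            intergenic5_len=500,
            neighbors=(100, None),
        )
        assert unit.length == 300

    def test_blank_length_uses_full_gap(self, toy_genome):
        gene = plus_gene()
        unit = build_scan_unit(
            gene, "GENE1.1", toy_genome,
            selected_kinds={RegionKind.INTERGENIC5},
            intergenic5_len=None,
            neighbors=(50, None),
        )
        assert unit.length == 201 - 51  # 51..200 inclusive

    def test_full_selection_length_is_additive(self, toy_genome):
        gene = plus_gene()
        unit = build_scan_unit(
            gene, "GENE1.1", toy_genome,
            intergenic5_len=30, intergenic3_len=40,
        )
        assert unit.length == 30 + 10 + 30 + 10 + 40

    def test_clamped_at_chromosome_start(self, toy_genome):
        gene = plus_gene(utr5=(11, 20), cds=(21, 50), utr3=(51, 60))
        unit = build_scan_unit(
            gene, "GENE1.1", toy_genome,
            selected_kinds={RegionKind.INTERGENIC5},
            intergenic5_len=500,
        )
        assert unit.length == 10  # positions 1..10 only

    def test_overlapping_neighbor_gives_empty_intergenic(self, toy_genome):
        gene = plus_gene()
        unit = build_scan_unit(
            gene, "GENE1.1", toy_genome,
            selected_kinds={RegionKind.INTERGENIC5},
            neighbors=(250, None),  # neighbor CDS reaches past our start
        )
        assert unit.length == 0

    def test_unknown_region_kind_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="unknown region kind"):
            build_scan_unit(
                plus_gene(), "GENE1.1", toy_genome, selected_kinds={"promoter"}
            )

    def test_minus_strand_unit_is_reverse_complement(self, toy_genome):
        gene = minus_gene()
        unit = build_scan_unit(
            gene, "GENE2.1", toy_genome,
            selected_kinds={RegionKind.UTR5, RegionKind.CDS, RegionKind.UTR3},
        )
        genomic = toy_genome.fetch("chr1", 301, 350)
        assert unit.sequence == reverse_complement(genomic)

    def test_offset_to_genomic_round_trip(self, toy_genome):
        for gene, tid in ((plus_gene(), "GENE1.1"), (minus_gene(), "GENE2.1")):
            unit = build_scan_unit(
                gene, tid, toy_genome, intergenic5_len=25, intergenic3_len=15
            )
            for off in range(unit.length):
                assert unit.unit_offset_at(unit.genomic_position(off)) == off

    def test_boundaries_concatenated_without_separator(self, toy_genome):
        unit = build_scan_unit(
            plus_gene(), "GENE1.1", toy_genome,
            selected_kinds={RegionKind.UTR5, RegionKind.CDS},
        )
        assert unit.sequence == toy_genome.fetch("chr1", 201, 240)


class TestAtgRelativePosition:
    def test_base_before_atg_is_minus_one(self, toy_genome):
        unit = build_scan_unit(plus_gene(), "GENE1.1", toy_genome)
        off = unit.unit_offset_at(210)  # last UTR5 base, immediately 5' of ATG
        assert atg_relative_position(unit, off) == -1

    def test_a_of_start_codon_is_plus_one(self, toy_genome):
        unit = build_scan_unit(plus_gene(), "GENE1.1", toy_genome)
        assert atg_relative_position(unit, unit.unit_offset_at(211)) == 1

    def test_ten_bases_upstream_is_minus_ten(self, toy_genome):
        unit = build_scan_unit(plus_gene(), "GENE1.1", toy_genome)
        assert atg_relative_position(unit, unit.unit_offset_at(201)) == -10

    def test_no_position_zero(self, toy_genome):
        unit = build_scan_unit(
            plus_gene(), "GENE1.1", toy_genome,
            selected_kinds={RegionKind.UTR5, RegionKind.CDS, RegionKind.UTR3},
        )
        positions = {atg_relative_position(unit, off) for off in range(unit.length)}
        assert 0 not in positions
        assert positions == set(range(-10, 0)) | set(range(1, 41))

    def test_minus_strand_signs(self, toy_genome):
        unit = build_scan_unit(minus_gene(), "GENE2.1", toy_genome)
        # ATG at genomic 340; genomic 341 is 5' of it on the minus strand
        assert atg_relative_position(unit, unit.unit_offset_at(341)) == -1
        assert atg_relative_position(unit, unit.unit_offset_at(340)) == 1

    def test_offset_outside_unit_rejected(self, toy_genome):
        unit = build_scan_unit(plus_gene(), "GENE1.1", toy_genome)
        with pytest.raises(IndexError):
            atg_relative_position(unit, unit.length)


def test_flanking_cds_bounds_orders_neighbors(toy_genome):
    a = plus_gene(utr5=(101, 110), cds=(111, 140), utr3=(141, 150), gene_id="A")
    b = plus_gene(utr5=(401, 410), cds=(411, 440), utr3=(441, 450), gene_id="B")
    c = plus_gene(utr5=(701, 710), cds=(711, 740), utr3=(741, 750), gene_id="C")
    bounds = flanking_cds_bounds([a, b, c])
    assert bounds["A"] == (None, 411)
    assert bounds["B"] == (140, 711)
    assert bounds["C"] == (440, None)
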