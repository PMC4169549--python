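"""File-format contracts: FASTA, GFF3, pileup dialect, VCF, fixture table."""

from __future__ import annotations

import textwrap

import pytest

import snp2gene as sg
from snp2gene.models import FormatError, Observation, PileupColumn, VariantCall


# ---------------------------------------------------------------------------
# FASTA

def write(tmp_path, name, content):
    p = tmp_path / name
    p.write_text(textwrap.dedent(content))
    return p


class TestFasta:
    def test_two_records_total_length(self, tmp_path):
        p = write(tmp_path, "a.fa", f">one\n{'A' * 50}\n>two desc text\n{'C' * 70}\n")
        genome = sg.read_fasta(p)
        assert list(genome.chromosomes) == ["one", "two"]
        assert genome.total_length == 120

    def test_lowercase_upper_cased(self, tmp_path):
        p = write(tmp_path, "a.fa", ">r\nacgt\n")
        assert sg.read_fasta(p).chromosomes["r"] == "ACGT"

    def test_invalid_character_names_line(self, tmp_path):
        p = write(tmp_path, "a.fa", ">r\nACGT\nAXGT\n")
        with pytest.raises(FormatError, match="line 3"):
            sg.read_fasta(p)

    def test_empty_sequence_rejected(self, tmp_path):
        p = write(tmp_path, "a.fa", ">r1\n>r2\nACGT\n")
        with pytest.raises(FormatError, match="empty sequence"):
            sg.read_fasta(p)

    def test_roundtrip(self, tmp_path):
        genome = sg.ReferenceGenome({"c1": "ACGTN" * 30, "c2": "TTTT"})
        p = tmp_path / "g.fa"
        sg.write_fasta(genome, p)
        assert sg.read_fasta(p).chromosomes == genome.chromosomes


# ---------------------------------------------------------------------------
# GFF3

GFF_TEMPLATE = """\
##gff-version 3
chr1\tt\tgene\t1\t300\t.\t{strand}\t.\tID=G1
chr1\tt\tmRNA\t1\t300\t.\t{strand}\t.\tID=G1.1;Parent=G1
chr1\tt\texon\t1\t100\t.\t{strand}\t.\tParent=G1.1
chr1\tt\texon\t201\t300\t.\t{strand}\t.\tParent=G1.1
chr1\tt\tCDS\t51\t100\t.\t{strand}\t0\tParent=G1.1
chr1\tt\tCDS\t201\t250\t.\t{strand}\t0\tParent=G1.1
"""


class TestGff3:
    @pytest.mark.parametrize(
        "strand,utr5,utr3",
        [("+", [(1, 50)], [(251, 300)]), ("-", [(251, 300)], [(1, 50)])],
    )
    def test_utr_derivation_by_strand(self, tmp_path, strand, utr5, utr3):
        p = write(tmp_path, "g.gff3", GFF_TEMPLATE.format(strand=strand))
        (model,) = sg.read_gff3(p)
        assert model.utr5_segments == utr5
        assert model.utr3_segments == utr3
        assert model.cds_segments == [(51, 100), (201, 250)]

    def test_representative_transcript_longest_cds(self, tmp_path):
        gff = textwrap.dedent("""\
            ##gff-version 3
            chr1\tt\tgene\t1\t600\t.\t+\t.\tID=G1
            chr1\tt\tmRNA\t1\t600\t.\t+\t.\tID=G1.2;Parent=G1
            chr1\tt\texon\t1\t600\t.\t+\t.\tParent=G1.2
            chr1\tt\tCDS\t1\t300\t.\t+\t0\tParent=G1.2
            chr1\tt\tmRNA\t1\t600\t.\t+\t.\tID=G1.1;Parent=G1
            chr1\tt\texon\t1\t600\t.\t+\t.\tParent=G1.1
            chr1\tt\tCDS\t1\t150\t.\t+\t0\tParent=G1.1
            """)
        p = write(tmp_path, "g.gff3", gff)
        (model,) = sg.read_gff3(p)
        assert model.cds_segments == [(1, 300)]

    def test_cds_without_mrna_parent_rejected(self, tmp_path):
        gff = textwrap.dedent("""\
            ##gff-version 3
            chr1\tt\tgene\t1\t300\t.\t+\t.\tID=G1
            chr1\tt\tCDS\t51\t100\t.\t+\t0\tID=orphan;Parent=G1
            """)
        p = write(tmp_path, "g.gff3", gff)
        with pytest.raises(FormatError, match="no parent mRNA"):
            sg.read_gff3(p)

    def test_zero_genes_warns_empty(self, tmp_path):
        p = write(tmp_path, "g.gff3", "##gff-version 3\nchr1\tt\tregion\t1\t10\t.\t+\t.\tID=r\n")
        with pytest.warns(UserWarning, match="no gene features"):
            assert sg.read_gff3(p) == []

    def test_utr_cds_union_equals_exons(self, tmp_path):
        p = write(tmp_path, "g.gff3", GFF_TEMPLATE.format(strand="+"))
        (m,) = sg.read_gff3(p)
        union = sorted(
            set().union(*(set(range(a, b + 1)) for a, b in
                          m.cds_segments + m.utr5_segments + m.utr3_segments))
        )
        exonic = sorted(set().union(*(set(range(a, b + 1)) for a, b in m.exons)))
        assert union == exonic

    def test_gff3_roundtrip(self, tmp_path):
        p = write(tmp_path, "g.gff3", GFF_TEMPLATE.format(strand="+"))
        (m,) = sg.read_gff3(p)
        p2 = tmp_path / "out.gff3"
        sg.write_gff3([m], p2)
        (m2,) = sg.read_gff3(p2)
        assert m2 == m


# ---------------------------------------------------------------------------
# pileup dialect

class TestPileup:
    def test_depth_and_indel_evidence(self, tmp_path):
        p = write(tmp_path, "p.tsv",
                  "chr1\t5\tG\tA:30:u,A:28:u,G:31:r,A:2:u,A:30:u:+AT\n")
        (col,) = sg.read_pileup(p)
        assert col.depth == 5
        assert col.observations[4].indel == "+AT"
        assert col.observations[2].unique is False

    def test_empty_file_warns(self, tmp_path):
        p = write(tmp_path, "p.tsv", "")
        with pytest.warns(UserWarning, match="empty pileup"):
            assert list(sg.read_pileup(p)) == []

    @pytest.mark.parametrize(
        "line,match",
        [
            ("chr1\t5\tG\tA:41:u", "quality 41"),
            ("chr1\t0\tG\tA:30:u", "position 0"),
            ("chr1\t5\tG\tA:30:x", "mapping flag"),
        ],
    )
    def test_format_errors(self, tmp_path, line, match):
        p = write(tmp_path, "p.tsv", line + "\n")
        with pytest.raises(FormatError, match=match):
            list(sg.read_pileup(p))

    def test_roundtrip_preserves_observations(self, tmp_path):
        cols = [
            PileupColumn("chr1", 3, "G", [
                Observation("A", 30, True, None),
                Observation("G", 12, False, "-CC"),
            ]),
            PileupColumn("chr2", 9, "T", []),
        ]
        p = tmp_path / "p.tsv"
        sg.write_pileup(cols, p)
        assert list(sg.read_pileup(p)) == cols


# ---------------------------------------------------------------------------
# VCF and effects TSV

class TestVcf:
    CALLS = [
        VariantCall("chr1", 10, "G", "A", "SNP", 9, 0.9, 36, "homozygous"),
        VariantCall("chr1", 44, "T", "TAT", "INS", 4, 1.0, 40, "homozygous"),
        VariantCall("chr2", 5, "CA", "C", "DEL", 5, 5 / 6, 33, "homozygous"),
    ]

    def test_site_records_written(self, tmp_path):
        p = tmp_path / "c.vcf"
        sg.write_vcf(self.CALLS, p)
        body = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert len(body) == 3
        assert "GT" not in p.read_text()

    def test_write_read_roundtrip(self, tmp_path):
        p = tmp_path / "c.vcf"
        sg.write_vcf(self.CALLS, p)
        assert sg.read_vcf(p) == self.CALLS

    def test_body_bit_identical_after_roundtrip(self, tmp_path):
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        sg.write_vcf(self.CALLS, p1)
        sg.write_vcf(sg.read_vcf(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_effects_tsv_stop_labels(self, tmp_path):
        effect = sg.SnpEffect(
            chromosome="chr1", position=9, ref="G", alt="A", locus_id="G1",
            region="cds", consequence="stop_gained", codon_index=3,
            codon_position=3, ref_codon="TGG", alt_codon="TGA",
            ref_aa="W", alt_aa="*",
        )
        p = tmp_path / "e.tsv"
        sg.write_effects_tsv([effect], p)
        assert "stop_gained(isSNP)" in p.read_text()


# ---------------------------------------------------------------------------
# packaged per-chromosome table

class TestFixtureTable:
    def test_row_values(self):
        rows = sg.load_table2_fixture()
        assert len(rows) == 12
        by_chrom = {r.chromosome: r for r in rows}
        assert by_chrom["1"].total_snps == 207659
        assert by_chrom["1"].non_synonymous == 13377
        assert by_chrom["9"].total_snps == 109797

    def test_row_internal_consistency(self):
        for r in sg.load_table2_fixture():
            assert r.synonymous + r.non_synonymous == r.cds


class TestLabelTable:
    def test_multi_label_and_unmatched(self, tmp_path):
        p = write(tmp_path, "l.tsv", "L1\tfamA\nL1\tfamB\nL2\tfamA\nLX\tfamC\n")
        table = sg.read_label_table(p, namespace="family")
        assert table.labels_by_locus["L1"] == {"famA", "famB"}
        assert table.loci_by_label["famA"] == {"L1", "L2"}
        assert table.unmatched({"L1", "L2"}) == {"LX"}
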