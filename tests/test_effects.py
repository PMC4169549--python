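"""Codon-level effect classification, region location and their invariants."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from Bio.Seq import Seq

import snp2gene as sg
from snp2gene.effects import reverse_complement, spliced_cds
from snp2gene.models import GeneModel, ReferenceMismatchError, VariantCall

from conftest import build_gene, random_cds


def snp(chrom, pos, ref, alt):
    return VariantCall(chrom, pos, ref, alt, "SNP", 5, 1.0, 40, "homozygous")


def oracle_consequence(model, genome, variant):
    """Independent route: mutate the full CDS, translate both proteins with
    Biopython and compare them."""
    cds = spliced_cds(model, genome)
    from snp2gene.effects import _coding_offset

    offset = _coding_offset(model, variant.position)
    alt = variant.alt if model.strand == "+" else reverse_complement(variant.alt)
    mutated = cds[:offset] + alt + cds[offset + 1 :]
    ref_protein = str(Seq(cds).translate())
    alt_protein = str(Seq(mutated).translate())
    if ref_protein == alt_protein:
        return "synonymous"
    diffs = [i for i, (a, b) in enumerate(zip(ref_protein, alt_protein)) if a != b]
    assert len(diffs) == 1
    i = diffs[0]
    if alt_protein[i] == "*":
        return "stop_gained"
    if ref_protein[i] == "*":
        return "stop_lost"
    return "missense"


# M  A  W  *
TOY_CDS = "ATGGCTTGGTGA"


class TestCodonEffect:
    def test_synonymous_third_position(self):
        genome, model = build_gene(TOY_CDS, "+")
        pos = model.cds_segments[0][0] + 5  # third base of GCT
        effect = sg.codon_effect(snp("chr1", pos, genome.base("chr1", pos), "C"),
                                 model, genome)
        assert (effect.ref_codon, effect.alt_codon) == ("GCT", "GCC")
        assert effect.ref_aa == effect.alt_aa == "A"
        assert effect.consequence == "synonymous"

    def test_stop_gained_trp_to_stop(self):
        genome, model = build_gene(TOY_CDS, "+")
        pos = model.cds_segments[0][0] + 8  # third base of TGG
        effect = sg.codon_effect(snp("chr1", pos, "G", "A"), model, genome)
        assert (effect.ref_codon, effect.alt_codon) == ("TGG", "TGA")
        assert (effect.ref_aa, effect.alt_aa) == ("W", "*")
        assert effect.consequence == "stop_gained"

    def test_stop_lost_terminal_codon(self):
        genome, model = build_gene(TOY_CDS, "+")
        pos = model.cds_segments[0][0] + 11  # third base of terminal TGA
        effect = sg.codon_effect(snp("chr1", pos, "A", "G"), model, genome)
        assert (effect.ref_aa, effect.alt_aa) == ("*", "W")
        assert effect.consequence == "stop_lost"

    def test_minus_strand_matches_retranslation_oracle(self):
        genome, model = build_gene(TOY_CDS, "-")
        start, end = model.cds_segments[0]
        for pos in range(start, end + 1):
            ref = genome.base("chr1", pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                variant = snp("chr1", pos, ref, alt)
                effect = sg.codon_effect(variant, model, genome)
                assert effect.consequence == oracle_consequence(model, genome, variant)

    def test_reference_mismatch_raises(self):
        genome, model = build_gene(TOY_CDS, "+")
        pos = model.cds_segments[0][0]
        wrong_ref = "C" if genome.base("chr1", pos) != "C" else "G"
        with pytest.raises(ReferenceMismatchError):
            sg.codon_effect(snp("chr1", pos, wrong_ref, "T"), model, genome)


@pytest.mark.parametrize("strand", ["+", "-"])
@pytest.mark.parametrize("introns", [(), (40, 61)])
def test_oracle_equivalence_random_gene(strand, introns):
    """Every single-base CDS substitution of a random 60-codon gene agrees
    with full-CDS retranslation, on both strands, spliced or not."""
    rng = np.random.default_rng(11 if strand == "+" else 13)
    genome, model = build_gene(random_cds(rng, 60), strand, intron_lengths=introns, rng=rng)
    checked = 0
    for start, end in model.cds_segments:
        for pos in range(start, end + 1):
            ref = genome.base("chr1", pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                variant = snp("chr1", pos, ref, alt)
                effect = sg.codon_effect(variant, model, genome)
                assert effect.consequence == oracle_consequence(model, genome, variant)
                checked += 1
    assert checked == 9 * 60


def test_strand_symmetry_of_consequences():
    """Annotating the reverse-complemented genome with the mirrored model
    yields the identical consequence multiset."""
    rng = np.random.default_rng(5)
    genome, model = build_gene(random_cds(rng, 40), "+", rng=rng)
    seq = genome.chromosomes["chr1"]
    L = len(seq)
    mirror_genome = sg.ReferenceGenome({"chr1": reverse_complement(seq)})
    flip = lambda iv: (L + 1 - iv[1], L + 1 - iv[0])
    mirror_model = GeneModel(
        locus_id=model.locus_id, chromosome="chr1", strand="-",
        span=flip(model.span),
        exons=sorted(flip(iv) for iv in model.exons),
        cds_segments=sorted(flip(iv) for iv in model.cds_segments),
    )

    def all_consequences(g, m):
        out = []
        for start, end in m.cds_segments:
            for pos in range(start, end + 1):
                ref = g.base("chr1", pos)
                for alt in "ACGT":
                    if alt != ref:
                        out.append(sg.codon_effect(snp("chr1", pos, ref, alt), m, g).consequence)
        return Counter(out)

    assert all_consequences(genome, model) == all_consequences(mirror_genome, mirror_model)


# ---------------------------------------------------------------------------
# location and aggregation

class TestLocate:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.genome, self.model = build_gene(
            random_cds(rng, 40), "+", intron_lengths=(50,), rng=rng, flank=100
        )
        # widen the span with UTRs on either side of the CDS
        a, b = self.model.span
        self.model = GeneModel(
            locus_id="G1", chromosome="chr1", strand="+",
            span=(a - 20, b + 20),
            exons=[(a - 20, self.model.exons[0][1])]
            + self.model.exons[1:-1]
            + [(self.model.exons[-1][0], b + 20)],
            cds_segments=self.model.cds_segments,
            utr5_segments=[(a - 20, a - 1)],
            utr3_segments=[(b + 1, b + 20)],
        )
        self.index = sg.build_interval_index([self.model])

    def locate(self, pos):
        ref = self.genome.base("chr1", pos)
        alt = "A" if ref != "A" else "C"
        return sg.locate_variant(snp("chr1", pos, ref, alt), self.index, self.genome)

    def test_utr5(self):
        assert self.locate(self.model.span[0]) == [("G1", "utr5")]

    def test_intergenic(self):
        assert self.locate(2) == [(None, "intergenic")]

    def test_intron(self):
        intron_pos = self.model.exons[0][1] + 1
        assert self.locate(intron_pos) == [("G1", "intron_noncoding")]

    def test_cds(self):
        assert self.locate(self.model.cds_segments[0][0]) == [("G1", "cds")]

    def test_beyond_chromosome_raises(self):
        with pytest.raises(IndexError):
            self.locate(len(self.genome.chromosomes["chr1"]) + 5)

    def test_overlapping_loci_both_returned(self):
        other = GeneModel(
            locus_id="G0", chromosome="chr1", strand="+",
            span=(1, self.model.span[0] + 5),
            exons=[(1, self.model.span[0] + 5)], cds_segments=[],
        )
        index = sg.build_interval_index([self.model, other])
        pos = self.model.span[0]
        ref = self.genome.base("chr1", pos)
        hits = sg.locate_variant(snp("chr1", pos, ref, "A" if ref != "A" else "C"), index)
        assert {h[0] for h in hits} == {"G0", "G1"}


class TestAnnotateAll:
    def test_precedence_and_partition(self):
        rng = np.random.default_rng(9)
        genome, model = build_gene(random_cds(rng, 40), "+", rng=rng, flank=60)
        cds_pos = model.cds_segments[0][0] + 3
        variants = [
            snp("chr1", 2, genome.base("chr1", 2), "A" if genome.base("chr1", 2) != "A" else "C"),
            snp("chr1", cds_pos, genome.base("chr1", cds_pos),
                "A" if genome.base("chr1", cds_pos) != "A" else "C"),
        ]
        result = sg.annotate_all(variants, [model], genome)
        assert len(result.effects) == 2
        assert sorted(result.primary.values()) == ["cds", "intergenic"]
        # primary categories partition the variant set
        assert len(result.primary) == len(variants)

    def test_cds_beats_intron_for_primary(self):
        rng = np.random.default_rng(9)
        genome, model = build_gene(random_cds(rng, 40), "+", rng=rng, flank=60)
        hull = GeneModel(
            locus_id="G2", chromosome="chr1", strand="+",
            span=(1, len(genome.chromosomes["chr1"])),
            exons=[(1, 10)], cds_segments=[],
        )
        pos = model.cds_segments[0][0]
        ref = genome.base("chr1", pos)
        result = sg.annotate_all(
            [snp("chr1", pos, ref, "A" if ref != "A" else "C")],
            [model, hull], genome,
        )
        assert len(result.effects) == 2
        assert list(result.primary.values()) == ["cds"]

    def test_empty_variant_list(self):
        rng = np.random.default_rng(9)
        genome, model = build_gene(random_cds(rng, 40), "+", rng=rng)
        result = sg.annotate_all([], [model], genome)
        assert result.effects == [] and result.primary == {}

    def test_syn_plus_nonsyn_equals_cds_count(self):
        """Per-locus CDS arithmetic: synonymous + non-synonymous = CDS SNPs."""
        rng = np.random.default_rng(21)
        genome, model = build_gene(random_cds(rng, 80), "-", rng=rng)
        variants = []
        for start, end in model.cds_segments:
            for pos in range(start, end + 1, 7):
                ref = genome.base("chr1", pos)
                variants.append(snp("chr1", pos, ref, "A" if ref != "A" else "C"))
        result = sg.annotate_all(variants, [model], genome)
        (summary,) = sg.summarize_genes(result.effects)
        assert summary.synonymous + summary.ka == summary.cds == len(variants)
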