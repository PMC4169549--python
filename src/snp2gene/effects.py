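"""Variant-to-gene functional classification at codon resolution.

Each SNP is located against the gene models (intergenic, intron/non-coding,
5'UTR, 3'UTR or CDS, one record per overlapping locus) and, inside a CDS,
classified by codon substitution: the CDS segments are spliced in genomic
order, reverse-complemented for minus-strand genes, the affected codon is
substituted with the single alternate base and both codons are translated
with the standard nuclear genetic code. Consequences follow the usual
accounting in which stop-gained ("isSNP", a sense codon turned into a stop)
and stop-lost ("psSNP", a stop turned into a sense codon) are counted inside
the non-synonymous total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table
from intervaltree import IntervalTree

from .models import (
    GeneModel,
    ReferenceGenome,
    ReferenceMismatchError,
    REGION_PRECEDENCE,
    SnpEffect,
    VariantCall,
)

__all__ = [
    "CODON_TABLE",
    "translate_cds",
    "LocusIndex",
    "build_interval_index",
    "locate_variant",
    "spliced_cds",
    "codon_effect",
    "AnnotationResult",
    "annotate_all",
]

# Standard nuclear genetic code, stops as '*'.
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(seq: str) -> str:
    """Translate a nucleotide sequence codon by codon ('X' for ambiguity)."""
    return "".join(
        CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


class LocusIndex:
    """Sub-linear (chromosome, position) -> overlapping gene models lookup."""

    def __init__(self, models: Iterable[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        self.models: dict[str, GeneModel] = {}
        for m in models:
            if m.locus_id in self.models:
                raise ValueError(f"duplicate locus id {m.locus_id}")
            self.models[m.locus_id] = m
            tree = self._trees.setdefault(m.chromosome, IntervalTree())
            # intervaltree uses half-open ends
            tree.addi(m.span[0], m.span[1] + 1, m.locus_id)

    def overlapping(self, chromosome: str, position: int) -> list[GeneModel]:
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.at(position))
        return [self.models[locus] for locus in hits]


def build_interval_index(models: Iterable[GeneModel]) -> LocusIndex:
    return LocusIndex(models)


def _region_within(model: GeneModel, position: int) -> str:
    for kind, segments in (
        ("cds", model.cds_segments),
        ("utr5", model.utr5_segments),
        ("utr3", model.utr3_segments),
    ):
        for start, end in segments:
            if start <= position <= end:
                return kind
    return "intron_noncoding"


def locate_variant(
    variant: VariantCall, index: LocusIndex, genome: ReferenceGenome | None = None
) -> list[tuple[str | None, str]]:
    """Region category per overlapping locus; ``[(None, 'intergenic')]`` when none."""
    if genome is not None:
        length = len(genome.chromosomes.get(variant.chromosome, ""))
        if variant.position > length:
            raise IndexError(
                f"{variant.chromosome}:{variant.position} beyond chromosome length {length}"
            )
    models = index.overlapping(variant.chromosome, variant.position)
    if not models:
        return [(None, "intergenic")]
    return [(m.locus_id, _region_within(m, variant.position)) for m in models]


def spliced_cds(model: GeneModel, genome: ReferenceGenome) -> str:
    """CDS sequence in coding orientation (reverse-complemented on '-')."""
    seq = genome.chromosomes[model.chromosome]
    spliced = "".join(seq[s - 1 : e] for s, e in model.cds_segments)
    return reverse_complement(spliced) if model.strand == "-" else spliced


def _coding_offset(model: GeneModel, position: int) -> int | None:
    """0-based offset of a genomic position within the coding sequence."""
    plus_offset = 0
    found = None
    for start, end in model.cds_segments:
        if start <= position <= end:
            found = plus_offset + (position - start)
            break
        plus_offset += end - start + 1
    if found is None:
        return None
    if model.strand == "-":
        return model.cds_length - 1 - found
    return found


def cds_offset_to_genomic(model: GeneModel, offset: int) -> int:
    """Genomic 1-based position of a 0-based coding-sequence offset."""
    if not 0 <= offset < model.cds_length:
        raise IndexError(f"CDS offset {offset} outside [0, {model.cds_length})")
    plus_offset = model.cds_length - 1 - offset if model.strand == "-" else offset
    for start, end in model.cds_segments:
        seg_len = end - start + 1
        if plus_offset < seg_len:
            return start + plus_offset
        plus_offset -= seg_len
    raise AssertionError("unreachable")


def codon_effect(
    variant: VariantCall, model: GeneModel, genome: ReferenceGenome
) -> SnpEffect | None:
    """Codon-level consequence of a SNP inside a model's CDS.

    Returns None when the variant falls in a trailing partial codon of an
    out-of-frame CDS annotation (complete codons still annotate). Raises
    :class:`ReferenceMismatchError` when the genome base disagrees with the
    variant's stated reference allele.
    """
    genome_base = genome.base(variant.chromosome, variant.position)
    if genome_base != variant.ref:
        raise ReferenceMismatchError(
            f"{variant.chromosome}:{variant.position} genome has {genome_base}, "
            f"variant states {variant.ref}"
        )
    offset = _coding_offset(model, variant.position)
    if offset is None:
        raise ValueError(
            f"{variant.chromosome}:{variant.position} not in CDS of {model.locus_id}"
        )
    cds = spliced_cds(model, genome)
    codon_idx = offset // 3
    codon_pos = offset % 3
    if 3 * codon_idx + 3 > len(cds):
        return None  # trailing partial codon of an out-of-frame CDS

    ref_codon = cds[3 * codon_idx : 3 * codon_idx + 3]
    alt_base = variant.alt if model.strand == "+" else reverse_complement(variant.alt)
    alt_codon = ref_codon[:codon_pos] + alt_base + ref_codon[codon_pos + 1 :]
    ref_aa = CODON_TABLE.get(ref_codon, "X")
    alt_aa = CODON_TABLE.get(alt_codon, "X")

    if ref_aa == alt_aa:
        consequence = "synonymous"
    elif alt_aa == "*":
        consequence = "stop_gained"
    elif ref_aa == "*":
        consequence = "stop_lost"
    else:
        consequence = "missense"

    return SnpEffect(
        chromosome=variant.chromosome,
        position=variant.position,
        ref=variant.ref,
        alt=variant.alt,
        locus_id=model.locus_id,
        region="cds",
        consequence=consequence,
        codon_index=codon_idx + 1,
        codon_position=codon_pos + 1,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
    )


@dataclass
class AnnotationResult:
    """Per-locus effect records plus a per-variant primary category.

    ``primary`` maps each variant key to a single genome-wide category
    chosen by precedence cds > utr5 > utr3 > intron_noncoding > intergenic
    across the variant's overlapping loci.
    """

    effects: list[SnpEffect] = field(default_factory=list)
    primary: dict[tuple, str] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def primary_effect(self, key: tuple) -> SnpEffect:
        """The effect record realising a variant's primary category
        (smallest locus id on ties)."""
        region = self.primary[key]
        candidates = [
            e for e in self.effects if e.variant_key == key and e.region == region
        ]
        return min(candidates, key=lambda e: e.locus_id or "")


def annotate_all(
    variants: Sequence[VariantCall],
    models: Iterable[GeneModel] | LocusIndex,
    genome: ReferenceGenome,
) -> AnnotationResult:
    """Classify every SNP call against all overlapping loci.

    Each variant yields one record per overlapping locus (or a single
    intergenic record) and one primary category. SNPs in the CDS of a
    locus whose annotation is out of frame only in its trailing partial
    codon still classify; truly unclassifiable CDS sites are logged.
    """
    index = models if isinstance(models, LocusIndex) else build_interval_index(models)
    result = AnnotationResult()
    for variant in variants:
        if variant.var_type != "SNP":
            continue
        records: list[SnpEffect] = []
        for locus_id, region in locate_variant(variant, index, genome):
            if region == "cds":
                model = index.models[locus_id]
                if not model.cds_in_frame:
                    result.skipped.append(
                        f"{locus_id}: CDS length {model.cds_length} not divisible by 3"
                    )
                effect = codon_effect(variant, model, genome)
                if effect is None:
                    result.skipped.append(
                        f"{variant.chromosome}:{variant.position} in partial codon "
                        f"of {locus_id}; located only"
                    )
                    effect = SnpEffect(
                        chromosome=variant.chromosome,
                        position=variant.position,
                        ref=variant.ref,
                        alt=variant.alt,
                        locus_id=locus_id,
                        region="intron_noncoding",
                    )
                records.append(effect)
            else:
                records.append(
                    SnpEffect(
                        chromosome=variant.chromosome,
                        position=variant.position,
                        ref=variant.ref,
                        alt=variant.alt,
                        locus_id=locus_id,
                        region=region,
                    )
                )
        result.effects.extend(records)
        regions = {r.region for r in records}
        for region in REGION_PRECEDENCE:
            if region in regions:
                result.primary[variant.key] = region
                break
    return result
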