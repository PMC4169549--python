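"""Shared fixtures: tiny hand-built genes and a fast simulated study."""

from __future__ import annotations

import numpy as np
import pytest

from snp2gene import GeneModel, ReferenceGenome
from snp2gene.effects import CODON_TABLE, reverse_complement

SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
STOP_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa == "*")


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + sense codons + one terminal stop."""
    body = "".join(rng.choice(SENSE_CODONS, n_codons - 2))
    return "ATG" + body + str(rng.choice(STOP_CODONS))


def build_gene(
    cds_seq: str,
    strand: str = "+",
    locus_id: str = "G1",
    chromosome: str = "chr1",
    flank: int = 30,
    intron_lengths: tuple[int, ...] = (),
    rng: np.random.Generator | None = None,
) -> tuple[ReferenceGenome, GeneModel]:
    """Embed a coding sequence in a chromosome as a (possibly multi-exon)
    gene, returning the genome and its model. ``intron_lengths`` splits the
    CDS into len+1 roughly equal exons."""
    rng = rng or np.random.default_rng(0)
    rand = lambda n: "".join(rng.choice(list("ACGT"), n))

    n_seg = len(intron_lengths) + 1
    seg_len = len(cds_seq) // n_seg
    cuts = [seg_len * i for i in range(1, n_seg)] + [len(cds_seq)]
    pieces, start = [], 0
    for cut in cuts:
        pieces.append(cds_seq[start:cut])
        start = cut

    gene_parts, cds_local, cursor = [], [], 0
    for i, piece in enumerate(pieces):
        cds_local.append((cursor, cursor + len(piece) - 1))
        gene_parts.append(piece)
        cursor += len(piece)
        if i < len(intron_lengths):
            gene_parts.append(rand(intron_lengths[i]))
            cursor += intron_lengths[i]
    gene_seq = "".join(gene_parts)

    if strand == "-":
        lg = len(gene_seq)
        gene_seq = reverse_complement(gene_seq)
        cds_local = sorted((lg - 1 - b, lg - 1 - a) for a, b in cds_local)

    offset = flank + 1
    chrom_seq = rand(flank) + gene_seq + rand(flank)
    cds = [(a + offset, b + offset) for a, b in cds_local]
    model = GeneModel(
        locus_id=locus_id,
        chromosome=chromosome,
        strand=strand,
        span=(offset, offset + len(gene_seq) - 1),
        exons=cds,
        cds_segments=cds,
    )
    return ReferenceGenome({chromosome: chrom_seq}), model


@pytest.fixture(scope="session")
def small_study():
    """A fast end-to-end simulated study (2 x 60 kb, ~12 genes)."""
    from snp2gene.simulate import SimulationConfig, generate_genome, plant_variants

    config = SimulationConfig(seed=7, n_chromosomes=2, chromosome_length=60_000)
    genome, models = generate_genome(config)
    truth = plant_variants(genome, models, config)
    return config, genome, models, truth
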