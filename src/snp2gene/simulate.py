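"""Synthetic genomes, planted variant truth sets and noisy pileups.

The simulator emulates, at desk scale, a resequencing comparison of two
inbred genomes: a multi-chromosome reference with strand-mixed multi-exon
genes, a truth set of categorised SNPs/InDels planted per region (the
"sample" alleles), and per-site read pileups at configurable depth,
sequencing-error rate and heterozygosity. Every CDS plant's intended
consequence is verified at planting time by full-CDS retranslation, so the
truth set is sound by construction and downstream recovery tests compare
against it directly.

All randomness flows from one explicit seed through per-stage child
streams (genome, planting, pileup), so each stage is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .effects import (
    CODON_TABLE,
    cds_offset_to_genomic,
    reverse_complement,
    spliced_cds,
    translate_cds,
)
from .models import (
    GeneModel,
    Interval,
    Observation,
    PileupColumn,
    ReferenceGenome,
)

__all__ = [
    "SimulationConfig",
    "PlantedVariant",
    "TruthSet",
    "generate_genome",
    "plant_variants",
    "simulate_pileup",
]

_SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
_STOP_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa == "*")
_BASES = "ACGT"

SNP_CATEGORIES = (
    "intergenic",
    "intron",
    "utr5",
    "utr3",
    "cds_synonymous",
    "cds_missense",
    "stop_gained",
    "stop_lost",
)


def _default_snp_rates() -> dict[str, float]:
    # per-kb of each category's own territory; chosen to yield an overall
    # genic/intergenic mix of a few SNPs per kb on a 2 x 250 kb genome
    return {
        "intergenic": 3.0,
        "intron": 3.0,
        "utr5": 3.0,
        "utr3": 3.0,
        "cds_synonymous": 2.5,
        "cds_missense": 3.5,
        "stop_gained": 0.3,
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Rates are per kb of the relevant territory (so ``cds_synonymous`` is
    per kb of CDS). ``stop_lost_per_gene`` is a per-gene probability since
    each gene exposes exactly one stop codon. ``het_fraction`` marks that
    fraction of planted variants heterozygous. Background (non-variant)
    pileup columns are emitted at ``background_sites_per_kb``.
    """

    seed: int
    n_chromosomes: int = 2
    chromosome_length: int = 250_000
    gene_density: float = 0.1  # genes per kb
    exons_per_gene: tuple[int, int] = (2, 5)
    minus_strand_fraction: float = 0.5
    snp_rate_per_kb: dict[str, float] = field(default_factory=_default_snp_rates)
    stop_lost_per_gene: float = 0.1
    indel_rate_per_kb: float = 0.3
    depth: int = 20
    error_rate: float = 0.0
    het_fraction: float = 0.0
    background_sites_per_kb: float = 20.0
    low_quality_fraction: float = 0.02
    unique_fraction: float = 0.98

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory; no implicit randomness")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        for k, v in self.snp_rate_per_kb.items():
            if v < 0:
                raise ValueError(f"rate {k} must be >= 0")
        for name in ("error_rate", "het_fraction", "minus_strand_fraction",
                     "low_quality_fraction", "unique_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    def rng(self, stage: int) -> np.random.Generator:
        """Per-stage child stream: 0 genome, 1 planting, 2 pileup."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(3)[stage]
        )


@dataclass(frozen=True)
class PlantedVariant:
    chromosome: str
    position: int
    ref: str
    alt: str
    var_type: str  # SNP | INS | DEL
    category: str  # region (or region_consequence for CDS plants)
    consequence: str  # synonymous | missense | stop_gained | stop_lost | none
    zygosity: str  # homozygous | heterozygous
    locus_id: str | None
    indel_evidence: str | None = None  # "+SEQ" / "-SEQ" as seen in reads

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref, self.alt)


@dataclass
class TruthSet:
    variants: list[PlantedVariant]

    @property
    def homozygous(self) -> list[PlantedVariant]:
        return [v for v in self.variants if v.zygosity == "homozygous"]

    @property
    def heterozygous(self) -> list[PlantedVariant]:
        return [v for v in self.variants if v.zygosity == "heterozygous"]

    def snps(self, zygosity: str | None = None) -> list[PlantedVariant]:
        return [
            v for v in self.variants
            if v.var_type == "SNP" and (zygosity is None or v.zygosity == zygosity)
        ]

    def category_counts(self, zygosity: str | None = None) -> dict[str, int]:
        counts: dict[str, int] = {}
        for v in self.snps(zygosity):
            counts[v.category] = counts.get(v.category, 0) + 1
        return counts

    def per_locus_counts(self, zygosity: str | None = None) -> dict[str, int]:
        counts: dict[str, int] = {}
        for v in self.snps(zygosity):
            if v.locus_id is not None:
                counts[v.locus_id] = counts.get(v.locus_id, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# genome generation

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, n)])


def _split_lengths(rng: np.random.Generator, total: int, parts: int, minimum: int) -> list[int]:
    """Partition ``total`` into ``parts`` lengths each >= minimum."""
    spare = total - minimum * parts
    if spare < 0:
        raise ValueError("total too small to split")
    if parts == 1:
        return [total]
    cuts = np.sort(rng.integers(0, spare + 1, parts - 1))
    pieces = np.diff(np.concatenate(([0], cuts, [spare])))
    return [minimum + int(p) for p in pieces]


def _make_gene(
    rng: np.random.Generator, locus_id: str, chromosome: str, strand: str,
    n_exons_range: tuple[int, int],
) -> tuple[str, dict[str, list[Interval]]]:
    """Build one gene; returns its genomic-plus-strand sequence and 0-based
    local intervals for exons/CDS/UTRs (already strand-adjusted)."""
    n_codons = int(rng.integers(100, 301))  # incl. terminal stop codon
    cds_seq = (
        "ATG"
        + "".join(rng.choice(_SENSE_CODONS, n_codons - 2))
        + str(rng.choice(_STOP_CODONS))
    )
    u5 = int(rng.integers(100, 301))
    u3 = int(rng.integers(100, 301))
    transcript = _random_seq(rng, u5) + cds_seq + _random_seq(rng, u3)
    lt = len(transcript)

    n_exons = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
    exon_lengths = _split_lengths(rng, lt, n_exons, 50)
    intron_lengths = [int(rng.integers(100, 401)) for _ in range(n_exons - 1)]

    # assemble genomic sequence in transcript orientation, recording exon
    # local intervals and the transcript offset each exon starts at
    seq_parts: list[str] = []
    exons: list[Interval] = []
    exon_toffsets: list[int] = []
    gpos = tpos = 0
    for i, elen in enumerate(exon_lengths):
        seq_parts.append(transcript[tpos : tpos + elen])
        exons.append((gpos, gpos + elen - 1))
        exon_toffsets.append(tpos)
        gpos += elen
        tpos += elen
        if i < n_exons - 1:
            seq_parts.append(_random_seq(rng, intron_lengths[i]))
            gpos += intron_lengths[i]
    gene_seq = "".join(seq_parts)
    lg = len(gene_seq)

    def map_range(t0: int, t1: int) -> list[Interval]:
        """Transcript range [t0, t1] -> local genomic intervals."""
        out = []
        for (g0, g1), toff in zip(exons, exon_toffsets):
            e0, e1 = toff, toff + (g1 - g0)
            lo, hi = max(t0, e0), min(t1, e1)
            if lo <= hi:
                out.append((g0 + lo - e0, g0 + hi - e0))
        return out

    segments = {
        "exon": list(exons),
        "cds": map_range(u5, u5 + len(cds_seq) - 1),
        "utr5": map_range(0, u5 - 1),
        "utr3": map_range(u5 + len(cds_seq), lt - 1),
    }
    if strand == "-":
        gene_seq = reverse_complement(gene_seq)
        segments = {
            kind: sorted((lg - 1 - b, lg - 1 - a) for a, b in ivs)
            for kind, ivs in segments.items()
        }
    return gene_seq, segments


def generate_genome(config: SimulationConfig) -> tuple[ReferenceGenome, list[GeneModel]]:
    """Random genome with non-overlapping multi-exon genes on both strands.

    Every CDS starts with ATG, carries no internal in-frame stop and ends
    with exactly one terminal stop codon; CDS length is divisible by 3.
    """
    rng = config.rng(0)
    chromosomes: dict[str, str] = {}
    models: list[GeneModel] = []
    gene_no = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        length = config.chromosome_length
        n_genes = int(round(config.gene_density * length / 1000))
        genes: list[tuple[str, dict[str, list[Interval]], str]] = []
        for _ in range(n_genes):
            gene_no += 1
            locus_id = f"SYN{gene_no:05d}"
            strand = "-" if rng.random() < config.minus_strand_fraction else "+"
            seq, segs = _make_gene(rng, locus_id, chrom, strand, config.exons_per_gene)
            genes.append((locus_id, segs, strand, seq))
        total_gene_len = sum(len(g[3]) for g in genes)
        spare = length - total_gene_len
        min_gap = 200
        if spare < min_gap * (n_genes + 1):
            raise ValueError(
                f"gene density too high: {total_gene_len} gene bases in "
                f"{length} bp chromosome leaves no room for gaps"
            )
        gaps = _split_lengths(rng, spare, n_genes + 1, min_gap)
        parts: list[str] = []
        cursor = 0
        for (locus_id, segs, strand, seq), gap in zip(genes, gaps):
            parts.append(_random_seq(rng, gap))
            cursor += gap
            offset = cursor + 1  # local 0-based -> genomic 1-based
            parts.append(seq)
            models.append(
                GeneModel(
                    locus_id=locus_id,
                    chromosome=chrom,
                    strand=strand,
                    span=(offset, offset + len(seq) - 1),
                    exons=[(a + offset, b + offset) for a, b in segs["exon"]],
                    cds_segments=[(a + offset, b + offset) for a, b in segs["cds"]],
                    utr5_segments=[(a + offset, b + offset) for a, b in segs["utr5"]],
                    utr3_segments=[(a + offset, b + offset) for a, b in segs["utr3"]],
                )
            )
            cursor += len(seq)
        parts.append(_random_seq(rng, gaps[-1]))
        chromosomes[chrom] = "".join(parts)
    genome = ReferenceGenome(chromosomes)
    for m in models:
        protein = translate_cds(spliced_cds(m, genome))
        assert protein[0] == "M" and protein[-1] == "*" and "*" not in protein[:-1]
    return genome, models


# ---------------------------------------------------------------------------
# variant planting

def _sample_positions(
    rng: np.random.Generator, intervals: list[Interval], n: int, used: set[int]
) -> list[int]:
    """n distinct positions drawn uniformly from intervals, avoiding used."""
    pool = np.concatenate(
        [np.arange(a, b + 1) for a, b in intervals]
    ) if intervals else np.array([], dtype=int)
    pool = pool[~np.isin(pool, list(used))] if used else pool
    if len(pool) < n:
        raise ValueError(f"cannot place {n} variants in {len(pool)} available bases")
    chosen = rng.choice(pool, size=n, replace=False)
    return [int(p) for p in np.sort(chosen)]


def _classify_codon_change(ref_codon: str, alt_codon: str) -> str:
    ref_aa, alt_aa = CODON_TABLE[ref_codon], CODON_TABLE[alt_codon]
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "stop_gained"
    if ref_aa == "*":
        return "stop_lost"
    return "missense"


def _verify_cds_plant(
    model: GeneModel, genome: ReferenceGenome, position: int, alt: str, consequence: str
) -> None:
    """Full-CDS retranslation check of a planted coding variant."""
    cds = spliced_cds(model, genome)
    from .effects import _coding_offset  # shared coordinate arithmetic

    offset = _coding_offset(model, position)
    alt_coding = alt if model.strand == "+" else reverse_complement(alt)
    mutated = cds[:offset] + alt_coding + cds[offset + 1 :]
    ref_protein, alt_protein = translate_cds(cds), translate_cds(mutated)
    idx = offset // 3
    diffs = [i for i, (a, b) in enumerate(zip(ref_protein, alt_protein)) if a != b]
    if consequence == "synonymous":
        assert ref_protein == alt_protein
    else:
        assert diffs == [idx], f"expected single change at residue {idx}, got {diffs}"
        if consequence == "stop_gained":
            assert alt_protein[idx] == "*" and ref_protein[idx] != "*"
        elif consequence == "stop_lost":
            assert ref_protein[idx] == "*" and alt_protein[idx] != "*"


def _plant_cds_variant(
    rng: np.random.Generator,
    model: GeneModel,
    genome: ReferenceGenome,
    cds: str,
    desired: str,
    used: set[tuple[str, int]],
    max_tries: int = 2000,
) -> PlantedVariant | None:
    n_codons = len(cds) // 3
    for _ in range(max_tries):
        if desired == "stop_lost":
            codon_idx = n_codons - 1  # the single terminal stop
        else:
            codon_idx = int(rng.integers(0, n_codons - 1))  # sense codons only
        pos_in_codon = int(rng.integers(0, 3))
        offset = 3 * codon_idx + pos_in_codon
        ref_codon = cds[3 * codon_idx : 3 * codon_idx + 3]
        alt_base = _BASES[int(rng.integers(0, 4))]
        if alt_base == cds[offset]:
            continue
        alt_codon = ref_codon[:pos_in_codon] + alt_base + ref_codon[pos_in_codon + 1 :]
        if _classify_codon_change(ref_codon, alt_codon) != desired:
            continue
        position = cds_offset_to_genomic(model, offset)
        if (model.chromosome, position) in used:
            continue
        ref = genome.base(model.chromosome, position)
        alt = alt_base if model.strand == "+" else reverse_complement(alt_base)
        _verify_cds_plant(model, genome, position, alt, desired)
        used.add((model.chromosome, position))
        category = desired if desired in ("stop_gained", "stop_lost") else f"cds_{desired}"
        return PlantedVariant(
            chromosome=model.chromosome,
            position=position,
            ref=ref,
            alt=alt,
            var_type="SNP",
            category=category,
            consequence=desired,
            zygosity="homozygous",
            locus_id=model.locus_id,
        )
    return None


def plant_variants(
    genome: ReferenceGenome, models: list[GeneModel], config: SimulationConfig
) -> TruthSet:
    """Plant categorised SNPs and InDels; counts follow the configured
    per-kb rates over each category's territory (rounded, so achieved
    density tracks the configured rate closely)."""
    rng = config.rng(1)
    rates = config.snp_rate_per_kb
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chromosome, []).append(m)

    used: set[tuple[str, int]] = set()
    variants: list[PlantedVariant] = []

    def plant_noncoding(category: str, chrom: str, intervals: list[Interval],
                        locus_of: dict[int, str] | None, n: int) -> None:
        used_here = {p for c, p in used if c == chrom}
        for pos in _sample_positions(rng, intervals, n, used_here):
            ref = genome.base(chrom, pos)
            alt = str(rng.choice([b for b in _BASES if b != ref]))
            used.add((chrom, pos))
            variants.append(
                PlantedVariant(
                    chromosome=chrom, position=pos, ref=ref, alt=alt,
                    var_type="SNP", category=category, consequence="none",
                    zygosity="homozygous",
                    locus_id=locus_of.get(pos) if locus_of else None,
                )
            )

    from .formats import subtract_intervals

    for chrom, seq in genome.chromosomes.items():
        chrom_models = by_chrom.get(chrom, [])
        spans = sorted(m.span for m in chrom_models)
        intergenic = subtract_intervals([(1, len(seq))], spans)

        territory: dict[str, list[Interval]] = {"intron": [], "utr5": [], "utr3": []}
        locus_of: dict[str, dict[int, str]] = {k: {} for k in territory}
        for m in chrom_models:
            introns = subtract_intervals([m.span], m.exons)
            for kind, ivs in (("intron", introns), ("utr5", m.utr5_segments),
                              ("utr3", m.utr3_segments)):
                territory[kind].extend(ivs)
                for a, b in ivs:
                    for p in range(a, b + 1):
                        locus_of[kind][p] = m.locus_id

        def kb(ivs: list[Interval]) -> float:
            return sum(b - a + 1 for a, b in ivs) / 1000.0

        plant_noncoding("intergenic", chrom, intergenic, None,
                        int(round(rates.get("intergenic", 0) * kb(intergenic))))
        for kind in ("intron", "utr5", "utr3"):
            ivs = sorted(territory[kind])
            plant_noncoding(kind, chrom, ivs, locus_of[kind],
                            int(round(rates.get(kind, 0) * kb(ivs))))

        # coding plants, apportioned per gene by CDS length
        for m in chrom_models:
            cds = spliced_cds(m, genome)
            cds_kb = len(cds) / 1000.0
            for desired, rate_key in (
                ("synonymous", "cds_synonymous"),
                ("missense", "cds_missense"),
                ("stop_gained", "stop_gained"),
            ):
                n = _stochastic_round(rng, rates.get(rate_key, 0) * cds_kb)
                for _ in range(n):
                    v = _plant_cds_variant(rng, m, genome, cds, desired, used)
                    if v is not None:
                        variants.append(v)
            if rng.random() < config.stop_lost_per_gene:
                v = _plant_cds_variant(rng, m, genome, cds, "stop_lost", used)
                if v is not None:
                    variants.append(v)

        # InDels anywhere (region recorded for bookkeeping, not consequence)
        n_indels = int(round(config.indel_rate_per_kb * len(seq) / 1000.0))
        used_here = {p for c, p in used if c == chrom}
        safe = [(1, len(seq) - 10)]
        for pos in _sample_positions(rng, safe, n_indels, used_here):
            size = int(rng.integers(1, 4))
            ref_base = genome.base(chrom, pos)
            if rng.random() < 0.5:
                ins = _random_seq(rng, size)
                v = PlantedVariant(
                    chromosome=chrom, position=pos, ref=ref_base,
                    alt=ref_base + ins, var_type="INS",
                    category=_region_of(chrom_models, pos), consequence="none",
                    zygosity="homozygous", locus_id=None,
                    indel_evidence=f"+{ins}",
                )
            else:
                deleted = seq[pos : pos + size]
                v = PlantedVariant(
                    chromosome=chrom, position=pos, ref=ref_base + deleted,
                    alt=ref_base, var_type="DEL",
                    category=_region_of(chrom_models, pos), consequence="none",
                    zygosity="homozygous", locus_id=None,
                    indel_evidence=f"-{deleted}",
                )
            used.add((chrom, pos))
            variants.append(v)

    # heterozygous marking
    if config.het_fraction > 0:
        flags = rng.random(len(variants)) < config.het_fraction
        import dataclasses

        variants = [
            dataclasses.replace(v, zygosity="heterozygous") if flag else v
            for v, flag in zip(variants, flags)
        ]

    variants.sort(key=lambda v: (v.chromosome, v.position))
    return TruthSet(variants=variants)


def _stochastic_round(rng: np.random.Generator, x: float) -> int:
    """Round x to an integer, sending the fraction up with its probability
    (keeps low per-gene expected counts unbiased)."""
    base = int(np.floor(x))
    return base + (1 if rng.random() < x - base else 0)


def _region_of(models: list[GeneModel], position: int) -> str:
    for m in models:
        if m.contains(position):
            for kind, segs in (("cds", m.cds_segments), ("utr5", m.utr5_segments),
                               ("utr3", m.utr3_segments)):
                if any(a <= position <= b for a, b in segs):
                    return kind
            return "intron"
    return "intergenic"


# ---------------------------------------------------------------------------
# pileup simulation

def simulate_pileup(
    genome: ReferenceGenome, truth: TruthSet, config: SimulationConfig
) -> Iterator[PileupColumn]:
    """Yield sorted pileup columns at every planted site plus background
    (non-variant) sites at the configured density.

    Homozygous planted sites emit the alternate allele on every non-error
    read. Heterozygous sites draw the alternate-read count from a binomial
    at 0.5, resampled until both alleles hold at least 30% of the depth, so
    every planted het is unambiguously heterozygous at the configured
    depth whatever the seed. Correct bases draw qualities in [25, 40] with
    a low-quality tail below the masking cutoff; error bases substitute a
    random other base.
    """
    rng = config.rng(2)
    planted: dict[tuple[str, int], PlantedVariant] = {
        (v.chromosome, v.position): v for v in truth.variants
    }
    for chrom, seq in genome.chromosomes.items():
        n_bg = int(round(config.background_sites_per_kb * len(seq) / 1000.0))
        taken = {p for c, p in planted if c == chrom}
        bg = _sample_positions(rng, [(1, len(seq))], n_bg, taken)
        positions = sorted(set(bg) | taken)
        for pos in positions:
            ref = seq[pos - 1]
            variant = planted.get((chrom, pos))
            yield _simulate_column(rng, config, chrom, pos, ref, variant)


def _draw_quality(rng: np.random.Generator, config: SimulationConfig) -> int:
    if rng.random() < config.low_quality_fraction:
        return int(rng.integers(0, 5))
    return int(rng.integers(25, 41))


def _simulate_column(
    rng: np.random.Generator,
    config: SimulationConfig,
    chrom: str,
    pos: int,
    ref: str,
    variant: PlantedVariant | None,
) -> PileupColumn:
    depth = config.depth
    if variant is None:
        intended = [ref] * depth
        evidence = [None] * depth
    elif variant.var_type == "SNP":
        allele = variant.alt
        if variant.zygosity == "homozygous":
            n_alt = depth
        else:
            n_alt = _balanced_binomial(rng, depth)
        intended = [allele] * n_alt + [ref] * (depth - n_alt)
        evidence = [None] * depth
    else:  # indel: reads span the site (base = ref) and carry evidence
        if variant.zygosity == "homozygous":
            n_alt = depth
        else:
            n_alt = _balanced_binomial(rng, depth)
        intended = [ref] * depth
        evidence = [variant.indel_evidence] * n_alt + [None] * (depth - n_alt)

    order = rng.permutation(depth)
    observations = []
    for i in order:
        base = intended[i]
        if rng.random() < config.error_rate:
            base = str(rng.choice([b for b in _BASES if b != base]))
            quality = int(rng.integers(6, 26))
        else:
            quality = _draw_quality(rng, config)
        unique = bool(rng.random() < config.unique_fraction)
        observations.append(Observation(base, quality, unique, evidence[i]))
    return PileupColumn(chrom, pos, ref, observations)


def _balanced_binomial(rng: np.random.Generator, depth: int) -> int:
    """Binomial(depth, 0.5) conditioned on both alleles holding >= 30%."""
    lo = int(np.ceil(0.3 * depth))
    hi = depth - lo
    if lo > hi:
        return depth // 2
    while True:
        n = int(rng.binomial(depth, 0.5))
        if lo <= n <= hi:
            return n
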