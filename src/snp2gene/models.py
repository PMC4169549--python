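"""Domain containers shared across the toolkit.

Coordinates are 1-based inclusive throughout (GFF3/VCF native); intervals
are ``(start, end)`` tuples with ``start <= end``. No half-open coordinates
are exposed anywhere in the public API.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

VALID_BASES = frozenset("ACGTN")
CALL_BASES = frozenset("ACGT")

Interval = tuple[int, int]


class Snp2GeneError(Exception):
    """Base class for toolkit errors."""


class FormatError(Snp2GeneError):
    """Malformed input file; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ReferenceMismatchError(Snp2GeneError):
    """A variant's stated reference base disagrees with the genome."""


def _check_intervals(name: str, intervals: list[Interval], span: Interval) -> None:
    prev_end = None
    for start, end in intervals:
        if start > end:
            raise ValueError(f"{name} interval ({start}, {end}) has start > end")
        if start < span[0] or end > span[1]:
            raise ValueError(f"{name} interval ({start}, {end}) outside span {span}")
        if prev_end is not None and start <= prev_end:
            raise ValueError(f"{name} intervals unsorted or overlapping at ({start}, {end})")
        prev_end = end


def interval_length(intervals: list[Interval]) -> int:
    return sum(end - start + 1 for start, end in intervals)


@dataclass
class ReferenceGenome:
    """Named chromosome sequences, upper-cased, alphabet A/C/G/T/N."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for chrom, seq in self.chromosomes.items():
            if chrom in seen:
                raise ValueError(f"duplicate chromosome id {chrom!r}")
            seen.add(chrom)
            if not seq:
                raise ValueError(f"chromosome {chrom!r} has empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {chrom!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def base(self, chrom: str, position: int) -> str:
        """Reference base at a 1-based position."""
        seq = self.chromosomes[chrom]
        if not 1 <= position <= len(seq):
            raise IndexError(f"position {position} outside {chrom} (length {len(seq)})")
        return seq[position - 1]


@dataclass
class GeneModel:
    """A stranded multi-exon gene locus with CDS and UTR segments.

    UTR roles (5'/3') are in transcript orientation: on the minus strand the
    5' UTR lies at higher genomic coordinates than the CDS.
    """

    locus_id: str
    chromosome: str
    strand: str
    span: Interval
    exons: list[Interval]
    cds_segments: list[Interval]
    utr5_segments: list[Interval] = field(default_factory=list)
    utr3_segments: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        _check_intervals("exon", self.exons, self.span)
        _check_intervals("CDS", self.cds_segments, self.span)
        _check_intervals("5'UTR", self.utr5_segments, self.span)
        _check_intervals("3'UTR", self.utr3_segments, self.span)
        exon_bases = self._base_set(self.exons)
        cds_bases = self._base_set(self.cds_segments)
        if not cds_bases <= exon_bases:
            raise ValueError(f"{self.locus_id}: CDS segments extend outside exons")
        if self.cds_segments and self.cds_length < 3:
            raise ValueError(f"{self.locus_id}: total CDS length {self.cds_length} < 3")

    @staticmethod
    def _base_set(intervals: list[Interval]) -> set[int]:
        bases: set[int] = set()
        for start, end in intervals:
            bases.update(range(start, end + 1))
        return bases

    @property
    def cds_length(self) -> int:
        return interval_length(self.cds_segments)

    @property
    def cds_in_frame(self) -> bool:
        """True when the total CDS length is divisible by 3."""
        return self.cds_length % 3 == 0

    def contains(self, position: int) -> bool:
        return self.span[0] <= position <= self.span[1]


@dataclass
class LabelTable:
    """Mapping of locus id to one or more labels (gene family, TF family, GO term)."""

    namespace: str
    labels_by_locus: dict[str, set[str]]

    @property
    def loci_by_label(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for locus, labels in self.labels_by_locus.items():
            for label in labels:
                out.setdefault(label, set()).add(locus)
        return out

    def unmatched(self, known_loci: set[str]) -> set[str]:
        """Locus ids present in the table but absent from an annotation."""
        return set(self.labels_by_locus) - known_loci


class Observation(NamedTuple):
    """One read's evidence at a pileup column."""

    base: str
    quality: int
    unique: bool
    indel: str | None = None  # "+SEQ" insertion after site, "-SEQ" deletion


@dataclass
class PileupColumn:
    chromosome: str
    position: int
    ref_base: str
    observations: list[Observation]

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise FormatError(f"position {self.position} must be positive")
        if self.ref_base not in VALID_BASES:
            raise FormatError(f"invalid reference base {self.ref_base!r}")
        for obs in self.observations:
            if not 0 <= obs.quality <= 40:
                raise FormatError(f"quality {obs.quality} outside [0, 40]")
            if obs.base not in CALL_BASES:
                raise FormatError(f"invalid observed base {obs.base!r}")

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class VariantCall:
    """A consensus variant call with its supporting evidence summary."""

    chromosome: str
    position: int
    ref: str
    alt: str
    var_type: str  # SNP | INS | DEL
    support: int
    concordance: float
    quality: int
    zygosity: str  # homozygous | heterozygous

    def __post_init__(self) -> None:
        if self.var_type not in {"SNP", "INS", "DEL"}:
            raise ValueError(f"bad var_type {self.var_type!r}")
        if self.var_type == "SNP":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ValueError(
                    f"SNP must have distinct single-base alleles, got {self.ref}>{self.alt}"
                )
        if self.zygosity not in {"homozygous", "heterozygous"}:
            raise ValueError(f"bad zygosity {self.zygosity!r}")
        # fixed precision so VCF serialisation round-trips exactly
        object.__setattr__(self, "concordance", round(self.concordance, 6))

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref, self.alt)


# Region categories, ordered by annotation precedence (most informative first).
REGION_PRECEDENCE = ("cds", "utr5", "utr3", "intron_noncoding", "intergenic")

CONSEQUENCES = ("synonymous", "missense", "stop_gained", "stop_lost", "none")

# Field-standard aliases used in output tables.
CONSEQUENCE_LABELS = {
    "synonymous": "synonymous",
    "missense": "missense",
    "stop_gained": "stop_gained(isSNP)",
    "stop_lost": "stop_lost(psSNP)",
    "none": "none",
}


@dataclass(frozen=True)
class SnpEffect:
    """Classification of one variant against one locus (or intergenic)."""

    chromosome: str
    position: int
    ref: str
    alt: str
    locus_id: str | None
    region: str
    consequence: str = "none"
    codon_index: int | None = None  # 1-based codon number within the CDS
    codon_position: int | None = None  # 1..3 within the codon
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None

    def __post_init__(self) -> None:
        if self.region not in REGION_PRECEDENCE:
            raise ValueError(f"bad region {self.region!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"bad consequence {self.consequence!r}")
        if (self.consequence != "none") != (self.region == "cds"):
            raise ValueError("coding consequence iff region is cds")
        if self.consequence == "stop_gained" and not (
            self.alt_aa == "*" and self.ref_aa != "*"
        ):
            raise ValueError("stop_gained requires alt_aa '*' and ref_aa sense")
        if self.consequence == "stop_lost" and not (
            self.ref_aa == "*" and self.alt_aa != "*"
        ):
            raise ValueError("stop_lost requires ref_aa '*' and alt_aa sense")
        if self.consequence == "synonymous" and self.ref_aa != self.alt_aa:
            raise ValueError("synonymous requires ref_aa == alt_aa")

    @property
    def variant_key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref, self.alt)

    @property
    def is_nonsynonymous(self) -> bool:
        """Stop-affecting changes count inside the non-synonymous total."""
        return self.consequence in {"missense", "stop_gained", "stop_lost"}


@dataclass
class GeneSnpSummary:
    """Per-locus SNP tallies with raw-count Ka/Ks."""

    locus_id: str
    utr5: int = 0
    utr3: int = 0
    intron: int = 0
    cds: int = 0
    synonymous: int = 0
    missense: int = 0
    stop_gained: int = 0
    stop_lost: int = 0

    @property
    def total_snps(self) -> int:
        return self.utr5 + self.utr3 + self.intron + self.cds

    @property
    def ka(self) -> int:
        return self.missense + self.stop_gained + self.stop_lost

    @property
    def ks(self) -> int:
        return self.synonymous

    @property
    def ka_ks(self) -> float | None:
        """Ka/Ks as a ratio of substitution counts; undefined when Ks = 0."""
        if self.ks == 0:
            return None
        return self.ka / self.ks


@dataclass
class ChromosomeSummary:
    """One row of the per-chromosome distribution table.

    ``intergenic_noncoding`` merges intergenic with intronic/non-coding sites;
    the two are also reported separately so either convention can be read off.
    """

    chromosome: str
    total_snps: int
    insertions: int
    deletions: int
    intergenic_noncoding: int
    utr3: int
    utr5: int
    cds: int
    synonymous: int
    non_synonymous: int
    snp_per_kb: float | None = None
    intergenic_only: int | None = None
    intron_noncoding_only: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "total_snps", "insertions", "deletions", "intergenic_noncoding",
            "utr3", "utr5", "cds", "synonymous", "non_synonymous",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))
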