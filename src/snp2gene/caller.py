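"""Threshold-based homozygous consensus calling from pileup columns.

The caller applies, per site: base-quality masking, majority scoring,
zygosity classification and threshold filtering. A homozygous SNP is
emitted only when the majority base differs from the reference and the
site passes concordance (>= 0.80 of surviving reads on the majority base),
support (>= 3 unique-mapping reads carrying it) and quality (strictly
> 25 on a 0-40 scale). Sites classified heterozygous (minority fraction
>= 0.25) are diverted to a side channel and never enter the homozygous
output. InDels are called from exact-match indel evidence strings under
the same support/concordance thresholds.

The 0-40 site quality is computed as
``round(40 * concordance * min(1, support / min_support))``: it preserves
the scale and strict-cutoff semantics of upstream quality scores while
remaining computable from pileup evidence alone. The chastity cutoff
(Illumina cluster purity, 0.5-1.0) acts at base-calling time upstream of
any pileup and is retained only as a pass-through configuration field.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple

from .models import PileupColumn, VariantCall

__all__ = [
    "CallerConfig",
    "HetSite",
    "SkippedSite",
    "SiteDecision",
    "mask_bases",
    "score_column",
    "classify_zygosity",
    "call_site",
    "call_indels",
    "call_genome",
]


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds governing consensus calling.

    min_concordance   minimum fraction of reads on the majority base (>=)
    min_support       minimum unique-mapping reads carrying the call (>=)
    min_quality       0-40 score cutoff, strict (call requires quality > this)
    het_minority      minority-read fraction at or above which a site is
                      classified heterozygous
    base_mask_quality observations below this quality are masked out
    chastity_cutoff   upstream cluster-purity cutoff; pass-through only
    """

    min_concordance: float = 0.80
    min_support: int = 3
    min_quality: int = 25
    het_minority: float = 0.25
    base_mask_quality: int = 5
    chastity_cutoff: float = 0.5

    def __post_init__(self) -> None:
        for name in ("min_concordance", "het_minority"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.5 <= self.chastity_cutoff <= 1.0:
            raise ValueError("chastity_cutoff must be in [0.5, 1.0]")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


class HetSite(NamedTuple):
    """A site diverted to the heterozygous side channel."""

    chromosome: str
    position: int
    ref_base: str
    majority_base: str
    minority_fraction: float


class SkippedSite(NamedTuple):
    chromosome: str
    position: int
    reason: str


class SiteDecision(NamedTuple):
    call: VariantCall | None
    het: HetSite | None
    skipped: SkippedSite | None


def mask_bases(column: PileupColumn, config: CallerConfig = CallerConfig()) -> PileupColumn:
    """Drop observations below the base-masking quality; depth is recomputed."""
    kept = [o for o in column.observations if o.quality >= config.base_mask_quality]
    if len(kept) == len(column.observations):
        return column
    return replace(column, observations=kept)


def score_column(
    column: PileupColumn, config: CallerConfig = CallerConfig()
) -> tuple[str, int, float, int] | None:
    """Majority base with its support, concordance and 0-40 quality.

    Returns None on a tied majority (no consensus; such sites take the
    heterozygous path) or on zero depth. Support counts only unique-mapping
    reads carrying the majority base; concordance is computed over all
    surviving observations.
    """
    if column.depth == 0:
        return None
    counts = Counter(o.base for o in column.observations)
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None  # tie: no majority
    majority, majority_count = ranked[0]
    support = sum(
        1 for o in column.observations if o.base == majority and o.unique
    )
    concordance = majority_count / column.depth
    quality = _site_quality(concordance, support, config)
    return majority, support, concordance, quality


def _site_quality(concordance: float, support: int, config: CallerConfig) -> int:
    q = round(40 * concordance * min(1.0, support / config.min_support))
    return max(0, min(40, int(q)))


def classify_zygosity(
    column: PileupColumn, config: CallerConfig = CallerConfig()
) -> str:
    """Heterozygous iff the minority-read fraction reaches ``het_minority``.

    Tied majorities are heterozygous by construction (minority fraction 0.5).
    """
    if column.depth == 0:
        raise ValueError("cannot classify zygosity with no observations")
    counts = Counter(o.base for o in column.observations)
    majority_count = counts.most_common(1)[0][1]
    minority_fraction = (column.depth - majority_count) / column.depth
    return "heterozygous" if minority_fraction >= config.het_minority else "homozygous"


def call_site(column: PileupColumn, config: CallerConfig = CallerConfig()) -> SiteDecision:
    """Decide one (masked) column: homozygous SNP call, het record, or skip."""
    chrom, pos = column.chromosome, column.position
    if column.ref_base == "N":
        return SiteDecision(None, None, SkippedSite(chrom, pos, "reference base N"))
    if column.depth == 0:
        return SiteDecision(None, None, SkippedSite(chrom, pos, "no surviving observations"))

    counts = Counter(o.base for o in column.observations)
    scored = score_column(column, config)
    if scored is None:
        # tied majority: heterozygous by the tie rule
        top = counts.most_common(1)[0][0]
        return SiteDecision(None, HetSite(chrom, pos, column.ref_base, top, 0.5), None)
    majority, support, concordance, quality = scored

    if classify_zygosity(column, config) == "heterozygous":
        minority_fraction = (column.depth - counts[majority]) / column.depth
        return SiteDecision(
            None, HetSite(chrom, pos, column.ref_base, majority, minority_fraction), None
        )
    if majority == column.ref_base:
        return SiteDecision(None, None, None)
    if (
        concordance >= config.min_concordance
        and support >= config.min_support
        and quality > config.min_quality
    ):
        call = VariantCall(
            chromosome=chrom,
            position=pos,
            ref=column.ref_base,
            alt=majority,
            var_type="SNP",
            support=support,
            concordance=concordance,
            quality=quality,
            zygosity="homozygous",
        )
        return SiteDecision(call, None, None)
    return SiteDecision(None, None, None)


def call_indels(
    columns: Iterable[PileupColumn], config: CallerConfig = CallerConfig()
) -> list[VariantCall]:
    """Call insertions/deletions from exact-match indel evidence.

    At each site, identical indel strings observed on >= min_support
    unique-mapping reads and constituting >= min_concordance of all reads at
    the site (indel-bearing plus reference-spanning) yield one INS/DEL call.
    At most one indel can satisfy a concordance threshold above 0.5.
    """
    calls: list[VariantCall] = []
    for column in columns:
        column = mask_bases(column, config)
        if column.depth == 0 or column.ref_base == "N":
            continue
        evidence = Counter(o.indel for o in column.observations if o.indel)
        if not evidence:
            continue
        for indel, count in evidence.most_common():
            unique_count = sum(
                1 for o in column.observations if o.indel == indel and o.unique
            )
            concordance = count / column.depth
            if unique_count < config.min_support or concordance < config.min_concordance:
                continue
            quality = _site_quality(concordance, unique_count, config)
            if quality <= config.min_quality:
                continue
            seq = indel[1:]
            if indel[0] == "+":
                ref, alt, var_type = column.ref_base, column.ref_base + seq, "INS"
            else:
                ref, alt, var_type = column.ref_base + seq, column.ref_base, "DEL"
            calls.append(
                VariantCall(
                    chromosome=column.chromosome,
                    position=column.position,
                    ref=ref,
                    alt=alt,
                    var_type=var_type,
                    support=unique_count,
                    concordance=concordance,
                    quality=quality,
                    zygosity="homozygous",
                )
            )
            break  # only one indel can pass the concordance threshold
    return calls


def call_genome(
    columns: Iterable[PileupColumn], config: CallerConfig = CallerConfig()
) -> tuple[list[VariantCall], list[HetSite], list[SkippedSite]]:
    """Stream mask -> score -> classify -> call over a sorted pileup.

    Input must be sorted by chromosome then position (a chromosome may not
    reappear after another starts). Returns homozygous calls (SNPs and
    InDels, coordinate order), the heterozygous side channel, and the
    skipped-site log.
    """
    calls: list[VariantCall] = []
    hets: list[HetSite] = []
    skipped: list[SkippedSite] = []
    indel_columns: list[PileupColumn] = []

    seen_chroms: list[str] = []
    last_pos: int | None = None
    for column in columns:
        if not seen_chroms or column.chromosome != seen_chroms[-1]:
            if column.chromosome in seen_chroms:
                raise ValueError(
                    f"unsorted pileup: chromosome {column.chromosome} reappears"
                )
            seen_chroms.append(column.chromosome)
            last_pos = None
        if last_pos is not None and column.position <= last_pos:
            raise ValueError(
                f"unsorted pileup at {column.chromosome}:{column.position}"
            )
        last_pos = column.position

        masked = mask_bases(column, config)
        decision = call_site(masked, config)
        if decision.call:
            calls.append(decision.call)
        if decision.het:
            hets.append(decision.het)
        if decision.skipped:
            skipped.append(decision.skipped)
        if any(o.indel for o in masked.observations):
            indel_columns.append(masked)

    calls.extend(call_indels(indel_columns, config))
    calls.sort(key=lambda c: (seen_chroms.index(c.chromosome), c.position, c.var_type))
    return calls, hets, skipped
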