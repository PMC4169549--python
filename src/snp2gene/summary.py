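"""Aggregation of annotated variants into gene- and genome-level tables.

Covers per-locus summaries with raw-count Ka/Ks (Ka = non-synonymous
substitution count including stop-affecting changes, Ks = synonymous
count; their ratio is a selection signature, > 1 suggesting positive
selection), hotspot detection (loci with strictly more than 100 SNPs),
SNP-range binning, the per-chromosome distribution table, genome SNP/kb
density, genic-fraction arithmetic and label-table (gene family /
transcription factor / GO term) roll-ups.

Percentages are rounded to the nearest whole percent and densities to one
decimal, matching the reporting conventions of the tables these summaries
mirror.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .effects import AnnotationResult
from .models import (
    ChromosomeSummary,
    GeneSnpSummary,
    LabelTable,
    SnpEffect,
    VariantCall,
    round_half_up,
)

__all__ = [
    "summarize_genes",
    "detect_hotspots",
    "SNP_RANGE_BINS",
    "bin_gene_counts",
    "chromosome_table",
    "summaries_to_frame",
    "chromosome_rows_to_frame",
    "genome_density",
    "share_percent",
    "GenicFractionStats",
    "genic_fraction_stats",
    "LabelSummary",
    "label_table_summary",
    "validate_printed_totals",
    "nei_gojobori_sites",
    "ka_ks_normalized",
]


def summarize_genes(effects: Iterable[SnpEffect]) -> list[GeneSnpSummary]:
    """One summary per locus carrying at least one effect record."""
    by_locus: dict[str, GeneSnpSummary] = {}
    for e in effects:
        if e.locus_id is None:
            continue
        s = by_locus.setdefault(e.locus_id, GeneSnpSummary(locus_id=e.locus_id))
        if e.region == "utr5":
            s.utr5 += 1
        elif e.region == "utr3":
            s.utr3 += 1
        elif e.region == "intron_noncoding":
            s.intron += 1
        elif e.region == "cds":
            s.cds += 1
            if e.consequence == "synonymous":
                s.synonymous += 1
            elif e.consequence == "missense":
                s.missense += 1
            elif e.consequence == "stop_gained":
                s.stop_gained += 1
            elif e.consequence == "stop_lost":
                s.stop_lost += 1
    return sorted(by_locus.values(), key=lambda s: s.locus_id)


def detect_hotspots(
    summaries: Iterable[GeneSnpSummary], threshold: int = 100
) -> list[GeneSnpSummary]:
    """Loci with strictly more than ``threshold`` SNPs, most variable first."""
    hot = [s for s in summaries if s.total_snps > threshold]
    return sorted(hot, key=lambda s: (-s.total_snps, s.locus_id))


# Range bins over per-gene SNP counts: 1-5, 6-10, ..., 96-100, >100.
SNP_RANGE_BINS: list[str] = [f"{lo}–{lo + 4}" for lo in range(1, 100, 5)] + [">100"]


def bin_gene_counts(summaries: Iterable[GeneSnpSummary]) -> dict[str, int]:
    """Number of SNP-carrying genes in each SNP-count range bin."""
    counts = dict.fromkeys(SNP_RANGE_BINS, 0)
    for s in summaries:
        n = s.total_snps
        if n <= 0:
            continue
        counts[">100" if n > 100 else SNP_RANGE_BINS[(n - 1) // 5]] += 1
    return counts


def _chromosome_order(chroms: Iterable[str]) -> list[str]:
    seen: list[str] = []
    for c in chroms:
        if c not in seen:
            seen.append(c)
    return seen


def chromosome_table(
    annotation: AnnotationResult,
    indel_calls: Sequence[VariantCall] = (),
    covered_kb: Mapping[str, float] | None = None,
) -> tuple[list[ChromosomeSummary], ChromosomeSummary]:
    """Per-chromosome distribution rows plus a totals row computed by summation.

    SNPs are counted once each through their primary category; the
    ``intergenic_noncoding`` column merges intergenic with intron/non-coding
    (the separate tallies are kept in ``intergenic_only`` and
    ``intron_noncoding_only``). Synonymous/non-synonymous counts come from
    the primary CDS record of each CDS-primary variant. SNP/kb density is
    filled where per-chromosome covered kb is supplied and positive.
    """
    chroms = _chromosome_order(
        [k[0] for k in annotation.primary] + [c.chromosome for c in indel_calls]
    )
    zero = lambda: {
        "total_snps": 0, "insertions": 0, "deletions": 0, "intergenic": 0,
        "intron": 0, "utr3": 0, "utr5": 0, "cds": 0, "syn": 0, "nonsyn": 0,
    }
    acc = {c: zero() for c in chroms}
    for key, region in annotation.primary.items():
        row = acc[key[0]]
        row["total_snps"] += 1
        if region == "intergenic":
            row["intergenic"] += 1
        elif region == "intron_noncoding":
            row["intron"] += 1
        elif region == "utr3":
            row["utr3"] += 1
        elif region == "utr5":
            row["utr5"] += 1
        else:
            row["cds"] += 1
            effect = annotation.primary_effect(key)
            if effect.consequence == "synonymous":
                row["syn"] += 1
            else:
                row["nonsyn"] += 1
    for call in indel_calls:
        if call.var_type == "INS":
            acc[call.chromosome]["insertions"] += 1
        elif call.var_type == "DEL":
            acc[call.chromosome]["deletions"] += 1

    rows: list[ChromosomeSummary] = []
    for chrom in chroms:
        a = acc[chrom]
        density = None
        if covered_kb and covered_kb.get(chrom, 0) > 0:
            density = genome_density(a["total_snps"], covered_kb[chrom])
        rows.append(
            ChromosomeSummary(
                chromosome=chrom,
                total_snps=a["total_snps"],
                insertions=a["insertions"],
                deletions=a["deletions"],
                intergenic_noncoding=a["intergenic"] + a["intron"],
                utr3=a["utr3"],
                utr5=a["utr5"],
                cds=a["cds"],
                synonymous=a["syn"],
                non_synonymous=a["nonsyn"],
                snp_per_kb=density,
                intergenic_only=a["intergenic"],
                intron_noncoding_only=a["intron"],
            )
        )
    return rows, totals_row(rows, covered_kb)


_SUM_FIELDS = (
    "total_snps", "insertions", "deletions", "intergenic_noncoding",
    "utr3", "utr5", "cds", "synonymous", "non_synonymous",
)


def totals_row(
    rows: Sequence[ChromosomeSummary],
    covered_kb: Mapping[str, float] | None = None,
) -> ChromosomeSummary:
    """Column sums of a per-chromosome table (always computed, never copied)."""
    sums = {f: sum(getattr(r, f) for r in rows) for f in _SUM_FIELDS}
    density = None
    if covered_kb:
        total_kb = sum(covered_kb.get(r.chromosome, 0) for r in rows)
        if total_kb > 0:
            density = genome_density(sums["total_snps"], total_kb)
    return ChromosomeSummary(chromosome="total", snp_per_kb=density, **sums)


def validate_printed_totals(
    rows: Sequence[ChromosomeSummary], printed: Mapping[str, int]
) -> dict[str, tuple[int, int]]:
    """Compare computed column sums against an externally printed totals row.

    Returns ``{column: (computed, printed)}`` for every column that
    disagrees — useful for flagging internally inconsistent published tables.
    """
    computed = totals_row(rows)
    return {
        f: (getattr(computed, f), printed[f])
        for f in _SUM_FIELDS
        if f in printed and getattr(computed, f) != printed[f]
    }


def genome_density(total_snps: int, covered_kb: float) -> float:
    """SNPs per covered kb, rounded to one decimal."""
    if covered_kb <= 0:
        raise ValueError("covered_kb must be positive")
    return round(total_snps / covered_kb, 1)


def share_percent(part: float, whole: float) -> int:
    """100 * part / whole, rounded half-up to the nearest whole percent."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round_half_up(100.0 * part / whole)


@dataclass(frozen=True)
class GenicFractionStats:
    genic_snps: int
    genome_total: int
    genic_percent: int
    top_k: int
    top_snps: int
    top_share_percent: int
    hotspot_snps: int
    hotspot_share_percent: int


def genic_fraction_stats(
    summaries: Sequence[GeneSnpSummary],
    genome_total: int,
    top_fraction: float = 0.33,
    hotspot_threshold: int = 100,
) -> GenicFractionStats:
    """How concentrated genic variation is.

    genic%  = genic SNPs / genome-wide SNPs; top-share% = share of genic
    SNPs held by the top ``top_fraction`` of SNP-carrying genes ranked by
    count (ties at the cut broken by locus id); hotspot-share% = share of
    genic SNPs in hotspot loci.
    """
    if genome_total <= 0:
        raise ValueError("genome_total must be positive")
    carriers = sorted(
        (s for s in summaries if s.total_snps > 0),
        key=lambda s: (-s.total_snps, s.locus_id),
    )
    genic = sum(s.total_snps for s in carriers)
    if genome_total < genic:
        raise ValueError("genome_total smaller than genic SNP total")
    k = round_half_up(top_fraction * len(carriers))
    top_snps = sum(s.total_snps for s in carriers[:k])
    hotspot_snps = sum(
        s.total_snps for s in carriers if s.total_snps > hotspot_threshold
    )
    return GenicFractionStats(
        genic_snps=genic,
        genome_total=genome_total,
        genic_percent=share_percent(genic, genome_total),
        top_k=k,
        top_snps=top_snps,
        top_share_percent=share_percent(top_snps, genic) if genic else 0,
        hotspot_snps=hotspot_snps,
        hotspot_share_percent=share_percent(hotspot_snps, genic) if genic else 0,
    )


@dataclass(frozen=True)
class LabelSummary:
    label: str
    members: int
    members_with_snps: int
    total_snps: int
    synonymous: int
    non_synonymous: int


def label_table_summary(
    summaries: Sequence[GeneSnpSummary], label_table: LabelTable
) -> list[LabelSummary]:
    """Roll per-locus summaries up to label rows (families, TFs, GO terms).

    Member loci without any SNP count as zero-SNP members, so a row of
    zeros marks a fully conserved family. A locus carrying several labels
    contributes to every one of its rows.
    """
    if not label_table.labels_by_locus:
        warnings.warn("empty label table", stacklevel=2)
        return []
    by_locus = {s.locus_id: s for s in summaries}
    rows: list[LabelSummary] = []
    for label, loci in sorted(label_table.loci_by_label.items()):
        present = [by_locus[l] for l in loci if l in by_locus]
        rows.append(
            LabelSummary(
                label=label,
                members=len(loci),
                members_with_snps=sum(1 for s in present if s.total_snps > 0),
                total_snps=sum(s.total_snps for s in present),
                synonymous=sum(s.synonymous for s in present),
                non_synonymous=sum(s.ka for s in present),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# optional site-normalised Ka/Ks (Nei–Gojobori-style site counting)

def nei_gojobori_sites(cds: str) -> tuple[float, float]:
    """(non-synonymous sites, synonymous sites) of a coding sequence.

    Each codon position contributes the fraction of its three possible
    single-base changes that are synonymous to the synonymous-site count,
    and the complement to the non-synonymous count. Stop codons and
    codons with ambiguity are skipped.
    """
    from .effects import CODON_TABLE

    n_sites = s_sites = 0.0
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        aa = CODON_TABLE.get(codon)
        if aa is None or aa == "*":
            continue
        for pos in range(3):
            syn = 0
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                mutant = codon[:pos] + base + codon[pos + 1 :]
                if CODON_TABLE.get(mutant) == aa:
                    syn += 1
            s_sites += syn / 3.0
            n_sites += 1.0 - syn / 3.0
    return n_sites, s_sites


def ka_ks_normalized(summary: GeneSnpSummary, cds: str) -> float | None:
    """Per-site Ka/Ks: substitution counts divided by site counts.

    This is NOT the raw-count ratio used in the main tables; it is offered
    for users who expect per-site rates. Undefined when the per-site Ks
    is zero.
    """
    n_sites, s_sites = nei_gojobori_sites(cds)
    if n_sites == 0 or s_sites == 0 or summary.ks == 0:
        return None
    ka = summary.ka / n_sites
    ks = summary.ks / s_sites
    return ka / ks


# ---------------------------------------------------------------------------
# DataFrame views (for TSV export and inspection)

def summaries_to_frame(summaries: Sequence[GeneSnpSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_id": [s.locus_id for s in summaries],
            "utr5": [s.utr5 for s in summaries],
            "utr3": [s.utr3 for s in summaries],
            "intron": [s.intron for s in summaries],
            "cds": [s.cds for s in summaries],
            "synonymous": [s.synonymous for s in summaries],
            "missense": [s.missense for s in summaries],
            "stop_gained": [s.stop_gained for s in summaries],
            "stop_lost": [s.stop_lost for s in summaries],
            "total_snps": [s.total_snps for s in summaries],
            "Ka": [s.ka for s in summaries],
            "Ks": [s.ks for s in summaries],
            "Ka_Ks": [s.ka_ks for s in summaries],
        }
    )


def chromosome_rows_to_frame(
    rows: Sequence[ChromosomeSummary], totals: ChromosomeSummary | None = None
) -> pd.DataFrame:
    all_rows = list(rows) + ([totals] if totals is not None else [])
    return pd.DataFrame(
        {
            "chromosome": [r.chromosome for r in all_rows],
            "total_snps": [r.total_snps for r in all_rows],
            "insertions": [r.insertions for r in all_rows],
            "deletions": [r.deletions for r in all_rows],
            "intergenic_noncoding": [r.intergenic_noncoding for r in all_rows],
            "utr3": [r.utr3 for r in all_rows],
            "utr5": [r.utr5 for r in all_rows],
            "cds": [r.cds for r in all_rows],
            "synonymous": [r.synonymous for r in all_rows],
            "non_synonymous": [r.non_synonymous for r in all_rows],
            "snp_per_kb": [r.snp_per_kb for r in all_rows],
        }
    )
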