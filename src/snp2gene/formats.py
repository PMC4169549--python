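"""Readers and writers for the on-disk formats the toolkit consumes and emits.

Formats
-------
FASTA          reference genomes (alphabet A/C/G/T/N, upper-cased on load)
GFF3           gene models (gene/mRNA/exon/CDS, optional explicit UTRs)
pileup TSV     a documented mpileup-inspired dialect, defined below
VCF 4.2        consensus variant calls (written and read back losslessly)
effects TSV    one row per (variant, locus) classification
label TSV      locus-id -> label membership tables (families, TFs, GO terms)

Pileup dialect
--------------
Tab-separated columns: chromosome, position (1-based), reference base, and
a comma-separated observation list. Each observation is ``BASE:QUAL:FLAG``
with an optional fourth ``:+SEQ`` / ``:-SEQ`` field recording insertion or
deletion evidence immediately after the site. FLAG is ``u`` for a
unique-mapping ("non-repetitive") read, ``r`` otherwise. A column with no
observations writes ``.`` in the fourth field.
"""

from __future__ import annotations

import importlib.resources
import warnings
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gffutils
import pysam

from .models import (
    CALL_BASES,
    VALID_BASES,
    ChromosomeSummary,
    FormatError,
    GeneModel,
    Interval,
    LabelTable,
    Observation,
    PileupColumn,
    ReferenceGenome,
    SnpEffect,
    VariantCall,
    CONSEQUENCE_LABELS,
    interval_length,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_pileup",
    "write_pileup",
    "read_vcf",
    "write_vcf",
    "write_effects_tsv",
    "read_label_table",
    "load_table2_fixture",
    "TABLE2_PRINTED_TOTALS",
]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> ReferenceGenome:
    """Load a FASTA file into a :class:`ReferenceGenome`.

    Record ids are the first whitespace-delimited token of each header.
    Sequences are upper-cased; characters outside A/C/G/T/N are rejected
    with the offending line number.
    """
    chromosomes: dict[str, str] = {}
    name: str | None = None
    parts: list[str] = []
    header_line = 0

    def flush() -> None:
        if name is None:
            return
        seq = "".join(parts)
        if not seq:
            raise FormatError(f"record {name!r} has an empty sequence", header_line)
        if name in chromosomes:
            raise FormatError(f"duplicate record id {name!r}", header_line)
        chromosomes[name] = seq

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                tokens = line[1:].split()
                if not tokens:
                    raise FormatError("empty FASTA header", lineno)
                name, parts, header_line = tokens[0], [], lineno
            else:
                if name is None:
                    raise FormatError("sequence data before any header", lineno)
                seq = line.upper()
                bad = set(seq) - VALID_BASES
                if bad:
                    raise FormatError(
                        f"invalid sequence characters {sorted(bad)}", lineno
                    )
                parts.append(seq)
    flush()
    if not chromosomes:
        raise FormatError("no FASTA records found")
    return ReferenceGenome(chromosomes)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.chromosomes.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# interval helpers

def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def subtract_intervals(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Base-set difference a \\ b, both sorted non-overlapping."""
    out: list[Interval] = []
    for start, end in a:
        cur = start
        for bs, be in b:
            if be < cur or bs > end:
                continue
            if bs > cur:
                out.append((cur, bs - 1))
            cur = max(cur, be + 1)
            if cur > end:
                break
        if cur <= end:
            out.append((cur, end))
    return out


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse GFF3 gene models.

    One :class:`GeneModel` per gene. When a gene carries several mRNAs the
    representative transcript is the one with the longest total CDS (ties
    broken by lexicographically smallest transcript id). UTR segments are
    taken from explicit five_prime_UTR / three_prime_UTR features when
    present, otherwise derived as exon-minus-CDS split by strand.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    for cds in db.features_of_type("CDS"):
        if not any(db.parents(cds.id, featuretype="mRNA")):
            raise FormatError(f"CDS feature {cds.id!r} has no parent mRNA")

    models: list[GeneModel] = []
    genes = list(db.features_of_type("gene"))
    if not genes:
        warnings.warn(f"{path}: no gene features found", stacklevel=2)
        return []
    for gene in genes:
        mrnas = list(db.children(gene.id, featuretype="mRNA"))
        if not mrnas:
            warnings.warn(f"gene {gene.id} has no mRNA; skipped", stacklevel=2)
            continue

        def cds_total(mrna) -> int:
            return sum(
                f.end - f.start + 1 for f in db.children(mrna.id, featuretype="CDS")
            )

        rep = min(mrnas, key=lambda m: (-cds_total(m), m.id))
        exons = merge_intervals(
            (f.start, f.end) for f in db.children(rep.id, featuretype="exon")
        )
        cds = merge_intervals(
            (f.start, f.end) for f in db.children(rep.id, featuretype="CDS")
        )
        utr5 = merge_intervals(
            (f.start, f.end)
            for f in db.children(rep.id, featuretype="five_prime_UTR")
        )
        utr3 = merge_intervals(
            (f.start, f.end)
            for f in db.children(rep.id, featuretype="three_prime_UTR")
        )
        if not utr5 and not utr3 and cds:
            utr5, utr3 = derive_utrs(exons, cds, gene.strand)
        models.append(
            GeneModel(
                locus_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                span=(gene.start, gene.end),
                exons=exons,
                cds_segments=cds,
                utr5_segments=utr5,
                utr3_segments=utr3,
            )
        )
    return models


def derive_utrs(
    exons: list[Interval], cds: list[Interval], strand: str
) -> tuple[list[Interval], list[Interval]]:
    """Exon-minus-CDS, split at the CDS genomic extent into UTR roles."""
    noncoding = subtract_intervals(exons, cds)
    cds_start, cds_end = cds[0][0], cds[-1][1]
    left = [iv for iv in noncoding if iv[1] < cds_start]
    right = [iv for iv in noncoding if iv[0] > cds_end]
    if strand == "+":
        return left, right
    return right, left


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Serialise gene models as GFF3 (one mRNA per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            tid = f"{m.locus_id}.1"
            row = "\t".join
            fh.write(row([
                m.chromosome, "snp2gene", "gene", str(m.span[0]), str(m.span[1]),
                ".", m.strand, ".", f"ID={m.locus_id}",
            ]) + "\n")
            fh.write(row([
                m.chromosome, "snp2gene", "mRNA", str(m.span[0]), str(m.span[1]),
                ".", m.strand, ".", f"ID={tid};Parent={m.locus_id}",
            ]) + "\n")
            for kind, ivs in (
                ("exon", m.exons),
                ("CDS", m.cds_segments),
                ("five_prime_UTR", m.utr5_segments),
                ("three_prime_UTR", m.utr3_segments),
            ):
                phase = "0" if kind == "CDS" else "."
                for start, end in ivs:
                    fh.write(row([
                        m.chromosome, "snp2gene", kind, str(start), str(end),
                        ".", m.strand, phase, f"Parent={tid}",
                    ]) + "\n")


# ---------------------------------------------------------------------------
# pileup TSV

def read_pileup(path: str | Path) -> Iterator[PileupColumn]:
    """Stream pileup columns in file order (see module docstring for dialect)."""
    with open(path) as fh:
        empty = True
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            empty = False
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"expected 4 tab-separated fields, got {len(fields)}", lineno)
            chrom, pos_s, ref, obs_s = fields
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"bad position {pos_s!r}", lineno) from None
            if pos <= 0:
                raise FormatError(f"position {pos} must be positive", lineno)
            observations: list[Observation] = []
            if obs_s != ".":
                for entry in obs_s.split(","):
                    parts = entry.split(":")
                    if len(parts) not in (3, 4):
                        raise FormatError(f"bad observation {entry!r}", lineno)
                    base, qual_s, flag = parts[:3]
                    indel = parts[3] if len(parts) == 4 else None
                    try:
                        qual = int(qual_s)
                    except ValueError:
                        raise FormatError(f"bad quality {qual_s!r}", lineno) from None
                    if not 0 <= qual <= 40:
                        raise FormatError(f"quality {qual} outside [0, 40]", lineno)
                    if base not in CALL_BASES:
                        raise FormatError(f"bad observed base {base!r}", lineno)
                    if flag not in ("u", "r"):
                        raise FormatError(f"bad mapping flag {flag!r}", lineno)
                    if indel is not None and (
                        len(indel) < 2 or indel[0] not in "+-"
                        or not set(indel[1:]) <= CALL_BASES
                    ):
                        raise FormatError(f"bad indel evidence {indel!r}", lineno)
                    observations.append(Observation(base, qual, flag == "u", indel))
            try:
                yield PileupColumn(chrom, pos, ref, observations)
            except FormatError as exc:
                raise FormatError(str(exc), lineno) from None
        if empty:
            warnings.warn(f"{path}: empty pileup", stacklevel=2)


def write_pileup(columns: Iterable[PileupColumn], path: str | Path) -> None:
    with open(path, "w") as fh:
        for col in columns:
            if col.observations:
                obs_s = ",".join(
                    f"{o.base}:{o.quality}:{'u' if o.unique else 'r'}"
                    + (f":{o.indel}" if o.indel else "")
                    for o in col.observations
                )
            else:
                obs_s = "."
            fh.write(f"{col.chromosome}\t{col.position}\t{col.ref_base}\t{obs_s}\n")


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=VT,Number=1,Type=String,Description="Variant type: SNP, INS or DEL">',
    '##INFO=<ID=SUP,Number=1,Type=Integer,Description="Unique-mapping reads supporting the call">',
    '##INFO=<ID=CONC,Number=1,Type=Float,Description="Fraction of reads carrying the called allele">',
    '##INFO=<ID=ZY,Number=1,Type=String,Description="Zygosity of the call">',
]


def write_vcf(calls: Iterable[VariantCall], path: str | Path) -> None:
    """Write site-only (GT-free) VCF 4.2 records, QUAL carrying the 0-40 score."""
    calls = list(calls)
    contigs: list[str] = []
    for c in calls:
        if c.chromosome not in contigs:
            contigs.append(c.chromosome)
    with open(path, "w") as fh:
        for line in _VCF_HEADER:
            fh.write(line + "\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = (
                f"VT={c.var_type};SUP={c.support};"
                f"CONC={c.concordance:.6f};ZY={c.zygosity}"
            )
            fh.write(
                f"{c.chromosome}\t{c.position}\t.\t{c.ref}\t{c.alt}\t"
                f"{c.quality}\tPASS\t{info}\n"
            )


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Read calls written by :func:`write_vcf`; round-trips the call list exactly."""
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            calls.append(
                VariantCall(
                    chromosome=rec.chrom,
                    position=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    var_type=rec.info["VT"],
                    support=int(rec.info["SUP"]),
                    concordance=float(rec.info["CONC"]),
                    quality=int(round(rec.qual)),
                    zygosity=rec.info["ZY"],
                )
            )
    return calls


# ---------------------------------------------------------------------------
# effects / labels / fixture tables

EFFECTS_COLUMNS = [
    "chromosome", "position", "ref", "alt", "locus_id", "region",
    "consequence", "codon_index", "codon_position", "ref_codon",
    "alt_codon", "ref_aa", "alt_aa", "primary",
]


def write_effects_tsv(
    effects: Iterable[SnpEffect],
    path: str | Path,
    primary: Mapping[tuple, str] | None = None,
) -> None:
    """One row per (variant, locus); consequence column uses the field labels
    ``stop_gained(isSNP)`` / ``stop_lost(psSNP)``. When a primary-category
    map is given, the row matching the variant's primary category is flagged.
    """
    def cell(v) -> str:
        return "." if v is None else str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(EFFECTS_COLUMNS) + "\n")
        for e in effects:
            is_primary = ""
            if primary is not None:
                is_primary = "yes" if primary.get(e.variant_key) == e.region else "no"
            fh.write("\t".join([
                e.chromosome, str(e.position), e.ref, e.alt, cell(e.locus_id),
                e.region, CONSEQUENCE_LABELS[e.consequence], cell(e.codon_index),
                cell(e.codon_position), cell(e.ref_codon), cell(e.alt_codon),
                cell(e.ref_aa), cell(e.alt_aa), is_primary or ".",
            ]) + "\n")


def read_label_table(path: str | Path, namespace: str = "family") -> LabelTable:
    """Two-column TSV ``locus_id<TAB>label``; a locus may appear on several rows."""
    labels: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError("expected locus_id<TAB>label", lineno)
            labels.setdefault(fields[0], set()).add(fields[1])
    return LabelTable(namespace=namespace, labels_by_locus=labels)


# Grand totals as printed in the source distribution table. The SNP columns
# equal their column sums; the insertion/deletion totals exceed them, which
# validate_printed_totals (summary module) flags.
TABLE2_PRINTED_TOTALS = {
    "total_snps": 1674360,
    "insertions": 80146,
    "deletions": 92655,
    "intergenic_noncoding": 294511,
    "utr3": 22686,
    "utr5": 23242,
    "cds": 195098,
    "synonymous": 75262,
    "non_synonymous": 119836,
}


def load_table2_fixture() -> list[ChromosomeSummary]:
    """The packaged 12-chromosome SNP/InDel distribution table."""
    resource = importlib.resources.files("snp2gene") / "data" / "table2_chromosomes.tsv"
    rows: list[ChromosomeSummary] = []
    lines = resource.read_text().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        if not line:
            continue
        rec = dict(zip(header, line.split("\t")))
        rows.append(
            ChromosomeSummary(
                chromosome=rec["chromosome"],
                total_snps=int(rec["total_snps"]),
                insertions=int(rec["insertions"]),
                deletions=int(rec["deletions"]),
                intergenic_noncoding=int(rec["intergenic_noncoding"]),
                utr3=int(rec["utr3"]),
                utr5=int(rec["utr5"]),
                cds=int(rec["cds"]),
                synonymous=int(rec["synonymous"]),
                non_synonymous=int(rec["non_synonymous"]),
            )
        )
    return rows
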