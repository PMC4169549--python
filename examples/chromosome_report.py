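"""Genome-scale arithmetic on the packaged per-chromosome distribution table.

Loads the packaged 12-chromosome SNP/InDel distribution (an indica-vs-
japonica rice comparison), recomputes the column totals, the genome SNP
density over the 241,000 covered kb, and the genic-fraction percentages,
and flags the columns whose printed grand totals disagree with their own
column sums.
"""

import snp2gene as sg
from snp2gene.formats import TABLE2_PRINTED_TOTALS
from snp2gene.summary import totals_row, validate_printed_totals

rows = sg.load_table2_fixture()
t = totals_row(rows)
print(f"chromosomes: {len(rows)}")
print(f"total SNPs (computed sum): {t.total_snps:,}")
print(f"  CDS {t.cds:,} = synonymous {t.synonymous:,} + non-synonymous {t.non_synonymous:,}")
print(f"  5'UTR {t.utr5:,}  3'UTR {t.utr3:,}  intergenic/noncoding {t.intergenic_noncoding:,}")
print(f"SNP density: {sg.genome_density(t.total_snps, 241_000)} SNPs/kb over 241,000 covered kb")

# genic concentration, using the study's printed genic tallies as inputs
print(f"genic share: {sg.share_percent(535_537, t.total_snps)}% of all SNPs fall in genes")
print(f"top third of SNP-carrying genes hold {sg.share_percent(387_816, 535_537)}% of genic SNPs")
print(f"hotspot genes (>100 SNPs) hold {sg.share_percent(26_080, 535_537)}%")

mismatches = validate_printed_totals(rows, TABLE2_PRINTED_TOTALS)
print("\ncolumns whose printed totals disagree with their column sums:")
for col, (computed, printed) in mismatches.items():
    print(f"  {col}: computed {computed:,} vs printed {printed:,}")
# Only the insertion/deletion totals disagree; every SNP column sums exactly.
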