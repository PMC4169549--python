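"""Classify SNPs against gene models at codon resolution.

Builds a toy gene (protein M-A-W-*), applies three SNPs and prints their
coding consequences: a silent third-position change, a stop-gained
("isSNP": a tryptophan codon becomes TGA) and a stop-lost ("psSNP": the
terminal stop becomes tryptophan).
"""

import snp2gene as sg
from snp2gene.models import GeneModel, ReferenceGenome, VariantCall

flank = "ACGTACGTAC"
cds = "ATGGCTTGGTGA"  # M A W *
genome = ReferenceGenome({"chr1": flank + cds + flank})
span = (len(flank) + 1, len(flank) + len(cds))
model = GeneModel("LOC_toy01", "chr1", "+", span, exons=[span], cds_segments=[span])

variants = [
    VariantCall("chr1", span[0] + 5, "T", "C", "SNP", 5, 1.0, 40, "homozygous"),
    VariantCall("chr1", span[0] + 8, "G", "A", "SNP", 5, 1.0, 40, "homozygous"),
    VariantCall("chr1", span[0] + 11, "A", "G", "SNP", 5, 1.0, 40, "homozygous"),
]
result = sg.annotate_all(variants, [model], genome)
for e in result.effects:
    print(f"{e.chromosome}:{e.position} {e.ref}>{e.alt}  codon {e.ref_codon}->{e.alt_codon}  "
          f"{e.ref_aa}->{e.alt_aa}  {e.consequence}")
# GCT->GCC is synonymous; TGG->TGA creates a premature stop (truncated
# protein); TGA->TGG removes the stop (read-through into the 3' UTR).
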