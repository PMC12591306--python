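"""Classify variants against the ARCH-PD putative-driver criteria.

Builds a handful of annotated variants and prints which criterion (C1-C8)
each matches, illustrating precedence and the COSMIC-count boundaries.
"""

from chclone import VariantRecord, classify_archpd
from chclone.drivers import DriverResources, load_default_resources

base = load_default_resources()
res = DriverResources(
    lof_genes=base.lof_genes,
    hotspot_residues=base.hotspot_residues,
    calr_exon9=("chr19", 12_000, 12_500),
)


def v(**kw):
    fields = dict(sample_id="S", chrom="chr1", pos=100, ref="A", alt="G",
                  variant_class="SNV", depth=2000, alt_count=20, vaf=0.01,
                  popaf_exome=0.0, popaf_genome=0.0, cosmic_count=0)
    fields.update(kw)
    return VariantRecord(**fields)


cases = [
    ("DNMT3A nonsense", v(gene="DNMT3A", consequence="nonsense")),
    ("JAK2 V617F", v(gene="JAK2", consequence="missense",
                     protein_change="p.V617F")),
    ("DNMT3A R882H", v(gene="DNMT3A", consequence="missense",
                       protein_change="p.R882H")),
    ("COSMIC n=15, VAF 5%", v(gene="SF3B1", consequence="missense",
                              cosmic_count=15, vaf=0.05, alt_count=100)),
    ("COSMIC n=15, VAF 45%", v(gene="SF3B1", consequence="missense",
                               cosmic_count=15, vaf=0.45, alt_count=900)),
    ("COSMIC n=150, VAF 45%", v(gene="SF3B1", consequence="missense",
                                cosmic_count=150, vaf=0.45, alt_count=900)),
]

for label, variant in cases:
    call = classify_archpd(variant, res)
    print(f"{label:>24}: {call.criterion:<5} {call.rationale}")
# C-numbers are the matched criteria; "none" means the variant fails the
# VAF/population-frequency/occurrence boundaries of every rule.
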