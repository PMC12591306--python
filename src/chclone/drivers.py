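"""Putative-driver classification for age-related clonal hematopoiesis.

A variant is called an ARCH-PD (putative driver) if it matches one of the
following criteria, checked in order with the first match reported:

C1  truncating (nonsense/frameshift/splice) in a gene where loss of
    function drives myeloid disease (curated list, 17 genes by default);
C2  truncating in CALR exon 9;
C3  JAK2 V617F;
C4  FLT3 internal tandem duplication (in-frame insertion >= 3 nt in FLT3,
    consumed as an annotation-level flag);
C5  nonsynonymous at a curated hotspot residue;
C6  nonsynonymous with COSMIC occurrence count >= 10, VAF < 42% and
    population allele frequency < 0.003;
C8  nonsynonymous with COSMIC occurrence count > 100 and population
    allele frequency < 0.003, regardless of VAF.

Criterion C7 of the published rule list (clustering within a functionally
validated locus) is deliberately not implemented: it requires locus-level
evidence curation that is not objectively reproducible.  COSMIC counts and
population frequencies are annotation inputs (missing values read as 0);
no live database is queried.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from typing import Optional

from .records import TRUNCATING_CONSEQUENCES, VariantRecord

__all__ = [
    "DriverResources",
    "DriverCall",
    "is_truncating",
    "classify_archpd",
    "load_default_resources",
]

_NONSYNONYMOUS = {
    "missense", "nonsense", "frameshift", "splice_site", "stop_loss",
    "inframe_indel",
}

_HGVSP_POS = re.compile(r"^p\.?[A-Za-z*]{1,3}(\d+)")


def is_truncating(consequence: str) -> bool:
    """True for nonsense, frameshift and splice-site changes."""
    if consequence not in _NONSYNONYMOUS and consequence not in (
        "synonymous", "other",
    ):
        raise ValueError(f"unknown consequence class: {consequence!r}")
    return consequence in TRUNCATING_CONSEQUENCES


@dataclass
class DriverResources:
    """Curated inputs for the rule engine.

    ``hotspot_residues`` maps gene -> set of protein positions and is
    shipped deliberately small (seed entries for CBL, DNMT3A and FLT3);
    faithful use on real panels requires the user's own curated table.
    ``calr_exon9`` is the genomic interval (chrom, start, end; 1-based
    inclusive) of CALR exon 9, if available.
    """

    lof_genes: frozenset = frozenset()
    hotspot_residues: dict = field(default_factory=dict)
    calr_exon9: Optional[tuple] = None
    flt3_itd_min_len: int = 3

    def __post_init__(self) -> None:
        if not self.lof_genes:
            raise ValueError("lof_genes must be non-empty")


@dataclass(frozen=True)
class DriverCall:
    is_driver: bool
    criterion: str  # C1..C6, C8 or "none"
    rationale: str

    def __post_init__(self) -> None:
        assert self.is_driver == (self.criterion != "none")


def _protein_position(protein_change: str) -> Optional[int]:
    m = _HGVSP_POS.match(protein_change or "")
    return int(m.group(1)) if m else None


def _is_flt3_itd(v: VariantRecord, min_len: int) -> bool:
    inserted = len(v.alt) - len(v.ref)
    return (
        v.gene == "FLT3"
        and v.variant_class == "insertion"
        and inserted >= min_len
        and inserted % 3 == 0
    )


def classify_archpd(
    v: VariantRecord, res: DriverResources, enabled: Optional[set] = None
) -> DriverCall:
    """Classify one nonsynonymous variant against the ARCH-PD criteria.

    ``enabled`` restricts the criteria considered (used for rule-engine
    diagnostics); default is all.  Synonymous and unannotated variants are
    non-drivers.
    """
    active = enabled if enabled is not None else {
        "C1", "C2", "C3", "C4", "C5", "C6", "C8",
    }
    cons = v.consequence
    nonsyn = cons in _NONSYNONYMOUS
    trunc = cons in TRUNCATING_CONSEQUENCES
    cosmic = v.cosmic_count or 0
    popaf = v.max_popaf

    if "C1" in active and trunc and v.gene in res.lof_genes:
        return DriverCall(True, "C1", f"truncating in LOF gene {v.gene}")
    if "C2" in active and trunc and v.gene == "CALR":
        in_exon9 = res.calr_exon9 is not None and (
            v.chrom == res.calr_exon9[0]
            and res.calr_exon9[1] <= v.pos <= res.calr_exon9[2]
        )
        if in_exon9:
            return DriverCall(True, "C2", "truncating in CALR exon 9")
    if "C3" in active and v.gene == "JAK2" and (
        v.protein_change in ("p.V617F", "V617F")
    ):
        return DriverCall(True, "C3", "JAK2 V617F")
    if "C4" in active and _is_flt3_itd(v, res.flt3_itd_min_len):
        return DriverCall(True, "C4", "FLT3 internal tandem duplication")
    if "C5" in active and nonsyn:
        pos = _protein_position(v.protein_change)
        if pos is not None and pos in res.hotspot_residues.get(v.gene, ()):
            return DriverCall(
                True, "C5", f"hotspot residue {v.gene} p.{pos}"
            )
    if "C6" in active and nonsyn and cosmic >= 10 and v.vaf < 0.42 and popaf < 0.003:
        return DriverCall(
            True, "C6", f"COSMIC n={cosmic} (>=10), VAF<42%, popAF<0.3%"
        )
    if "C8" in active and nonsyn and cosmic > 100 and popaf < 0.003:
        return DriverCall(
            True, "C8", f"COSMIC n={cosmic} (>100), popAF<0.3%, any VAF"
        )
    return DriverCall(False, "none", "no ARCH-PD criterion matched")


def load_default_resources() -> DriverResources:
    """Bundled LOF-gene list and seed hotspot table.

    The hotspot table is explicitly incomplete; CALR exon-9 coordinates
    are not bundled (C2 then requires a truncating CALR call inside a
    user-supplied interval).
    """
    pkg = importlib_resources.files("chclone") / "resources"
    lof = frozenset(
        line.strip()
        for line in (pkg / "lof_genes.txt").read_text().splitlines()
        if line.strip() and not line.startswith("#")
    )
    hotspots: dict[str, set] = {}
    with (pkg / "hotspot_residues.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            hotspots.setdefault(row["gene"], set()).add(int(row["residue"]))
    return DriverResources(lof_genes=lof, hotspot_residues=hotspots)
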