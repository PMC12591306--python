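"""Core domain types for clonal-hematopoiesis (CH) variant analysis.

A *variant record* is one called somatic variant in one blood sample from an
error-corrected sequencing panel, carrying the consensus-read counts and the
annotation fields (gene, consequence, population allele frequencies, COSMIC
occurrence count, pathogenicity scores) that every downstream filtering and
classification rule consumes.  A *cohort row* is one subject's covariates:
age at the CH blood draw, age at first radioactive-iodine therapy (RAIT),
sex, smoking history, cumulative RAIT dose in GBq and elapsed months since
the first RAIT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from intervaltree import IntervalTree

__all__ = [
    "VariantRecord",
    "CohortRow",
    "RegionMask",
    "GeneModel",
    "CONSEQUENCES",
    "TRUNCATING_CONSEQUENCES",
]

#: Controlled vocabulary for functional consequence annotations.
CONSEQUENCES = frozenset(
    {
        "synonymous",
        "missense",
        "nonsense",
        "frameshift",
        "inframe_indel",
        "splice_site",
        "stop_loss",
        "other",
    }
)

#: Consequence classes treated as protein-truncating.
TRUNCATING_CONSEQUENCES = frozenset({"nonsense", "frameshift", "splice_site"})


@dataclass
class VariantRecord:
    """One called variant (one ALT allele) in one sample.

    Positions are 1-based as in VCF.  ``strand_counts`` is
    ``(ref_fwd, ref_rev, alt_fwd, alt_rev)``; ``orientation_counts`` is
    ``(alt_F1R2, alt_F2R1)`` read-pair orientation support for the ALT
    allele.  Missing annotations are ``None``; ``scores`` maps a
    pathogenicity-score name (e.g. ``"CADD"``) to its value.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str  # SNV | insertion | deletion | MNV
    depth: int
    alt_count: int
    vaf: float
    strand_counts: Optional[tuple[int, int, int, int]] = None
    orientation_counts: Optional[tuple[int, int]] = None
    gene: str = ""
    consequence: str = "other"
    protein_change: str = ""
    popaf_exome: Optional[float] = None
    popaf_genome: Optional[float] = None
    cosmic_count: Optional[int] = None
    dbsnp_member: Optional[bool] = None
    scores: dict = field(default_factory=dict)
    filter_status: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.alt_count > self.depth:
            raise ValueError(
                f"alt_count {self.alt_count} exceeds depth {self.depth}"
            )
        if self.strand_counts is not None and any(
            c < 0 for c in self.strand_counts
        ):
            raise ValueError("strand counts must be non-negative")
        if self.orientation_counts is not None and any(
            c < 0 for c in self.orientation_counts
        ):
            raise ValueError("orientation counts must be non-negative")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Variant identity across samples: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def ref_span(self) -> tuple[int, int]:
        """1-based inclusive genomic span of the reference allele."""
        return (self.pos, self.pos + len(self.ref) - 1)

    @property
    def max_popaf(self) -> float:
        """Max of exome/genome population AF; missing treated as 0."""
        return max(self.popaf_exome or 0.0, self.popaf_genome or 0.0)

    @property
    def passed(self) -> bool:
        return not self.filter_status

    def copy(self, **changes) -> "VariantRecord":
        out = replace(self, **changes)
        if "scores" not in changes:
            out.scores = dict(self.scores)
        if "filter_status" not in changes:
            out.filter_status = set(self.filter_status)
        return out


@dataclass(frozen=True)
class CohortRow:
    """One subject's covariates.

    ``dose_gbq`` is the cumulative radioiodine activity; 0 means no RAIT.
    ``age_rait`` and ``elapsed_months`` are ``None`` for untreated controls.
    """

    sample_id: str
    age_ch: float
    sex: str  # female | male
    smoking: bool
    dose_gbq: float
    age_rait: Optional[float] = None
    elapsed_months: Optional[float] = None
    paired_pre_sample: Optional[str] = None

    def __post_init__(self) -> None:
        if self.age_ch <= 0:
            raise ValueError(f"age_ch must be positive, got {self.age_ch}")
        if self.dose_gbq < 0:
            raise ValueError(f"dose_gbq must be >= 0, got {self.dose_gbq}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be female or male, got {self.sex!r}")


class RegionMask:
    """Error-prone-region mask with symmetric flanks.

    Intervals are stored 0-based half-open (BED convention) after extending
    each side by ``flank_bp`` (clamped at 0) and merging overlaps.  Queries
    take 1-based positions/spans, the convention used for variants.
    """

    def __init__(
        self,
        intervals: list[tuple[str, int, int]],
        flank_bp: int = 5,
    ) -> None:
        if flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        self.flank_bp = flank_bp
        self.raw_intervals = [tuple(iv) for iv in intervals]
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(
                    f"invalid interval {chrom}:{start}-{end} (start >= end)"
                )
            s = max(0, start - flank_bp)
            e = end + flank_bp
            self._trees.setdefault(chrom, IntervalTree()).addi(s, e)
        for tree in self._trees.values():
            tree.merge_overlaps()

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        """Flanked, merged intervals, sorted (0-based half-open)."""
        out = []
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                out.append((chrom, iv.begin, iv.end))
        return out

    def contains(self, chrom: str, pos: int) -> bool:
        """True if 1-based position ``pos`` falls in a masked interval."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def overlaps_span(self, chrom: str, start: int, end: int) -> bool:
        """True if the 1-based inclusive span [start, end] hits the mask."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start - 1, end))

    def overlaps_variant(self, v: VariantRecord) -> bool:
        s, e = v.ref_span
        return self.overlaps_span(v.chrom, s, e)


_STOP_CODONS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {}


def _build_codon_table() -> dict:
    # standard genetic code, built from Biopython to avoid transcription slips
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


def translate_codon(codon: str) -> str:
    """Single-letter amino acid for a DNA codon; '*' for stop."""
    global _CODON_TABLE
    if not _CODON_TABLE:
        _CODON_TABLE = _build_codon_table()
    return _CODON_TABLE[codon.upper()]


@dataclass(frozen=True)
class GeneModel:
    """Coding model of one panel gene.

    ``cds_sequence`` is the coding strand including the terminal stop codon;
    ``exon_coordinates`` are 1-based inclusive genomic intervals;
    ``flank5``/``flank3`` are the single reference bases adjacent to the CDS,
    used for trinucleotide context at its first and last positions.
    """

    gene: str
    cds_sequence: str
    exon_coordinates: tuple = ()
    strand: str = "+"
    flank5: str = "A"
    flank3: str = "A"

    def __post_init__(self) -> None:
        seq = self.cds_sequence.upper()
        if len(seq) % 3 != 0:
            raise ValueError(
                f"{self.gene}: CDS length {len(seq)} not divisible by 3"
            )
        if len(seq) < 6:
            raise ValueError(f"{self.gene}: CDS shorter than 2 codons")
        object.__setattr__(self, "cds_sequence", seq)
        for i in range(0, len(seq) - 3, 3):
            if seq[i : i + 3] in _STOP_CODONS:
                raise ValueError(
                    f"{self.gene}: internal stop codon at codon {i // 3 + 1}"
                )

    @property
    def n_codons(self) -> int:
        return len(self.cds_sequence) // 3

    def codon(self, i: int) -> str:
        return self.cds_sequence[3 * i : 3 * i + 3]
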