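"""Somatic-variant filtering for clonal-hematopoiesis calling.

Six rule families, applied in a fixed order with first-failure audit
attribution:

1. **Sequence bias** — two-sided exact binomial test of alt F1R2 vs F2R1
   read-pair orientation against 0.5, and a Fisher exact test of
   ref-vs-alt strand counts.  Both require the p-value below its alpha
   *and* a minimum imbalance fraction: at panel depths in the thousands a
   significance test alone flags a few percent of genuinely unbiased
   calls, so a bias call additionally demands that the dominant
   orientation/strand carry at least ``min_bias_imbalance`` of the alt
   reads (the way bias detectors threshold a bias score rather than a
   p-value).  Variants without usable counts are flagged untestable and
   passed.
2. **Germline** — population allele frequency > 1% in either the exome or
   genome reference database; VAF > 35%; VAF > 20% with the variant key in
   a curated review resource (a reproducible stand-in for manual dbSNP
   review).
3. **Region mask** — reference span intersects an error-prone interval
   after 5 bp flanking.
4. **Confidence** — depth must exceed 400x and alt reads must exceed 2
   (SNV/MNV) or 5 (indel); all strict inequalities.
5. **Recurrence** — a variant key seen in more than 10% of distinct
   samples is removed everywhere as a recurrent technical call.
6. **Detection floor** — VAF must exceed 0.5%; applied last so the audit
   separates floor losses from artifact losses.

Synonymous variants are excluded from the association stream but kept in
a parallel stream for dN/dS, which needs them.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from scipy import stats

from .config import PipelineConfig
from .records import RegionMask, VariantRecord

__all__ = [
    "FilterAudit",
    "assess_sequence_bias",
    "apply_germline_filters",
    "apply_region_mask",
    "apply_confidence_filters",
    "apply_recurrence_filter",
    "select_nonsynonymous",
    "run_filter_pipeline",
    "FILTER_ORDER",
]

log = logging.getLogger(__name__)

FILTER_ORDER = (
    "bias_orientation",
    "bias_strand",
    "germline_popaf",
    "germline_vaf35",
    "germline_review",
    "region_mask",
    "confidence",
    "recurrence",
    "vaf_floor",
)


@dataclass
class FilterAudit:
    """Per-filter removal counts with first-failure attribution."""

    n_input: int = 0
    n_retained: int = 0
    removed_by_filter: Counter = field(default_factory=Counter)
    failures: dict = field(default_factory=dict)  # (sample, key) -> [labels]

    @property
    def n_removed(self) -> int:
        return sum(self.removed_by_filter.values())

    def check_conservation(self) -> bool:
        return self.n_input == self.n_retained + self.n_removed

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed_by_filter": dict(self.removed_by_filter),
        }


def assess_sequence_bias(
    v: VariantRecord,
    alpha_orientation: float = 0.05,
    alpha_strand: float = 0.01,
    min_imbalance: float = 0.90,
    min_count: int = 20,
) -> tuple[bool, list[str]]:
    """Test one variant for orientation and strand bias.

    A bias call requires (i) at least ``min_count`` informative alt reads
    — below that the test is uninformative and the variant passes as
    untestable, as bias annotators behave — (ii) the exact-test p-value
    below its alpha and (iii) the dominant orientation/strand carrying at
    least ``min_imbalance`` of the alt reads.  Returns ``(passed, flags)``
    with flags among ``bias_orientation``, ``bias_strand``,
    ``untestable``.
    """
    flags: list[str] = []
    if v.orientation_counts is None and v.strand_counts is None:
        return True, ["untestable"]
    if v.orientation_counts is not None:
        f1r2, f2r1 = v.orientation_counts
        if f1r2 < 0 or f2r1 < 0:
            raise ValueError("negative orientation counts")
        total = f1r2 + f2r1
        if total >= max(1, min_count):
            p = stats.binomtest(f1r2, total, 0.5).pvalue
            imbalance = max(f1r2, f2r1) / total
            if p < alpha_orientation and imbalance >= min_imbalance:
                flags.append("bias_orientation")
    if v.strand_counts is not None:
        rf, rr, af, ar = v.strand_counts
        if min(rf, rr, af, ar) < 0:
            raise ValueError("negative strand counts")
        if af + ar >= max(1, min_count):
            _, p = stats.fisher_exact([[rf, rr], [af, ar]])
            imbalance = max(af, ar) / (af + ar)
            if p < alpha_strand and imbalance >= min_imbalance:
                flags.append("bias_strand")
    return not flags, flags


def apply_germline_filters(
    v: VariantRecord,
    review_resource: Optional[set] = None,
    popaf_max: float = 0.01,
    vaf_germline: float = 0.35,
    vaf_review: float = 0.20,
) -> tuple[bool, Optional[str]]:
    """Germline-origin checks.  Returns ``(keep, reason_if_dropped)``."""
    if (v.popaf_exome or 0.0) > popaf_max or (v.popaf_genome or 0.0) > popaf_max:
        return False, "germline_popaf"
    if v.vaf > vaf_germline:
        return False, "germline_vaf35"
    if v.vaf > vaf_review and review_resource and v.key in review_resource:
        return False, "germline_review"
    return True, None


def apply_region_mask(
    variants: Iterable[VariantRecord], mask: RegionMask
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split variants into (retained, removed) by masked-region overlap.

    A variant is removed iff any base of its reference span lies in a
    flanked interval.
    """
    retained, removed = [], []
    for v in variants:
        (removed if mask.overlaps_variant(v) else retained).append(v)
    return retained, removed


def apply_confidence_filters(
    v: VariantRecord,
    min_depth_exclusive: int = 400,
    min_alt_snv_exclusive: int = 2,
    min_alt_indel_exclusive: int = 5,
) -> tuple[bool, Optional[str]]:
    """Depth/alt-count confidence rule (strict inequalities)."""
    if v.depth <= min_depth_exclusive:
        return False, "confidence"
    threshold = (
        min_alt_indel_exclusive
        if v.variant_class in ("insertion", "deletion")
        else min_alt_snv_exclusive
    )
    if v.alt_count <= threshold:
        return False, "confidence"
    return True, None


def apply_recurrence_filter(
    variants: Iterable[VariantRecord],
    n_samples: int,
    fraction: float = 0.10,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Remove variant keys present in more than ``fraction`` of samples.

    Counts distinct samples per (chrom, pos, ref, alt) key; a recurrent key
    is removed from every sample.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    variants = list(variants)
    samples_per_key: dict = {}
    for v in variants:
        samples_per_key.setdefault(v.key, set()).add(v.sample_id)
    recurrent = {
        k for k, s in samples_per_key.items() if len(s) / n_samples > fraction
    }
    retained = [v for v in variants if v.key not in recurrent]
    removed = [v for v in variants if v.key in recurrent]
    return retained, removed


def select_nonsynonymous(
    variants: Iterable[VariantRecord],
) -> list[VariantRecord]:
    """Drop synonymous variants (the association stream).

    Unknown consequence classes are retained with a warning so that
    unexpected annotations are visible rather than silently lost.
    """
    out = []
    for v in variants:
        if v.consequence == "synonymous":
            continue
        if v.consequence == "other":
            log.warning(
                "unknown consequence for %s:%d %s>%s; retained",
                v.chrom, v.pos, v.ref, v.alt,
            )
        out.append(v)
    return out


def run_filter_pipeline(
    variants_by_sample: dict,
    mask: Optional[RegionMask] = None,
    config: Optional[PipelineConfig] = None,
    review_resource: Optional[set] = None,
) -> tuple[dict, FilterAudit]:
    """Run all filters over a cohort's raw calls.

    Parameters
    ----------
    variants_by_sample
        Mapping sample id -> list of raw :class:`VariantRecord`.
    mask
        Flanked error-prone-region mask, or ``None`` to skip masking.
    config
        Thresholds; defaults to :class:`PipelineConfig` defaults.

    Returns ``(filtered_by_sample, audit)``.  Every removal is attributed
    to the first failing filter in :data:`FILTER_ORDER`; the retained set
    itself is order-independent because all per-variant rules are
    independent predicates (recurrence is evaluated cohort-wide on the
    post-germline survivors).
    """
    cfg = config or PipelineConfig()
    audit = FilterAudit()
    n_samples = len(variants_by_sample)
    failures: dict = {}  # id(v) -> list of failed filter labels
    post_germline: list[VariantRecord] = []
    everything: list[VariantRecord] = []

    for sample_id, variants in variants_by_sample.items():
        for v in variants:
            audit.n_input += 1
            everything.append(v)
            failed: list[str] = []
            _, bias_flags = assess_sequence_bias(
                v,
                alpha_orientation=cfg.alpha_orientation,
                alpha_strand=cfg.alpha_strand,
                min_imbalance=cfg.min_bias_imbalance,
                min_count=cfg.min_bias_count,
            )
            failed += [f for f in bias_flags if f != "untestable"]
            keep, reason = apply_germline_filters(
                v,
                review_resource=review_resource,
                popaf_max=cfg.popaf_max,
                vaf_germline=cfg.vaf_germline,
                vaf_review=cfg.vaf_review,
            )
            if keep:
                post_germline.append(v)
            else:
                failed.append(reason)
            if mask is not None and mask.overlaps_variant(v):
                failed.append("region_mask")
            keep, reason = apply_confidence_filters(
                v,
                min_depth_exclusive=cfg.min_depth_exclusive,
                min_alt_snv_exclusive=cfg.min_alt_snv_exclusive,
                min_alt_indel_exclusive=cfg.min_alt_indel_exclusive,
            )
            if not keep:
                failed.append(reason)
            if not v.vaf > cfg.vaf_floor:
                failed.append("vaf_floor")
            failures[id(v)] = failed

    # cohort-level recurrence, always evaluated on the post-germline set
    _, recurrent = apply_recurrence_filter(
        post_germline, n_samples=n_samples, fraction=cfg.recurrence_fraction
    )
    recurrent_keys = {v.key for v in recurrent}
    filtered_by_sample: dict[str, list[VariantRecord]] = {
        s: [] for s in variants_by_sample
    }
    for v in everything:
        failed = failures[id(v)]
        if v.key in recurrent_keys:
            failed.append("recurrence")
        if failed:
            ordered = sorted(failed, key=FILTER_ORDER.index)
            audit.failures[(v.sample_id, *v.key)] = ordered
            audit.removed_by_filter[ordered[0]] += 1
            v.filter_status.update(ordered)
        else:
            audit.n_retained += 1
            filtered_by_sample[v.sample_id].append(v)
    if not audit.check_conservation():
        raise AssertionError("filter audit does not reconcile")
    return filtered_by_sample, audit
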