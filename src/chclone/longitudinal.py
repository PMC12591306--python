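"""Longitudinal clone dynamics from paired pre/post-treatment samples.

Variants from a patient's pre- and post-treatment blood draws are joined
on exact identity (chrom, pos, ref, alt); each mutation's trajectory is
classified as *vanished/decreased* (undetectable afterwards, or VAF
lower), *emerged/increased* (new afterwards, or VAF higher) or
*unchanged* (equal within an optional tolerance ``epsilon``; the
tie category keeps the rule deterministic).  Per-patient counts per
category and their cohort means summarize the dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .records import VariantRecord

__all__ = [
    "PairedVariant",
    "pair_variants",
    "classify_dynamics",
    "summarize_dynamics",
    "CATEGORIES",
]

CATEGORIES = ("vanished_decreased", "emerged_increased", "unchanged")


@dataclass(frozen=True)
class PairedVariant:
    """One mutation tracked across a patient's pre/post samples."""

    patient_id: str
    key: tuple  # (chrom, pos, ref, alt, gene)
    vaf_pre: Optional[float]
    vaf_post: Optional[float]
    months_between: Optional[float] = None

    def __post_init__(self) -> None:
        if self.vaf_pre is None and self.vaf_post is None:
            raise ValueError("at least one of vaf_pre/vaf_post must be present")


def pair_variants(
    pre: Iterable[VariantRecord],
    post: Iterable[VariantRecord],
    patient_id: str,
    months_between: Optional[float] = None,
) -> list[PairedVariant]:
    """Outer-join two samples' variants on exact variant identity."""
    pre_map = {(*v.key, v.gene): v for v in pre}
    post_map = {(*v.key, v.gene): v for v in post}
    out = []
    for key in sorted(set(pre_map) | set(post_map)):
        vp, vq = pre_map.get(key), post_map.get(key)
        out.append(
            PairedVariant(
                patient_id=patient_id,
                key=key,
                vaf_pre=None if vp is None else vp.vaf,
                vaf_post=None if vq is None else vq.vaf,
                months_between=months_between,
            )
        )
    return out


def classify_dynamics(pv: PairedVariant, epsilon: float = 0.0) -> str:
    """Trajectory category for one paired mutation.

    Vanished/decreased if undetectable afterwards or the VAF fell by more
    than ``epsilon``; emerged/increased if new afterwards or the VAF rose
    by more than ``epsilon``; unchanged otherwise.
    """
    if pv.vaf_post is None:
        return "vanished_decreased"
    if pv.vaf_pre is None:
        return "emerged_increased"
    if pv.vaf_post < pv.vaf_pre - epsilon:
        return "vanished_decreased"
    if pv.vaf_post > pv.vaf_pre + epsilon:
        return "emerged_increased"
    return "unchanged"


def summarize_dynamics(
    paired: Iterable[PairedVariant], epsilon: float = 0.0
) -> tuple[pd.DataFrame, dict]:
    """Per-patient category counts and cohort means.

    Returns a patient-sorted table with one count column per category and
    a dict of cohort means (``mean_<category>``), the headline summary of
    clone dynamics.
    """
    paired = list(paired)
    if not paired:
        raise ValueError("no paired variants to summarize")
    rows: dict[str, dict] = {}
    for pv in paired:
        rec = rows.setdefault(
            pv.patient_id, dict.fromkeys(CATEGORIES, 0)
        )
        rec[classify_dynamics(pv, epsilon)] += 1
    table = (
        pd.DataFrame.from_dict(rows, orient="index")
        .rename_axis("patient_id")
        .sort_index()
        .reset_index()
    )
    means = {f"mean_{c}": float(table[c].mean()) for c in CATEGORIES}
    return table, means
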