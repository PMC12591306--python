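"""Synthetic cohorts, mutation truth sets and artifact-laden raw calls.

The generator emulates the structure of a dose-stratified thyroid-cancer
cohort screened for clonal hematopoiesis with an error-corrected panel:

* three dose groups (no-RAIT controls, <7.4 GBq, >=7.4 GBq) with the
  group sizes, age means/SDs, sex ratios and dose distributions of the
  target study design (110/115/133 subjects; ages 60.0+-14.5, 52.4+-14.0,
  56.4+-13.9 years; high-dose mean 23.9 GBq);
* right-skewed (log-normal) clone-size distributions with a 0.5% VAF
  detection floor;
* age-dependent DNMT3A/TET2 clone acquisition and dose-dependent
  truncating-PPM1D / missense-TP53 clones (multiplicative hazards per
  decade and per 1.11 GBq);
* six injected artifact classes, each constructed to violate exactly one
  filtering rule: orientation bias, strand bias, germline leakage,
  error-prone-region calls, recurrent technical calls and low-depth calls;
* paired pre/post samples with multiplicative VAF drift for longitudinal
  analysis.

All generators are deterministic for a fixed master seed; each operation
draws from its own substream so stages can be re-run independently.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .records import CohortRow, GeneModel, RegionMask, VariantRecord

__all__ = [
    "CohortSimParams",
    "EffectConfig",
    "TruthVariant",
    "TruthSet",
    "simulate_cohort",
    "simulate_cds_panel",
    "simulate_region_mask",
    "simulate_truth_mutations",
    "render_raw_calls",
    "simulate_paired_cohort",
    "DEFAULT_GENE_NAMES",
]

#: Gene names assigned to the default synthetic panel, headed by the
#: clonal-hematopoiesis genes whose behaviour the effect model shapes.
DEFAULT_GENE_NAMES = (
    "DNMT3A", "TET2", "PPM1D", "TP53", "ASXL1",
    "JAK2", "SF3B1", "SRSF2", "GNB1", "CBL",
)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_GENE_SPACING = 100_000  # bp between synthetic gene starts on chr1


def substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-operation random stream derived from a master seed."""
    label_key = zlib.crc32(label.encode()) % (2**31)
    child = np.random.SeedSequence([int(seed) % (2**31), label_key])
    return np.random.default_rng(child)


# -------------------------------------------------------------------- cohort


@dataclass
class CohortSimParams:
    """Cohort composition, defaulting to the study design this emulates."""

    n_control: int = 110
    n_low: int = 115
    n_high: int = 133
    age_mean_sd: tuple = ((60.0, 14.5), (52.4, 14.0), (56.4, 13.9))
    female_fraction: tuple = (0.855, 0.861, 0.692)
    # ever-smoker fractions; modest, consistent with a largely female cohort
    smoking_fraction: tuple = (0.027, 0.052, 0.075)
    low_dose_range_gbq: tuple = (1.11, 7.4)
    high_dose_min_gbq: float = 7.4
    high_dose_mean_gbq: float = 23.9
    elapsed_mean_sd: tuple = ((75.9, 74.8), (116.4, 76.3))  # low, high groups
    min_age: float = 20.0
    min_elapsed_months: float = 12.0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_low, self.n_high) < 0:
            raise ValueError("group sizes must be >= 0")
        lo, hi = self.low_dose_range_gbq
        if not (0 < lo < hi <= self.high_dose_min_gbq):
            raise ValueError("low-dose range must sit below the high-dose cutoff")
        if self.high_dose_mean_gbq <= self.high_dose_min_gbq:
            raise ValueError("high-dose mean must exceed its minimum")


def _truncated_normal(rng, mean, sd, low, size):
    out = rng.normal(mean, sd, size=size)
    bad = out < low
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < low
    return out


def simulate_cohort(
    params: CohortSimParams = None, seed: int = 0
) -> list[CohortRow]:
    """Draw a cohort with exact group sizes and configured covariates.

    Controls have dose 0 and no RAIT age / elapsed time; treated subjects
    get doses uniform on the low range or shifted-exponential above the
    high cutoff, elapsed times truncated at one year, and an age at first
    treatment consistent with age at test minus elapsed time.
    """
    params = params or CohortSimParams()
    rng = substream(seed, "cohort")
    rows: list[CohortRow] = []
    sizes = (params.n_control, params.n_low, params.n_high)
    labels = ("CTRL", "LOW", "HIGH")
    for gi, (n, label) in enumerate(zip(sizes, labels)):
        if n == 0:
            continue
        mean, sd = params.age_mean_sd[gi]
        ages = _truncated_normal(rng, mean, sd, params.min_age, n)
        female = rng.random(n) < params.female_fraction[gi]
        smoking = rng.random(n) < params.smoking_fraction[gi]
        if gi == 0:
            doses = np.zeros(n)
            elapsed = np.full(n, np.nan)
        elif gi == 1:
            lo, hi = params.low_dose_range_gbq
            doses = rng.uniform(lo, hi, size=n)
            m, s = params.elapsed_mean_sd[0]
            elapsed = _truncated_normal(rng, m, s, params.min_elapsed_months, n)
        else:
            scale = params.high_dose_mean_gbq - params.high_dose_min_gbq
            doses = params.high_dose_min_gbq + rng.exponential(scale, size=n)
            m, s = params.elapsed_mean_sd[1]
            elapsed = _truncated_normal(rng, m, s, params.min_elapsed_months, n)
        for i in range(n):
            has_rait = doses[i] > 0
            age_rait = None
            el = None
            if has_rait:
                el = float(elapsed[i])
                age_rait = max(19.0, float(ages[i]) - el / 12.0)
            rows.append(
                CohortRow(
                    sample_id=f"{label}{i + 1:04d}",
                    age_ch=float(ages[i]),
                    sex="female" if female[i] else "male",
                    smoking=bool(smoking[i]),
                    dose_gbq=float(doses[i]),
                    age_rait=age_rait,
                    elapsed_months=el,
                )
            )
    return rows


# --------------------------------------------------------------- gene panel


def simulate_cds_panel(
    n_genes: int = 10, length_codons: int = 300, seed: int = 0
) -> list[GeneModel]:
    """Random coding sequences: ATG start, no internal stop, terminal stop.

    ``length_codons`` counts coding codons excluding the stop, so each CDS
    is ``3 * (length_codons + 1)`` nt.  Genes are laid out on a synthetic
    contig ``chr1`` at 100 kb spacing and named after canonical CH genes
    first, then ``GENE11``, ``GENE12``, ...
    """
    if length_codons < 2:
        raise ValueError("length_codons must be >= 2")
    rng = substream(seed, "panel")
    sense_codons = [
        a + b + c
        for a in _BASES for b in _BASES for c in _BASES
        if a + b + c not in _STOPS
    ]
    panel = []
    for g in range(n_genes):
        name = (
            DEFAULT_GENE_NAMES[g]
            if g < len(DEFAULT_GENE_NAMES)
            else f"GENE{g + 1}"
        )
        body = rng.choice(sense_codons, size=length_codons - 1)
        stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
        cds = "ATG" + "".join(body) + stop
        start = 1 + g * _GENE_SPACING
        panel.append(
            GeneModel(
                gene=name,
                cds_sequence=cds,
                exon_coordinates=(("chr1", start, start + len(cds) - 1),),
                strand="+",
                flank5=_BASES[rng.integers(4)],
                flank3=_BASES[rng.integers(4)],
            )
        )
    return panel


def simulate_region_mask(
    panel: list[GeneModel], n_intervals: int = 20, seed: int = 0,
    flank_bp: int = 5,
) -> RegionMask:
    """Error-prone intervals placed between genes, clear of every CDS."""
    rng = substream(seed, "mask")
    intervals = []
    for _ in range(n_intervals):
        g = int(rng.integers(len(panel)))
        base = g * _GENE_SPACING + _GENE_SPACING // 2  # mid-spacer, 0-based
        start = base + int(rng.integers(0, 20_000))
        intervals.append(("chr1", start, start + int(rng.integers(10, 200))))
    return RegionMask(intervals, flank_bp=flank_bp)


# ------------------------------------------------------------------ effects


@dataclass
class EffectConfig:
    """Mutation-acquisition and rendering model.

    Rates are expected mutation counts per subject per gene; hazards are
    multiplicative per decade of age (centred at 50) and per ``dose_unit``
    GBq of cumulative dose, the reporting unit used for dose effects.
    """

    background_rate: float = 0.25
    consequence_profile: dict = field(
        default_factory=lambda: {
            "synonymous": 0.25,
            "missense": 0.48,
            "nonsense": 0.09,
            "frameshift": 0.10,
            "splice_site": 0.04,
            "inframe_indel": 0.04,
        }
    )
    age_effect: dict = field(
        default_factory=lambda: {"DNMT3A": 1.7, "TET2": 1.7, "PPM1D": 1.4}
    )
    dose_effect: dict = field(
        default_factory=lambda: {
            ("PPM1D", "truncating"): 1.10,
            ("TP53", "missense"): 1.05,
        }
    )
    dose_unit_gbq: float = 1.11
    # clone-size model: log-normal on the percent scale with a detection
    # floor; defaults put ~16% of the untruncated mass above the floor and
    # ~3% of detected clones above 2% VAF, so a ~3.5-clone/subject burden
    # reproduces a ~97% / ~11% prevalence at the 0.5% / 2% cutoffs
    vaf_log_mu: float = -1.6     # ln(percent)
    vaf_log_sigma: float = 0.9
    vaf_floor: float = 0.005     # fraction
    # pathogenicity scores: CADD-like, higher for damaging classes, and a
    # positive coupling from score to clone size
    cadd_mean: dict = field(
        default_factory=lambda: {
            "synonymous": 5.0, "missense": 18.0, "nonsense": 35.0,
            "frameshift": 33.0, "splice_site": 30.0, "inframe_indel": 16.0,
        }
    )
    cadd_sd: float = 5.0
    score_vaf_coupling: float = 0.03  # ln-VAF shift per CADD point
    # rendering
    depth_mean: float = 1926.0
    depth_sd: float = 300.0
    depth_min: int = 1200
    depth_max: int = 3200
    # artifact burden: expected injected calls per sample per class
    artifact_rates: dict = field(
        default_factory=lambda: {
            "orientation_bias": 0.6,
            "strand_bias": 0.6,
            "germline_leak": 0.8,
            "masked_region": 0.5,
            "low_depth": 0.5,
        }
    )
    n_recurrent_keys: int = 3
    recurrent_sample_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if any(r < 0 for r in self.artifact_rates.values()):
            raise ValueError("artifact rates must be >= 0")
        total = sum(self.consequence_profile.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError("consequence_profile must sum to 1")


@dataclass(frozen=True)
class TruthVariant:
    """One planted call with its generating truth label."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    true_vaf: float
    label: str  # "true_CH" or an artifact class name

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TruthSet:
    """Planted mutations plus the sample roster they were drawn for."""

    variants: list
    sample_ids: list

    def by_sample(self) -> dict:
        out = {s: [] for s in self.sample_ids}
        for t in self.variants:
            out[t.sample_id].append(t)
        return out

    def labels(self) -> dict:
        return {(t.sample_id, *t.key): t.label for t in self.variants}


_TRUNCATING = {"nonsense", "frameshift", "splice_site"}


def _gene_span(gene: GeneModel) -> tuple[str, int, int]:
    chrom, start, end = gene.exon_coordinates[0]
    return chrom, start, end


def _draw_variant_alleles(rng, gene: GeneModel, consequence: str):
    """Position and ref/alt alleles consistent with the variant class."""
    chrom, start, _ = _gene_span(gene)
    L = len(gene.cds_sequence)
    off = int(rng.integers(0, L - 4))
    pos = start + off
    ref_base = gene.cds_sequence[off]
    if consequence in ("synonymous", "missense", "nonsense"):
        alt = _BASES[rng.integers(4)]
        while alt == ref_base:
            alt = _BASES[rng.integers(4)]
        return chrom, pos, ref_base, alt
    if consequence == "frameshift":
        # 1-2 bp deletion, VCF-style anchored on the preceding base
        dlen = int(rng.integers(1, 3))
        ref = gene.cds_sequence[off : off + dlen + 1]
        return chrom, pos, ref, ref_base
    if consequence == "inframe_indel":
        ref = gene.cds_sequence[off : off + 4]
        return chrom, pos, ref, ref_base
    # splice_site: model as an SNV at the gene edge
    alt = _BASES[rng.integers(4)]
    while alt == ref_base:
        alt = _BASES[rng.integers(4)]
    return chrom, pos, ref_base, alt


def _draw_vaf(rng, effects: EffectConfig, cadd: float) -> float:
    shift = effects.score_vaf_coupling * (cadd - 15.0)
    for _ in range(1000):
        pct = math.exp(rng.normal(effects.vaf_log_mu + shift, effects.vaf_log_sigma))
        if pct / 100.0 > effects.vaf_floor and pct < 60.0:
            return pct / 100.0
    return max(effects.vaf_floor * 1.5, 0.008)


def simulate_truth_mutations(
    cohort: list[CohortRow],
    effects: EffectConfig = None,
    panel: list[GeneModel] = None,
    seed: int = 0,
) -> TruthSet:
    """Plant true CH mutations per subject.

    Per gene and consequence class, mutation counts are Poisson with rate

        background_rate * P(class | gene)
        * age_effect[gene] ** ((age - 50) / 10)
        * dose_effect[gene, impact] ** (dose / dose_unit)

    so DNMT3A/TET2 burden grows with age and truncating-PPM1D burden with
    cumulative dose.  Each mutation receives alleles consistent with its
    class, a CADD-like score and a floored log-normal true VAF whose mean
    increases with the score.
    """
    effects = effects or EffectConfig()
    if panel is None:
        panel = simulate_cds_panel(seed=seed)
    if not panel:
        raise ValueError("panel must be non-empty")
    rng = substream(seed, "truth")
    variants: list[TruthVariant] = []
    seen: set = set()
    classes = list(effects.consequence_profile)
    probs = np.array([effects.consequence_profile[c] for c in classes])
    for row in cohort:
        age_decades = (row.age_ch - 50.0) / 10.0
        dose_units = row.dose_gbq / effects.dose_unit_gbq
        for gene in panel:
            age_mult = effects.age_effect.get(gene.gene, 1.0) ** age_decades
            for cls, p_cls in zip(classes, probs):
                impact = "truncating" if cls in _TRUNCATING else cls
                dose_mult = (
                    effects.dose_effect.get((gene.gene, impact), 1.0)
                    ** dose_units
                )
                lam = effects.background_rate * p_cls * age_mult * dose_mult
                n_mut = rng.poisson(lam)
                for _ in range(n_mut):
                    for _attempt in range(50):
                        chrom, pos, ref, alt = _draw_variant_alleles(
                            rng, gene, cls
                        )
                        if (row.sample_id, chrom, pos, ref, alt) not in seen:
                            break
                    seen.add((row.sample_id, chrom, pos, ref, alt))
                    cadd = float(
                        rng.normal(effects.cadd_mean[cls], effects.cadd_sd)
                    )
                    cadd = max(0.0, cadd)
                    variants.append(
                        TruthVariant(
                            sample_id=row.sample_id,
                            chrom=chrom,
                            pos=pos,
                            ref=ref,
                            alt=alt,
                            gene=gene.gene,
                            consequence=cls,
                            true_vaf=_draw_vaf(rng, effects, cadd),
                            label="true_CH",
                        )
                    )
    return TruthSet(variants=variants, sample_ids=[r.sample_id for r in cohort])


# ---------------------------------------------------------------- rendering


def _variant_class_of(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    return "insertion" if len(ref) < len(alt) else "deletion"


def _draw_depth(rng, effects: EffectConfig) -> int:
    d = int(round(rng.normal(effects.depth_mean, effects.depth_sd)))
    return int(np.clip(d, effects.depth_min, effects.depth_max))


def _balanced(total: int) -> tuple[int, int]:
    return total - total // 2, total // 2


def _render_true(rng, t: TruthVariant, effects: EffectConfig) -> VariantRecord:
    depth = _draw_depth(rng, effects)
    alt_count = int(math.ceil(t.true_vaf * depth))
    ref_total = depth - alt_count
    ref_fwd = int(rng.binomial(ref_total, 0.5))
    alt_fwd = int(rng.binomial(alt_count, 0.5))
    f1r2 = int(rng.binomial(alt_count, 0.5))
    scores = {}
    if t.consequence != "synonymous":
        scores["CADD"] = round(
            max(0.0, rng.normal(effects.cadd_mean[t.consequence], effects.cadd_sd)), 3
        )
    return VariantRecord(
        sample_id=t.sample_id,
        chrom=t.chrom,
        pos=t.pos,
        ref=t.ref,
        alt=t.alt,
        variant_class=_variant_class_of(t.ref, t.alt),
        depth=depth,
        alt_count=alt_count,
        vaf=alt_count / depth,
        strand_counts=(ref_fwd, ref_total - ref_fwd, alt_fwd, alt_count - alt_fwd),
        orientation_counts=(f1r2, alt_count - f1r2),
        gene=t.gene,
        consequence=t.consequence,
        popaf_exome=float(rng.uniform(0, 2e-4)),
        popaf_genome=float(rng.uniform(0, 2e-4)),
        cosmic_count=0,
        dbsnp_member=False,
        scores=scores,
    )


def _artifact_record(
    rng, sample_id: str, kind: str, panel, mask: RegionMask,
    effects: EffectConfig, recurrent_keys=None, key_index=None,
) -> tuple[VariantRecord, TruthVariant]:
    """Build one artifact call that violates exactly its intended rule.

    All other fields are construction-clean: counts perfectly balanced
    (exact binomial p = 1), popAF ~ 0, depth in the confident range and
    position outside the mask, so first-failure attribution is guaranteed.
    """
    gene = panel[int(rng.integers(len(panel)))]
    chrom, pos, ref, alt = _draw_variant_alleles(rng, gene, "missense")
    vaf = float(rng.uniform(0.008, 0.03))
    depth = _draw_depth(rng, effects)
    popaf_ex = popaf_ge = float(rng.uniform(0, 2e-4))

    if kind == "masked_region":
        iv = mask.intervals[int(rng.integers(len(mask.intervals)))]
        chrom = iv[0]
        pos = int(rng.integers(iv[1] + 1, iv[2] + 1))  # 1-based inside mask
        ref, alt = "A", "G"
    elif kind == "germline_leak":
        vaf = float(np.clip(rng.normal(0.5, 0.03), 0.40, 0.60))
        popaf_ex = float(rng.uniform(0.02, 0.30))
        popaf_ge = float(rng.uniform(0.02, 0.30))
    elif kind == "low_depth":
        depth = int(rng.integers(120, 401))  # never above the 400x cutoff

    alt_count = max(1, int(math.ceil(vaf * depth)))
    alt_count = min(alt_count, depth)
    ref_total = depth - alt_count
    rf, rr = _balanced(ref_total)
    af, ar = _balanced(alt_count)
    f1, f2 = _balanced(alt_count)
    if kind == "orientation_bias":
        alt_count = max(alt_count, 20)
        ref_total = depth - alt_count
        rf, rr = _balanced(ref_total)
        af, ar = _balanced(alt_count)
        f1, f2 = alt_count, 0
    elif kind == "strand_bias":
        alt_count = max(alt_count, 20)
        ref_total = depth - alt_count
        rf, rr = _balanced(ref_total)
        af, ar = alt_count, 0
        f1, f2 = _balanced(alt_count)
    if kind == "recurrent_call":
        idx = key_index if key_index is not None else int(
            rng.integers(len(recurrent_keys))
        )
        chrom, pos, ref, alt = recurrent_keys[idx]

    record = VariantRecord(
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        variant_class=_variant_class_of(ref, alt),
        depth=depth,
        alt_count=alt_count,
        vaf=alt_count / depth,
        strand_counts=(rf, rr, af, ar),
        orientation_counts=(f1, f2),
        gene=gene.gene,
        consequence="missense",
        popaf_exome=popaf_ex,
        popaf_genome=popaf_ge,
        cosmic_count=0,
        dbsnp_member=kind == "germline_leak",
        scores={},
    )
    truth = TruthVariant(
        sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
        gene=gene.gene, consequence="missense",
        true_vaf=record.vaf, label=kind,
    )
    return record, truth


def render_raw_calls(
    truth: TruthSet,
    effects: EffectConfig = None,
    mask: Optional[RegionMask] = None,
    panel: list[GeneModel] = None,
    seed: int = 0,
) -> tuple[dict, TruthSet]:
    """Render truth mutations into raw calls and inject labelled artifacts.

    Returns ``(calls_by_sample, full_truth)`` where ``full_truth`` extends
    the input truth set with one labelled entry per injected artifact.
    True calls get unbiased binomial(0.5) strand/orientation counts, depths
    from the configured panel distribution and alt counts of
    ``ceil(vaf * depth)``, which keeps every true call above the detection
    floor and the confident-count cutoffs by construction.
    """
    effects = effects or EffectConfig()
    if panel is None:
        panel = simulate_cds_panel(seed=seed)
    if mask is None:
        mask = simulate_region_mask(panel, seed=seed)
    rng = substream(seed, "render")
    calls: dict[str, list[VariantRecord]] = {s: [] for s in truth.sample_ids}
    all_truth = list(truth.variants)

    for t in truth.variants:
        calls[t.sample_id].append(_render_true(rng, t, effects))

    # recurrent technical calls: fixed keys hit a configured sample fraction
    recurrent_keys = []
    for _ in range(effects.n_recurrent_keys):
        gene = panel[int(rng.integers(len(panel)))]
        recurrent_keys.append(_draw_variant_alleles(rng, gene, "missense")[:4])

    existing = {(t.sample_id, *t.key) for t in all_truth}
    for sample_id in truth.sample_ids:
        kinds = []
        for kind, rate in effects.artifact_rates.items():
            kinds += [kind] * rng.poisson(rate)
        # each recurrent key independently hits the configured fraction of
        # samples, so its distinct-sample share exceeds the 10% cap
        for key_i, key in enumerate(recurrent_keys):
            if rng.random() < effects.recurrent_sample_fraction:
                kinds.append(("recurrent_call", key_i))
        for kind in kinds:
            key_index = None
            if isinstance(kind, tuple):
                kind, key_index = kind
            for _ in range(50):
                rec, tv = _artifact_record(
                    rng, sample_id, kind, panel, mask, effects,
                    recurrent_keys, key_index,
                )
                if (sample_id, *tv.key) not in existing:
                    break
            if (sample_id, *tv.key) in existing:
                continue  # e.g. a recurrent key colliding with a true call
            existing.add((sample_id, *tv.key))
            calls[sample_id].append(rec)
            all_truth.append(tv)
    return calls, TruthSet(variants=all_truth, sample_ids=truth.sample_ids)


# -------------------------------------------------------------- paired data


def simulate_paired_cohort(
    n_pairs: int = 24,
    drift_sd: float = 0.35,
    seed: int = 0,
    mutation_rate: float = 8.0,
    add_rate: float = 2.0,
    drop_rate: float = 0.10,
    effects: EffectConfig = None,
    panel: list[GeneModel] = None,
):
    """Pre/post-treatment sample pairs with drifting clone sizes.

    Each patient carries ``Poisson(mutation_rate)`` pre-treatment clones;
    post-treatment VAFs are the pre values perturbed by multiplicative
    log-normal noise ``exp(N(0, drift_sd))``, clones are dropped with
    probability ``drop_rate`` (or when drifting below the detection floor)
    and ``Poisson(add_rate)`` new clones appear.  Returns
    ``(cohort_rows, variants_by_sample)`` where post rows carry the
    ``paired_pre_sample`` link.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    effects = effects or EffectConfig()
    if panel is None:
        panel = simulate_cds_panel(seed=seed)
    rng = substream(seed, "paired")
    rows: list[CohortRow] = []
    variants: dict[str, list[VariantRecord]] = {}

    def _mk_record(sample_id, chrom, pos, ref, alt, gene, cls, vaf):
        depth = _draw_depth(rng, effects)
        alt_count = min(depth, int(math.ceil(vaf * depth)))
        rf, rr = _balanced(depth - alt_count)
        af, ar = _balanced(alt_count)
        return VariantRecord(
            sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
            variant_class=_variant_class_of(ref, alt),
            depth=depth, alt_count=alt_count, vaf=alt_count / depth,
            strand_counts=(rf, rr, af, ar),
            orientation_counts=_balanced(alt_count),
            gene=gene, consequence=cls,
        )

    classes = list(effects.consequence_profile)
    probs = np.array([effects.consequence_profile[c] for c in classes])
    for i in range(n_pairs):
        pre_id, post_id = f"PRE{i + 1:03d}", f"POST{i + 1:03d}"
        age = float(_truncated_normal(rng, 52.0, 13.0, 20.0, 1)[0])
        dose = float(rng.uniform(1.11, 7.4))
        elapsed = float(_truncated_normal(rng, 40.0, 25.0, 12.0, 1)[0])
        sex = "female" if rng.random() < 0.85 else "male"
        rows.append(CohortRow(pre_id, age, sex, False, 0.0))
        rows.append(
            CohortRow(
                post_id, age + elapsed / 12.0, sex, False, dose,
                age_rait=age, elapsed_months=elapsed,
                paired_pre_sample=pre_id,
            )
        )
        pre_vars, post_vars = [], []
        seen = set()
        for _ in range(rng.poisson(mutation_rate)):
            gene = panel[int(rng.integers(len(panel)))]
            cls = classes[int(rng.choice(len(classes), p=probs))]
            for _attempt in range(50):
                chrom, pos, ref, alt = _draw_variant_alleles(rng, gene, cls)
                if (chrom, pos, ref, alt) not in seen:
                    break
            seen.add((chrom, pos, ref, alt))
            vaf_pre = _draw_vaf(rng, effects, 15.0)
            pre_vars.append(
                _mk_record(pre_id, chrom, pos, ref, alt, gene.gene, cls, vaf_pre)
            )
            if rng.random() < drop_rate:
                continue
            if drift_sd == 0:
                # exact carry-over: the post call reproduces the pre call
                post_vars.append(pre_vars[-1].copy(sample_id=post_id))
                continue
            vaf_post = vaf_pre * math.exp(rng.normal(0.0, drift_sd))
            if vaf_post <= effects.vaf_floor:
                continue
            post_vars.append(
                _mk_record(post_id, chrom, pos, ref, alt, gene.gene, cls, vaf_post)
            )
        for _ in range(rng.poisson(add_rate)):
            gene = panel[int(rng.integers(len(panel)))]
            cls = classes[int(rng.choice(len(classes), p=probs))]
            for _attempt in range(50):
                chrom, pos, ref, alt = _draw_variant_alleles(rng, gene, cls)
                if (chrom, pos, ref, alt) not in seen:
                    break
            seen.add((chrom, pos, ref, alt))
            post_vars.append(
                _mk_record(
                    post_id, chrom, pos, ref, alt, gene.gene, cls,
                    _draw_vaf(rng, effects, 15.0),
                )
            )
        variants[pre_id] = pre_vars
        variants[post_id] = post_vars
    return rows, variants
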