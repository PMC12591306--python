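"""Readers and writers for the pipeline's file dialects.

VCF is read with cyvcf2 and written by a minimal emitter of the same
dialect.  The per-allele INFO contract (all ``Number=A`` unless noted):

===========  =====================================================
key          meaning
===========  =====================================================
DP           total consensus depth (Number=1)
AO           alternate-supporting reads
SRF / SRR    reference forward / reverse reads (Number=1)
SAF / SAR    alternate forward / reverse reads
F1R2 / F2R1  alternate read-pair orientation counts
GENE         gene symbol
CSQ          consequence class (controlled vocabulary)
HGVSP        protein change, HGVS-p short form
GNOMAD_AF_EX / GNOMAD_AF_GE   population allele frequencies
COSMIC_CNT   COSMIC occurrence count
DBSNP        dbSNP membership flag (0/1)
CADD (etc.)  pathogenicity scores, one key per score
===========  =====================================================

Cohort tables are TSV with columns ``sample_id, age_ch, age_rait, sex,
smoking, dose_gbq, elapsed_months, paired_pre_sample``; masks are BED
(0-based half-open); gene panels are a CDS FASTA plus a coordinate TSV.
Internally all positions are 1-based; BED is converted once at read time.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .records import CONSEQUENCES, CohortRow, GeneModel, RegionMask, VariantRecord

__all__ = [
    "read_variant_calls",
    "write_variant_calls",
    "read_cohort",
    "write_cohort",
    "read_region_mask",
    "write_region_mask",
    "read_gene_panel",
    "write_gene_panel",
    "read_variant_table",
    "write_variant_table",
]

SCORE_KEYS = ("CADD", "DANN", "REVEL", "SIFT", "PROVEAN", "METALR")

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total consensus depth">
##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate observation count">
##INFO=<ID=SRF,Number=1,Type=Integer,Description="Reference forward reads">
##INFO=<ID=SRR,Number=1,Type=Integer,Description="Reference reverse reads">
##INFO=<ID=SAF,Number=A,Type=Integer,Description="Alternate forward reads">
##INFO=<ID=SAR,Number=A,Type=Integer,Description="Alternate reverse reads">
##INFO=<ID=F1R2,Number=A,Type=Integer,Description="Alt F1R2 pairs">
##INFO=<ID=F2R1,Number=A,Type=Integer,Description="Alt F2R1 pairs">
##INFO=<ID=GENE,Number=A,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=A,Type=String,Description="Consequence class">
##INFO=<ID=HGVSP,Number=A,Type=String,Description="Protein change">
##INFO=<ID=GNOMAD_AF_EX,Number=A,Type=Float,Description="gnomAD exome AF">
##INFO=<ID=GNOMAD_AF_GE,Number=A,Type=Float,Description="gnomAD genome AF">
##INFO=<ID=COSMIC_CNT,Number=A,Type=Integer,Description="COSMIC occurrences">
##INFO=<ID=DBSNP,Number=A,Type=Integer,Description="dbSNP membership">
{score_lines}\
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _variant_class(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) < len(alt):
        return "insertion"
    if len(ref) > len(alt):
        return "deletion"
    return "MNV"


def _per_allele(value, i: int, n_alt: int):
    """Pick the i-th entry of a Number=A INFO value from cyvcf2."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return value[i] if i < len(value) else None
    if isinstance(value, str) and n_alt > 1:
        parts = value.split(",")
        return parts[i] if i < len(parts) else None
    return value if (n_alt == 1 or i == 0) else None


def read_variant_calls(path, sample_id: str) -> list[VariantRecord]:
    """Read one sample's calls, one record per ALT allele.

    Multi-allelic sites are split; per-allele INFO entries are matched by
    index.  Raises ``ValueError`` naming the field if DP or AO is missing.
    """
    out: list[VariantRecord] = []
    vcf = VCF(str(path))
    try:
        for var in vcf:
            info = var.INFO
            depth = info.get("DP")
            if depth is None:
                raise ValueError(
                    f"missing DP at {var.CHROM}:{var.POS} in {path}"
                )
            n_alt = len(var.ALT)
            ao = info.get("AO")
            if ao is None:
                raise ValueError(
                    f"missing AO at {var.CHROM}:{var.POS} in {path}"
                )
            srf, srr = info.get("SRF"), info.get("SRR")
            for i, alt in enumerate(var.ALT):
                alt_count = int(_per_allele(ao, i, n_alt))
                saf = _per_allele(info.get("SAF"), i, n_alt)
                sar = _per_allele(info.get("SAR"), i, n_alt)
                strand = None
                if None not in (srf, srr, saf, sar):
                    strand = (int(srf), int(srr), int(saf), int(sar))
                f1r2 = _per_allele(info.get("F1R2"), i, n_alt)
                f2r1 = _per_allele(info.get("F2R1"), i, n_alt)
                orient = None
                if None not in (f1r2, f2r1):
                    orient = (int(f1r2), int(f2r1))
                scores = {}
                for key in SCORE_KEYS:
                    val = _per_allele(info.get(key), i, n_alt)
                    if val is not None and not (
                        isinstance(val, float) and math.isnan(val)
                    ):
                        scores[key] = float(val)
                popaf_ex = _per_allele(info.get("GNOMAD_AF_EX"), i, n_alt)
                popaf_ge = _per_allele(info.get("GNOMAD_AF_GE"), i, n_alt)
                cosmic = _per_allele(info.get("COSMIC_CNT"), i, n_alt)
                dbsnp = _per_allele(info.get("DBSNP"), i, n_alt)
                csq = _per_allele(info.get("CSQ"), i, n_alt) or "other"
                if csq not in CONSEQUENCES:
                    csq = "other"
                out.append(
                    VariantRecord(
                        sample_id=sample_id,
                        chrom=var.CHROM,
                        pos=var.POS,
                        ref=var.REF,
                        alt=alt,
                        variant_class=_variant_class(var.REF, alt),
                        depth=int(depth),
                        alt_count=alt_count,
                        vaf=alt_count / int(depth) if depth else 0.0,
                        strand_counts=strand,
                        orientation_counts=orient,
                        gene=str(_per_allele(info.get("GENE"), i, n_alt) or ""),
                        consequence=str(csq),
                        protein_change=str(
                            _per_allele(info.get("HGVSP"), i, n_alt) or ""
                        ),
                        popaf_exome=None if popaf_ex is None else float(popaf_ex),
                        popaf_genome=None if popaf_ge is None else float(popaf_ge),
                        cosmic_count=None if cosmic is None else int(cosmic),
                        dbsnp_member=None if dbsnp is None else bool(int(dbsnp)),
                        scores=scores,
                    )
                )
    finally:
        vcf.close()
    return out


def _fmt_info(v: VariantRecord) -> str:
    parts = [f"DP={v.depth}", f"AO={v.alt_count}"]
    if v.strand_counts is not None:
        rf, rr, af, ar = v.strand_counts
        parts += [f"SRF={rf}", f"SRR={rr}", f"SAF={af}", f"SAR={ar}"]
    if v.orientation_counts is not None:
        parts += [
            f"F1R2={v.orientation_counts[0]}",
            f"F2R1={v.orientation_counts[1]}",
        ]
    if v.gene:
        parts.append(f"GENE={v.gene}")
    parts.append(f"CSQ={v.consequence}")
    if v.protein_change:
        parts.append(f"HGVSP={v.protein_change}")
    if v.popaf_exome is not None:
        parts.append(f"GNOMAD_AF_EX={v.popaf_exome:.6g}")
    if v.popaf_genome is not None:
        parts.append(f"GNOMAD_AF_GE={v.popaf_genome:.6g}")
    if v.cosmic_count is not None:
        parts.append(f"COSMIC_CNT={v.cosmic_count}")
    if v.dbsnp_member is not None:
        parts.append(f"DBSNP={int(v.dbsnp_member)}")
    for key, val in sorted(v.scores.items()):
        parts.append(f"{key}={val:.6g}")
    return ";".join(parts)


def write_variant_calls(variants: Iterable[VariantRecord], path) -> None:
    """Write one sample's records as an uncompressed VCF (biallelic rows)."""
    variants = sorted(variants, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    score_lines = "".join(
        f'##INFO=<ID={k},Number=A,Type=Float,Description="{k} score">\n'
        for k in SCORE_KEYS
    )
    score_lines += "".join(
        f"##contig=<ID={chrom}>\n"
        for chrom in sorted({v.chrom for v in variants})
    )
    lines = [_VCF_HEADER.format(score_lines=score_lines)]
    for v in variants:
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{_fmt_info(v)}\n"
        )
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------- cohort TSV

_COHORT_COLUMNS = [
    "sample_id",
    "age_ch",
    "age_rait",
    "sex",
    "smoking",
    "dose_gbq",
    "elapsed_months",
    "paired_pre_sample",
]


def read_cohort(path) -> list[CohortRow]:
    """Read the subject covariate table.

    Missing optional values (empty cells) become ``None``, never zero.
    Duplicate sample ids and negative doses raise ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "age_ch", "sex", "smoking", "dose_gbq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id: {dupes}")
    rows = []
    for _, r in df.iterrows():
        dose = float(r["dose_gbq"])
        if dose < 0:
            raise ValueError(
                f"negative dose_gbq for sample {r['sample_id']}: {dose}"
            )
        def opt(col, cast=float):
            val = r.get(col, "")
            return cast(val) if val not in ("", "NA", "nan") else None
        rows.append(
            CohortRow(
                sample_id=r["sample_id"],
                age_ch=float(r["age_ch"]),
                sex=r["sex"],
                smoking=r["smoking"].lower() in ("1", "true", "yes"),
                dose_gbq=dose,
                age_rait=opt("age_rait"),
                elapsed_months=opt("elapsed_months"),
                paired_pre_sample=opt("paired_pre_sample", str),
            )
        )
    return rows


def write_cohort(rows: Iterable[CohortRow], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_COHORT_COLUMNS)
        for r in rows:
            w.writerow(
                [
                    r.sample_id,
                    repr(r.age_ch),
                    "" if r.age_rait is None else repr(r.age_rait),
                    r.sex,
                    int(r.smoking),
                    repr(r.dose_gbq),
                    "" if r.elapsed_months is None else repr(r.elapsed_months),
                    r.paired_pre_sample or "",
                ]
            )


# ----------------------------------------------------------------- BED mask


def read_region_mask(path, flank_bp: int = 5) -> RegionMask:
    """Read a BED3+ file into a flanked, merged region mask."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            intervals.append((chrom, start, end))
    return RegionMask(intervals, flank_bp=flank_bp)


def write_region_mask(intervals: Iterable[tuple[str, int, int]], path) -> None:
    """Write raw (unflanked) intervals as BED3."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# --------------------------------------------------------------- gene panel


def write_gene_panel(panel: Iterable[GeneModel], fasta_path, coords_path) -> None:
    records = []
    rows = []
    for g in panel:
        records.append(
            SeqRecord(Seq(g.cds_sequence), id=g.gene, description="")
        )
        for chrom, start, end in g.exon_coordinates:
            rows.append([g.gene, chrom, start, end, g.strand, g.flank5, g.flank3])
        if not g.exon_coordinates:
            rows.append([g.gene, "", "", "", g.strand, g.flank5, g.flank3])
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(coords_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "chrom", "start", "end", "strand", "flank5", "flank3"])
        w.writerows(rows)


def read_gene_panel(fasta_path, coords_path=None) -> list[GeneModel]:
    coords: dict[str, list] = {}
    meta: dict[str, tuple] = {}
    if coords_path is not None:
        df = pd.read_csv(coords_path, sep="\t", dtype=str, keep_default_na=False)
        for _, r in df.iterrows():
            if r["chrom"]:
                coords.setdefault(r["gene"], []).append(
                    (r["chrom"], int(r["start"]), int(r["end"]))
                )
            meta[r["gene"]] = (r["strand"] or "+", r["flank5"] or "A", r["flank3"] or "A")
    panel = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        strand, f5, f3 = meta.get(rec.id, ("+", "A", "A"))
        panel.append(
            GeneModel(
                gene=rec.id,
                cds_sequence=str(rec.seq),
                exon_coordinates=tuple(coords.get(rec.id, ())),
                strand=strand,
                flank5=f5,
                flank3=f3,
            )
        )
    return panel


# ------------------------------------------------------------- variant TSVs

_VARIANT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "variant_class",
    "depth", "alt_count", "vaf", "strand_counts", "orientation_counts",
    "gene", "consequence", "protein_change", "popaf_exome", "popaf_genome",
    "cosmic_count", "dbsnp_member", "scores", "filter_status",
]


def write_variant_table(variants: Iterable[VariantRecord], path) -> None:
    """Lossless TSV serialization of variant records (round-trip exact)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_VARIANT_COLUMNS)
        for v in variants:
            w.writerow(
                [
                    v.sample_id, v.chrom, v.pos, v.ref, v.alt, v.variant_class,
                    v.depth, v.alt_count, repr(v.vaf),
                    json.dumps(v.strand_counts),
                    json.dumps(v.orientation_counts),
                    v.gene, v.consequence, v.protein_change,
                    "" if v.popaf_exome is None else repr(v.popaf_exome),
                    "" if v.popaf_genome is None else repr(v.popaf_genome),
                    "" if v.cosmic_count is None else v.cosmic_count,
                    "" if v.dbsnp_member is None else int(v.dbsnp_member),
                    json.dumps(v.scores, sort_keys=True),
                    json.dumps(sorted(v.filter_status)),
                ]
            )


def read_variant_table(path) -> list[VariantRecord]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for r in reader:
            strand = json.loads(r["strand_counts"])
            orient = json.loads(r["orientation_counts"])
            out.append(
                VariantRecord(
                    sample_id=r["sample_id"],
                    chrom=r["chrom"],
                    pos=int(r["pos"]),
                    ref=r["ref"],
                    alt=r["alt"],
                    variant_class=r["variant_class"],
                    depth=int(r["depth"]),
                    alt_count=int(r["alt_count"]),
                    vaf=float(r["vaf"]),
                    strand_counts=None if strand is None else tuple(strand),
                    orientation_counts=None if orient is None else tuple(orient),
                    gene=r["gene"],
                    consequence=r["consequence"],
                    protein_change=r["protein_change"],
                    popaf_exome=float(r["popaf_exome"]) if r["popaf_exome"] else None,
                    popaf_genome=float(r["popaf_genome"]) if r["popaf_genome"] else None,
                    cosmic_count=int(r["cosmic_count"]) if r["cosmic_count"] else None,
                    dbsnp_member=bool(int(r["dbsnp_member"])) if r["dbsnp_member"] else None,
                    scores=json.loads(r["scores"]),
                    filter_status=set(json.loads(r["filter_status"])),
                )
            )
    return out
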