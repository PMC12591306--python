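"""Maximum-likelihood dN/dS estimation with trinucleotide context.

Somatic selection on a gene is measured as the ratio of observed to
expected nonsynonymous mutations, where the expectation comes from a
neutral mutation-rate model calibrated on synonymous changes.  The model
here uses 96 strand-collapsed substitution classes (pyrimidine-centred
trinucleotide context x alternate base).  For every gene the full set of
3L possible single-base substitutions is enumerated and each is classified
by codon translation into synonymous, missense or truncating impact
(nonsense plus stop-loss; stop-retaining changes in the stop codon count
as synonymous).  Frameshift indels are outside the substitution model and
do not enter dN/dS.

With per-class neutral rates r_c fitted by Poisson maximum likelihood on
pooled synonymous counts (r_c = observed syn in class c / synonymous
opportunities in class c, empty classes shrunk to the global mean rate),
the expected count of impact class k in gene g is

    E_gk = sum_c r_c * n_gkc,

where n_gkc counts substitutions of class c with impact k in gene g.  The
estimate omega_k = O_gk / E_gk is the Poisson ML ratio; a likelihood-ratio
test of omega_k = 1 (1 df, chi-square reference) gives per-gene p-values,
adjusted per impact class across genes by Benjamini-Hochberg.  omega > 1
indicates positive selection, omega = 1 neutrality, omega < 1 negative
selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import GeneModel, VariantRecord, translate_codon

__all__ = [
    "SiteOpportunities",
    "DnDsEstimate",
    "N_CLASSES",
    "class_index",
    "enumerate_site_opportunities",
    "fit_neutral_context_model",
    "estimate_dnds",
    "estimate_dnds_table",
    "global_dnds",
    "adjust_fdr",
    "count_observed",
    "simulate_counts",
]

IMPACTS = ("synonymous", "missense", "truncating")
N_CLASSES = 96

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYRIMIDINES = "CT"


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def class_index(tri: str, alt: str) -> int:
    """Strand-collapsed substitution class of ``tri[1] -> alt`` in context.

    ``tri`` is the reference trinucleotide around the mutated base.  If the
    central base is a purine the triplet and alternate are
    reverse-complemented, so classes are indexed by
    (central pyrimidine, alt, 5' base, 3' base): 2 x 3 x 4 x 4 = 96.
    """
    if tri[1] not in _PYRIMIDINES:
        alt = _COMP[alt]
        tri = _revcomp(tri)
    ref = tri[1]
    alts = [b for b in _BASES if b != ref]
    return (
        _PYRIMIDINES.index(ref) * 48
        + alts.index(alt) * 16
        + _BASES.index(tri[0]) * 4
        + _BASES.index(tri[2])
    )


def _impact(old_aa: str, new_aa: str) -> str:
    if old_aa == new_aa:
        return "synonymous"
    if new_aa == "*" or old_aa == "*":
        return "truncating"  # nonsense, or stop-loss by convention
    return "missense"


@dataclass
class SiteOpportunities:
    """Counts of possible substitutions per class and impact for one gene.

    ``counts`` has shape (96, 3) with impact columns ordered as
    :data:`IMPACTS`; the total equals 3 x CDS length.
    """

    gene: str
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def by_impact(self) -> dict:
        return {
            impact: float(self.counts[:, k].sum())
            for k, impact in enumerate(IMPACTS)
        }


def enumerate_site_opportunities(gene: GeneModel) -> SiteOpportunities:
    """Exhaustively classify all 3L single-base substitutions of a CDS."""
    seq = gene.cds_sequence
    padded = gene.flank5 + seq + gene.flank3
    counts = np.zeros((N_CLASSES, 3), dtype=float)
    for i, ref in enumerate(seq):
        codon_i, within = divmod(i, 3)
        codon = gene.codon(codon_i)
        old_aa = translate_codon(codon)
        tri = padded[i : i + 3]
        for alt in _BASES:
            if alt == ref:
                continue
            new_codon = codon[:within] + alt + codon[within + 1 :]
            impact = _impact(old_aa, translate_codon(new_codon))
            counts[class_index(tri, alt), IMPACTS.index(impact)] += 1
    return SiteOpportunities(gene=gene.gene, counts=counts)


def fit_neutral_context_model(
    observed_syn: np.ndarray, opportunities: Iterable[SiteOpportunities]
) -> np.ndarray:
    """Per-class neutral rates from pooled synonymous counts.

    ``observed_syn`` is a length-96 vector of synonymous mutation counts
    pooled over genes.  The Poisson ML rate per class is count divided by
    synonymous opportunities; classes without opportunities (or without a
    defined rate) fall back to the global mean rate.
    """
    observed_syn = np.asarray(observed_syn, dtype=float)
    if observed_syn.shape != (N_CLASSES,):
        raise ValueError(f"observed_syn must have shape ({N_CLASSES},)")
    syn_opp = np.zeros(N_CLASSES)
    for opp in opportunities:
        syn_opp += opp.counts[:, 0]
    total_obs = observed_syn.sum()
    if total_obs == 0:
        raise ValueError(
            "no synonymous observations: the neutral model cannot be "
            "calibrated; provide a larger input"
        )
    global_rate = total_obs / syn_opp.sum()
    rates = np.full(N_CLASSES, global_rate)
    ok = syn_opp > 0
    rates[ok] = observed_syn[ok] / syn_opp[ok]
    return rates


@dataclass
class DnDsEstimate:
    """Per-gene selection estimate for one analysis group."""

    gene: str
    group: str
    obs: dict  # impact -> observed count
    exp: dict  # impact -> expected count under neutrality
    omega_mis: float
    omega_tru: float
    p_mis: float
    p_tru: float
    q_mis: float = np.nan
    q_tru: float = np.nan


def _poisson_lrt(obs: float, exp: float) -> tuple[float, float]:
    """(omega_hat, p) for H0: omega = 1 under Poisson counts."""
    if exp <= 0:
        return (np.inf if obs > 0 else np.nan, np.nan)
    omega = obs / exp
    if obs > 0:
        lrt = 2.0 * (obs * np.log(obs / exp) - (obs - exp))
    else:
        lrt = 2.0 * exp
    return omega, float(stats.chi2.sf(max(lrt, 0.0), df=1))


def estimate_dnds(
    observed: dict,
    opp: SiteOpportunities,
    rates: np.ndarray,
    group: str = "all",
) -> DnDsEstimate:
    """Selection estimate for one gene.

    ``observed`` maps impact class to the observed mutation count.  The
    expectation applies gene-level opportunity counts to the neutral
    per-class rates; omega is observed/expected and the p-value a 1-df
    likelihood-ratio test against neutrality.  Genes with zero expectation
    but observed mutations are flagged infinite (p = NaN) and excluded
    from FDR adjustment.
    """
    exp = {
        impact: float(rates @ opp.counts[:, k])
        for k, impact in enumerate(IMPACTS)
    }
    omega_mis, p_mis = _poisson_lrt(observed.get("missense", 0), exp["missense"])
    omega_tru, p_tru = _poisson_lrt(
        observed.get("truncating", 0), exp["truncating"]
    )
    return DnDsEstimate(
        gene=opp.gene,
        group=group,
        obs={k: float(observed.get(k, 0)) for k in IMPACTS},
        exp=exp,
        omega_mis=omega_mis,
        omega_tru=omega_tru,
        p_mis=p_mis,
        p_tru=p_tru,
    )


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def estimate_dnds_table(
    observed_by_gene: dict,
    opps: dict,
    rates: np.ndarray,
    group: str = "all",
) -> list[DnDsEstimate]:
    """Per-gene estimates with BH adjustment per impact class."""
    genes = sorted(opps)
    ests = [
        estimate_dnds(observed_by_gene.get(g, {}), opps[g], rates, group=group)
        for g in genes
    ]
    q_mis = adjust_fdr([e.p_mis for e in ests])
    q_tru = adjust_fdr([e.p_tru for e in ests])
    for e, qm, qt in zip(ests, q_mis, q_tru):
        e.q_mis, e.q_tru = float(qm), float(qt)
    return ests


def global_dnds(estimates: Iterable[DnDsEstimate]) -> float:
    """Group-level dN/dS: summed observed over summed expected
    nonsynonymous counts."""
    obs = exp = 0.0
    for e in estimates:
        obs += e.obs["missense"] + e.obs["truncating"]
        exp += e.exp["missense"] + e.exp["truncating"]
    return obs / exp if exp > 0 else np.nan


# ------------------------------------------------- observed-count utilities


def count_observed(
    variants: Iterable[VariantRecord], panel: list[GeneModel]
) -> tuple[dict, np.ndarray]:
    """Tabulate observed SNVs per gene/impact and synonymous per class.

    Each SNV is located on its gene's CDS (via the gene's genomic span)
    and re-classified from the codon change, so observed counts and
    opportunity counts use identical conventions.  Non-SNVs and variants
    outside a CDS are ignored.
    """
    by_gene: dict[str, GeneModel] = {g.gene: g for g in panel}
    observed: dict[str, dict] = {g.gene: dict.fromkeys(IMPACTS, 0) for g in panel}
    syn_by_class = np.zeros(N_CLASSES)
    for v in variants:
        gene = by_gene.get(v.gene)
        if gene is None or v.variant_class != "SNV":
            continue
        chrom, start, end = gene.exon_coordinates[0]
        if v.chrom != chrom or not (start <= v.pos <= end):
            continue
        off = v.pos - start
        seq = gene.cds_sequence
        if seq[off] != v.ref:
            continue  # annotation/reference mismatch; not classifiable
        codon_i, within = divmod(off, 3)
        codon = gene.codon(codon_i)
        new_codon = codon[:within] + v.alt + codon[within + 1 :]
        impact = _impact(translate_codon(codon), translate_codon(new_codon))
        observed[gene.gene][impact] += 1
        if impact == "synonymous":
            padded = gene.flank5 + seq + gene.flank3
            syn_by_class[class_index(padded[off : off + 3], v.alt)] += 1
    return observed, syn_by_class


def simulate_counts(
    opps: dict,
    rates: np.ndarray,
    omega: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict, np.ndarray]:
    """Draw Poisson mutation counts from the context model.

    ``omega`` maps gene -> (omega_mis, omega_tru); unlisted genes are
    neutral.  Returns observed counts per gene and the pooled synonymous
    per-class vector, in the shapes :func:`fit_neutral_context_model` and
    :func:`estimate_dnds_table` consume.
    """
    rng = rng or np.random.default_rng()
    omega = omega or {}
    observed: dict[str, dict] = {}
    syn_by_class = np.zeros(N_CLASSES)
    for g, opp in opps.items():
        w_mis, w_tru = omega.get(g, (1.0, 1.0))
        syn_counts = rng.poisson(rates * opp.counts[:, 0])
        syn_by_class += syn_counts
        observed[g] = {
            "synonymous": int(syn_counts.sum()),
            "missense": int(rng.poisson(w_mis * rates @ opp.counts[:, 1])),
            "truncating": int(rng.poisson(w_tru * rates @ opp.counts[:, 2])),
        }
    return observed, syn_by_class
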