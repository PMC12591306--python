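"""Subject-level association statistics.

Builds per-subject clonal-hematopoiesis summaries (maximum VAF, CH
presence at a ladder of VAF cutoffs, per-gene presence), assigns dose
groups, and fits the models used to relate CH to age and cumulative
radioiodine dose:

* Firth penalized logistic regression (see :mod:`chclone.firth`) for CH
  presence — sparse outcomes at the 2% and 5% cutoffs make penalization
  essential;
* ordinary least squares on log maximum VAF (percent scale; detected VAFs
  are bounded below by the 0.5% floor, so no pseudocount is needed), with
  age scaled per decade and dose per 1.11 GBq, optionally with an
  age x dose interaction;
* dose-cutoff optimization by the penalized likelihood-ratio trace of a
  dichotomized-dose Firth fit over a candidate grid;
* pairwise gene co-occurrence by two-sided Fisher exact tests with
  Benjamini-Hochberg adjustment;
* pathogenicity-score vs clone-size association (score tertiles plus an
  OLS slope of log VAF on the score).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dnds import adjust_fdr
from .firth import FirthFit, fit_firth_logistic
from .records import CohortRow, VariantRecord

__all__ = [
    "SubjectCH",
    "assign_dose_group",
    "max_vaf_per_individual",
    "ch_presence",
    "build_subject_table",
    "fit_ch_presence_model",
    "fit_log_vaf_regression",
    "optimize_dose_cutoff",
    "pairwise_cooccurrence",
    "pathogenicity_vaf_association",
]

DOSE_GROUPS = ("control", "low", "high")


def assign_dose_group(dose_gbq: float, cutoff_gbq: float = 7.4) -> str:
    """0 GBq -> control; (0, cutoff) -> low; >= cutoff -> high."""
    if dose_gbq < 0:
        raise ValueError(f"dose must be >= 0, got {dose_gbq}")
    if dose_gbq == 0:
        return "control"
    return "high" if dose_gbq >= cutoff_gbq else "low"


@dataclass
class SubjectCH:
    """Per-subject CH summary derived from filtered variants."""

    sample_id: str
    max_vaf: Optional[float]  # None when no mutations survive filtering
    max_vaf_variant: Optional[tuple] = None  # deterministic tie witness
    ch_present: dict = field(default_factory=dict)  # cutoff -> bool
    gene_presence: dict = field(default_factory=dict)  # (gene, cutoff) -> bool
    n_mutations: int = 0


def max_vaf_per_individual(
    variants: Iterable[VariantRecord],
    sample_id: str,
    cutoffs: Sequence[float] = (0.005, 0.01, 0.02, 0.05),
) -> SubjectCH:
    """Summarize one subject's filtered mutations.

    The maximum VAF is the largest mutation VAF; ties are broken by the
    lowest (chrom, pos) so the witness variant is deterministic.
    """
    variants = list(variants)
    subj = SubjectCH(sample_id=sample_id, max_vaf=None, n_mutations=len(variants))
    if variants:
        best = min(variants, key=lambda v: (-v.vaf, v.chrom, v.pos))
        subj.max_vaf = best.vaf
        subj.max_vaf_variant = best.key
    for cutoff in cutoffs:
        subj.ch_present[cutoff] = ch_presence(subj, cutoff)
        for v in variants:
            gene = v.gene
            if gene:
                key = (gene, cutoff)
                subj.gene_presence[key] = subj.gene_presence.get(key, False) or (
                    v.vaf > cutoff
                )
    return subj


def ch_presence(subject: SubjectCH, cutoff: float) -> bool:
    """CH present iff the maximum VAF strictly exceeds the cutoff."""
    return subject.max_vaf is not None and subject.max_vaf > cutoff


def build_subject_table(
    cohort: Iterable[CohortRow],
    variants_by_sample: dict,
    cutoffs: Sequence[float] = (0.005, 0.01, 0.02, 0.05),
    dose_cutoff_gbq: float = 7.4,
    dose_unit_gbq: float = 1.11,
) -> pd.DataFrame:
    """Merge covariates with per-subject CH summaries.

    Columns include scaled covariates (``age10`` per decade, ``dose_unit``
    per 1.11 GBq), the dose group, ``max_vaf`` (fraction, NaN when absent)
    and one boolean ``ch_gtX`` column per cutoff (percent-labelled).
    """
    rows = []
    for r in cohort:
        subj = max_vaf_per_individual(
            variants_by_sample.get(r.sample_id, ()), r.sample_id, cutoffs
        )
        row = {
            "sample_id": r.sample_id,
            "age_ch": r.age_ch,
            "age10": r.age_ch / 10.0,
            "sex_male": int(r.sex == "male"),
            "smoking": int(r.smoking),
            "dose_gbq": r.dose_gbq,
            "dose_unit": r.dose_gbq / dose_unit_gbq,
            "group": assign_dose_group(r.dose_gbq, dose_cutoff_gbq),
            "prior_rait": int(r.dose_gbq > 0),
            "elapsed_months": (
                np.nan if r.elapsed_months is None else r.elapsed_months
            ),
            "max_vaf": np.nan if subj.max_vaf is None else subj.max_vaf,
            "n_mutations": subj.n_mutations,
        }
        for cutoff in cutoffs:
            row[f"ch_gt{cutoff * 100:g}"] = int(subj.ch_present[cutoff])
        rows.append(row)
    return pd.DataFrame(rows)


def _design(
    df: pd.DataFrame,
    dose_as: str,
    adjust: Sequence[str],
    interaction: bool,
) -> tuple[np.ndarray, list[str]]:
    cols: list[tuple[str, np.ndarray]] = [("intercept", np.ones(len(df)))]
    cols.append(("age10", df["age10"].to_numpy(float)))
    if dose_as == "continuous":
        dose_cols = [("dose_unit", df["dose_unit"].to_numpy(float))]
    elif dose_as == "group":
        dose_cols = [
            ("group_low", (df["group"] == "low").to_numpy(float)),
            ("group_high", (df["group"] == "high").to_numpy(float)),
        ]
    elif dose_as == "none":
        dose_cols = []
    else:
        raise ValueError(f"unknown dose_as {dose_as!r}")
    cols += dose_cols
    if interaction:
        age = df["age10"].to_numpy(float)
        cols += [
            (f"age10:{name}", age * values) for name, values in dose_cols
        ]
    for a in adjust:
        cols.append((a, df[a].to_numpy(float)))
    names = [c[0] for c in cols]
    return np.column_stack([c[1] for c in cols]), names


def fit_ch_presence_model(
    df: pd.DataFrame,
    outcome: str,
    dose_as: str = "group",
    adjust: Sequence[str] = ("sex_male", "smoking"),
    **firth_kwargs,
) -> FirthFit:
    """Firth logistic fit of a CH-presence column on age and dose terms."""
    X, names = _design(df, dose_as, adjust, interaction=False)
    return fit_firth_logistic(
        X, df[outcome].to_numpy(float), names=names, **firth_kwargs
    )


@dataclass
class LinearFit:
    """OLS fit on log maximum VAF (percent scale)."""

    params: pd.Series
    se: pd.Series
    ci: pd.DataFrame
    p: pd.Series
    n_used: int
    n_excluded: int  # subjects without any surviving mutation
    results: object  # statsmodels results, for diagnostics

    def predict_log_vaf(self, grid: pd.DataFrame) -> np.ndarray:
        missing = set(self.params.index) - set(grid.columns)
        if missing:
            raise ValueError(f"grid lacks design columns: {sorted(missing)}")
        return grid[list(self.params.index)].to_numpy(float) @ self.params.to_numpy()


def fit_log_vaf_regression(
    df: pd.DataFrame,
    dose_as: str = "continuous",
    adjust: Sequence[str] = ("sex_male", "smoking"),
    interaction: bool = False,
    level: float = 0.95,
) -> LinearFit:
    """OLS of ln(max VAF in percent) on scaled age/dose covariates.

    Subjects with no surviving mutation have no clone size and are
    excluded (their number is reported on the fit).  Age enters per
    decade, dose per 1.11 GBq; ``interaction`` adds age x dose terms.
    """
    has_vaf = df["max_vaf"].notna()
    used = df[has_vaf]
    X, names = _design(used, dose_as, adjust, interaction)
    if len(used) <= X.shape[1]:
        raise ValueError(
            f"{len(used)} subjects with clones cannot identify "
            f"{X.shape[1]} parameters"
        )
    y = np.log(used["max_vaf"].to_numpy(float) * 100.0)
    res = sm.OLS(y, pd.DataFrame(X, columns=names, index=used.index)).fit()
    ci = res.conf_int(alpha=1 - level)
    ci.columns = ["low", "high"]
    return LinearFit(
        params=res.params,
        se=res.bse,
        ci=ci,
        p=res.pvalues,
        n_used=len(used),
        n_excluded=int((~has_vaf).sum()),
        results=res,
    )


def optimize_dose_cutoff(
    df: pd.DataFrame,
    outcome: str,
    grid: Sequence[float],
    min_group_n: int = 5,
    adjust: Sequence[str] = (),
    criterion: str = "firth_lrt",
) -> tuple[float, pd.DataFrame]:
    """Scan dose cutoffs for the best dichotomized predictor of CH.

    For each candidate cutoff the treated/untreated-by-threshold indicator
    ``dose >= c`` is fitted (Firth logistic, default criterion the
    penalized likelihood-ratio statistic of the indicator; ``"youden"``
    uses sensitivity + specificity - 1).  Candidates leaving fewer than
    ``min_group_n`` subjects on either side are skipped.  Returns the
    argmax cutoff and the full trace.
    """
    y = df[outcome].to_numpy(float)
    dose = df["dose_gbq"].to_numpy(float)
    rows = []
    for c in grid:
        high = (dose >= c).astype(float)
        if high.sum() < min_group_n or (1 - high).sum() < min_group_n:
            rows.append({"cutoff": c, "statistic": np.nan, "n_high": int(high.sum())})
            continue
        if criterion == "firth_lrt":
            base = df.assign(_high=high)
            cols = [np.ones(len(df)), high] + [
                base[a].to_numpy(float) for a in adjust
            ]
            X = np.column_stack(cols)
            names = ["intercept", "high"] + list(adjust)
            fit = fit_firth_logistic(X, y, names=names, ci_method="wald")
            # penalized LRT statistic of the indicator
            stat = float(stats.chi2.isf(fit.p[1], df=1)) if fit.p[1] > 0 else np.inf
        elif criterion == "youden":
            sens = y[high == 1].mean() if high.sum() else 0.0
            spec = 1.0 - y[high == 0].mean() if (1 - high).sum() else 0.0
            stat = sens + spec - 1.0
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        rows.append({"cutoff": c, "statistic": stat, "n_high": int(high.sum())})
    trace = pd.DataFrame(rows)
    if trace["statistic"].isna().all():
        raise ValueError("every candidate cutoff violates min_group_n")
    best = trace.loc[trace["statistic"].idxmax(), "cutoff"]
    return float(best), trace


def pairwise_cooccurrence(
    presence: pd.DataFrame,
) -> pd.DataFrame:
    """Gene-pair co-occurrence by two-sided Fisher exact tests.

    ``presence`` is a subjects x genes boolean frame (mutation presence at
    one VAF cutoff).  Returns one row per unordered pair with the 2x2
    table, odds ratio, exact p and BH q.
    """
    genes = [g for g in presence.columns if presence[g].any()]
    if len(genes) < 2:
        raise ValueError("need at least two genes with mutations")
    rows = []
    for a, b in combinations(genes, 2):
        pa = presence[a].astype(bool)
        pb = presence[b].astype(bool)
        both = int((pa & pb).sum())
        only_a = int((pa & ~pb).sum())
        only_b = int((~pa & pb).sum())
        neither = int((~pa & ~pb).sum())
        oddsr, p = stats.fisher_exact(
            [[both, only_a], [only_b, neither]], alternative="two-sided"
        )
        rows.append(
            {
                "gene_a": a, "gene_b": b, "both": both, "only_a": only_a,
                "only_b": only_b, "neither": neither,
                "odds_ratio": oddsr, "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = adjust_fdr(out["p"].to_numpy())
    return out.sort_values("p", ignore_index=True)


def pathogenicity_vaf_association(
    variants: Iterable[VariantRecord],
    score_name: str = "CADD",
) -> dict:
    """Relate a pathogenicity score to clone size across mutations.

    Scored mutations are split into empirical tertiles (rank-based, so a
    9-mutation input yields 3/3/3); the summary reports per-tertile VAF
    quartiles plus an OLS slope of ln(VAF%) on the score with its p-value.
    """
    scored = [v for v in variants if score_name in v.scores]
    if len(scored) < 3:
        raise ValueError(f"need >= 3 mutations with a {score_name} score")
    s = np.array([v.scores[score_name] for v in scored])
    if np.ptp(s) == 0:
        raise ValueError("no score variation: tertiles undefined")
    vaf = np.array([v.vaf for v in scored]) * 100.0
    order = np.argsort(s, kind="stable")
    tertile = np.empty(len(s), dtype=int)
    # rank-based assignment: lowest third -> T1, middle -> T2, top -> T3
    splits = np.array_split(order, 3)
    for t, idx in enumerate(splits):
        tertile[idx] = t + 1
    per_tertile = {
        f"T{t}": {
            "n": int((tertile == t).sum()),
            "median_vaf_pct": float(np.median(vaf[tertile == t])),
            "q1_vaf_pct": float(np.percentile(vaf[tertile == t], 25)),
            "q3_vaf_pct": float(np.percentile(vaf[tertile == t], 75)),
        }
        for t in (1, 2, 3)
    }
    X = sm.add_constant(s)
    res = sm.OLS(np.log(vaf), X).fit()
    return {
        "score": score_name,
        "n_scored": len(scored),
        "tertiles": per_tertile,
        "slope": float(res.params[1]),
        "slope_p": float(res.pvalues[1]),
    }
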