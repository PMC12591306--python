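"""End-to-end orchestration of the CH analysis stages.

Each stage function takes in-memory objects and returns in-memory results;
``run_all`` chains them on a fully synthetic cohort and writes per-stage
TSVs plus a JSON run manifest (config hash + seed) to an output directory.
The command-line interface in :mod:`chclone.cli` is a thin wrapper over
these functions.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as chio
from .association import (
    build_subject_table,
    fit_ch_presence_model,
    fit_log_vaf_regression,
    pathogenicity_vaf_association,
)
from .config import PipelineConfig
from .dnds import (
    count_observed,
    enumerate_site_opportunities,
    estimate_dnds_table,
    fit_neutral_context_model,
    global_dnds,
)
from .drivers import classify_archpd, load_default_resources
from .filters import run_filter_pipeline
from .longitudinal import pair_variants, summarize_dynamics
from .simulate import (
    CohortSimParams,
    EffectConfig,
    render_raw_calls,
    simulate_cds_panel,
    simulate_cohort,
    simulate_paired_cohort,
    simulate_region_mask,
    simulate_truth_mutations,
)

log = logging.getLogger(__name__)

__all__ = ["simulate_stage", "filter_stage", "classify_stage",
           "dnds_stage", "associate_stage", "longitudinal_stage", "run_all"]


def simulate_stage(config: PipelineConfig, seed: int, params=None, effects=None):
    """Generate cohort, panel, mask, truth and raw calls."""
    params = params or CohortSimParams()
    effects = effects or EffectConfig(vaf_floor=config.vaf_floor)
    cohort = simulate_cohort(params, seed=seed)
    panel = simulate_cds_panel(seed=seed)
    mask = simulate_region_mask(panel, seed=seed, flank_bp=config.mask_flank_bp)
    truth = simulate_truth_mutations(cohort, effects, panel, seed=seed)
    calls, full_truth = render_raw_calls(truth, effects, mask, panel, seed=seed)
    return {
        "cohort": cohort, "panel": panel, "mask": mask,
        "truth": full_truth, "calls": calls,
    }


def filter_stage(calls: dict, mask, config: PipelineConfig):
    filtered, audit = run_filter_pipeline(calls, mask=mask, config=config)
    log.info(
        "filtering: %d in, %d retained, removals %s",
        audit.n_input, audit.n_retained, dict(audit.removed_by_filter),
    )
    return filtered, audit


def classify_stage(filtered: dict, resources=None) -> pd.DataFrame:
    """ARCH-PD classification of every retained nonsynonymous variant."""
    res = resources or load_default_resources()
    rows = []
    for sample_id, variants in filtered.items():
        for v in variants:
            call = (
                classify_archpd(v, res)
                if v.consequence != "synonymous"
                else None
            )
            rows.append(
                {
                    "sample_id": sample_id, "chrom": v.chrom, "pos": v.pos,
                    "ref": v.ref, "alt": v.alt, "gene": v.gene,
                    "consequence": v.consequence, "vaf": v.vaf,
                    "is_driver": bool(call and call.is_driver),
                    "criterion": call.criterion if call else "none",
                }
            )
    return pd.DataFrame(rows)


def dnds_stage(filtered: dict, panel, cohort, dose_cutoff_gbq: float = 7.4):
    """Per-gene dN/dS within each dose group and overall."""
    from .association import assign_dose_group

    opps = {g.gene: enumerate_site_opportunities(g) for g in panel}
    group_of = {
        r.sample_id: assign_dose_group(r.dose_gbq, dose_cutoff_gbq)
        for r in cohort
    }
    results = {}
    for group in ("all", "control", "low", "high"):
        variants = [
            v
            for sample_id, vs in filtered.items()
            for v in vs
            if group == "all" or group_of.get(sample_id) == group
        ]
        observed, syn_by_class = count_observed(variants, panel)
        if syn_by_class.sum() == 0:
            log.warning("no synonymous variants in group %s; skipped", group)
            continue
        rates = fit_neutral_context_model(syn_by_class, opps.values())
        ests = estimate_dnds_table(observed, opps, rates, group=group)
        results[group] = {"estimates": ests, "global_dnds": global_dnds(ests)}
    return results


def associate_stage(cohort, filtered: dict, config: PipelineConfig):
    """Subject-level models: CH presence (Firth) and log-VAF OLS."""
    df = build_subject_table(
        cohort, filtered, cutoffs=config.vaf_cutoffs,
        dose_cutoff_gbq=config.dose_cutoff_gbq,
        dose_unit_gbq=config.dose_unit_gbq,
    )
    model_rows = []
    for cutoff in config.vaf_cutoffs:
        outcome = f"ch_gt{cutoff * 100:g}"
        fit = fit_ch_presence_model(df, outcome, dose_as="group")
        for name, coef, (lo, hi), p in zip(
            fit.names, fit.coef, fit.ci, fit.p
        ):
            model_rows.append(
                {
                    "model": f"firth:{outcome}", "predictor": name,
                    "estimate": coef, "or": float(np.exp(coef)),
                    "ci_low": lo, "ci_high": hi, "p": p, "n": len(df),
                }
            )
    linear = fit_log_vaf_regression(df, dose_as="continuous", interaction=True)
    for name in linear.params.index:
        model_rows.append(
            {
                "model": "ols:log_max_vaf", "predictor": name,
                "estimate": linear.params[name], "or": float("nan"),
                "ci_low": linear.ci.loc[name, "low"],
                "ci_high": linear.ci.loc[name, "high"],
                "p": linear.p[name], "n": linear.n_used,
            }
        )
    scored = [v for vs in filtered.values() for v in vs if "CADD" in v.scores]
    cadd = (
        pathogenicity_vaf_association(scored, "CADD")
        if len(scored) >= 3 and len({v.scores["CADD"] for v in scored}) > 1
        else None
    )
    return df, pd.DataFrame(model_rows), cadd


def longitudinal_stage(config: PipelineConfig, seed: int, n_pairs: int = 24):
    rows, variants = simulate_paired_cohort(n_pairs=n_pairs, seed=seed)
    paired = []
    by_id = {r.sample_id: r for r in rows}
    for r in rows:
        if r.paired_pre_sample:
            paired += pair_variants(
                variants[r.paired_pre_sample], variants[r.sample_id],
                patient_id=r.paired_pre_sample,
                months_between=r.elapsed_months,
            )
    table, means = summarize_dynamics(paired)
    return table, means


def _dnds_frame(results: dict) -> pd.DataFrame:
    rows = []
    for group, block in results.items():
        for e in block["estimates"]:
            rows.append(
                {
                    "group": group, "gene": e.gene,
                    "obs_syn": e.obs["synonymous"],
                    "obs_mis": e.obs["missense"],
                    "obs_tru": e.obs["truncating"],
                    "exp_mis": e.exp["missense"],
                    "exp_tru": e.exp["truncating"],
                    "omega_mis": e.omega_mis, "omega_tru": e.omega_tru,
                    "p_mis": e.p_mis, "p_tru": e.p_tru,
                    "q_mis": e.q_mis, "q_tru": e.q_tru,
                }
            )
    return pd.DataFrame(rows)


def run_all(config: PipelineConfig, seed: int, outdir) -> dict:
    """Full synthetic-cohort run; writes per-stage outputs to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_stage(config, seed)
    chio.write_cohort(sim["cohort"], out / "cohort.tsv")
    chio.write_region_mask(sim["mask"].raw_intervals, out / "mask.bed")
    chio.write_gene_panel(sim["panel"], out / "panel.fasta", out / "panel_coords.tsv")

    filtered, audit = filter_stage(sim["calls"], sim["mask"], config)
    all_filtered = [v for vs in filtered.values() for v in vs]
    chio.write_variant_table(all_filtered, out / "filtered_variants.tsv")
    (out / "filter_audit.json").write_text(json.dumps(audit.to_dict(), indent=2))

    drivers = classify_stage(filtered)
    drivers.to_csv(out / "driver_calls.tsv", sep="\t", index=False)

    dnds_results = dnds_stage(
        filtered, sim["panel"], sim["cohort"], config.dose_cutoff_gbq
    )
    _dnds_frame(dnds_results).to_csv(out / "dnds.tsv", sep="\t", index=False)

    subjects, models, cadd = associate_stage(sim["cohort"], filtered, config)
    subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
    models.to_csv(out / "association_models.tsv", sep="\t", index=False)

    paired_table, paired_means = longitudinal_stage(config, seed)
    paired_table.to_csv(out / "longitudinal_counts.tsv", sep="\t", index=False)

    manifest = {
        "seed": seed,
        "config_digest": config.digest(),
        "n_subjects": len(sim["cohort"]),
        "n_raw_calls": audit.n_input,
        "n_retained": audit.n_retained,
        "paired_means": paired_means,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "sim": sim, "filtered": filtered, "audit": audit,
        "drivers": drivers, "dnds": dnds_results, "subjects": subjects,
        "models": models, "cadd": cadd, "paired_means": paired_means,
    }
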