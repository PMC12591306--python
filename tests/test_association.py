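"""Subject-level statistics: dose groups, CH presence, regressions,
cutoff optimization, co-occurrence, pathogenicity association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chclone.association import (
    assign_dose_group,
    build_subject_table,
    ch_presence,
    fit_log_vaf_regression,
    max_vaf_per_individual,
    optimize_dose_cutoff,
    pairwise_cooccurrence,
    pathogenicity_vaf_association,
)
from chclone.records import CohortRow


class TestDoseGroup:
    @pytest.mark.parametrize(
        "dose,group",
        [(0.0, "control"), (1.2, "low"), (3.7, "low"), (7.39, "low"),
         (7.4, "high"), (30.0, "high")],
    )
    def test_boundaries(self, dose, group):
        assert assign_dose_group(dose) == group

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assign_dose_group(-0.1)


class TestMaxVaf:
    def test_maximum_selected(self, variant_factory):
        subj = max_vaf_per_individual(
            [variant_factory(vaf=0.006, alt_count=12),
             variant_factory(pos=9, vaf=0.021, alt_count=42)],
            "S1",
        )
        assert subj.max_vaf == pytest.approx(0.021)

    def test_no_mutations_is_missing(self):
        subj = max_vaf_per_individual([], "S1")
        assert subj.max_vaf is None
        assert not ch_presence(subj, 0.005)

    def test_tie_broken_by_lowest_position(self, variant_factory):
        subj = max_vaf_per_individual(
            [variant_factory(pos=900, vaf=0.01, alt_count=20),
             variant_factory(pos=100, vaf=0.01, alt_count=20)],
            "S1",
        )
        assert subj.max_vaf_variant[1] == 100

    @pytest.mark.parametrize("max_vaf,cutoff,present", [
        (0.020, 0.02, False),   # strictly greater than
        (0.021, 0.02, True),
        (0.005, 0.005, False),
    ])
    def test_presence_is_strict(self, variant_factory, max_vaf, cutoff, present):
        subj = max_vaf_per_individual(
            [variant_factory(vaf=max_vaf, alt_count=int(max_vaf * 2000))],
            "S1",
        )
        assert ch_presence(subj, cutoff) == present

    def test_prevalence_monotone_in_cutoff(self, variant_factory, rng):
        variants_by_sample = {}
        rows = []
        for i in range(40):
            sid = f"S{i}"
            rows.append(CohortRow(sid, 50.0, "female", False, 0.0))
            n = int(rng.integers(0, 4))
            variants_by_sample[sid] = [
                variant_factory(
                    sample_id=sid, pos=100 + j,
                    vaf=float(rng.uniform(0.005, 0.2)), alt_count=100,
                )
                for j in range(n)
            ]
        df = build_subject_table(rows, variants_by_sample)
        prev = [df[f"ch_gt{c}"].mean() for c in ("0.5", "1", "2", "5")]
        assert prev == sorted(prev, reverse=True)


class TestLogVafRegression:
    @staticmethod
    def _cohort_frame(rng, n, dose_slope=0.0, age_slope=0.0, sigma=0.8):
        age10 = rng.normal(5.5, 1.4, n)
        dose = rng.choice([0.0, 3.7, 11.1, 22.2], size=n)
        log_vaf = (
            0.2 + age_slope * age10 + dose_slope * (dose / 1.11)
            + rng.normal(0, sigma, n)
        )
        return pd.DataFrame(
            {
                "age10": age10, "dose_gbq": dose, "dose_unit": dose / 1.11,
                "group": ["control" if d == 0 else ("low" if d < 7.4 else "high")
                          for d in dose],
                "sex_male": rng.integers(0, 2, n),
                "smoking": rng.integers(0, 2, n),
                "max_vaf": np.exp(log_vaf) / 100.0,
            }
        )

    def test_dose_slope_recovered(self, rng):
        df = self._cohort_frame(rng, 2000, dose_slope=0.1)
        fit = fit_log_vaf_regression(df, dose_as="continuous")
        est, se = fit.params["dose_unit"], fit.se["dose_unit"]
        assert abs(est - 0.1) < 3 * se

    def test_affine_invariance_of_t_statistics(self, rng):
        df = self._cohort_frame(rng, 500, dose_slope=0.05, age_slope=0.1)
        fit1 = fit_log_vaf_regression(df, dose_as="continuous")
        df2 = df.assign(age10=df["age10"] * 10)
        fit2 = fit_log_vaf_regression(df2, dose_as="continuous")
        t1 = fit1.params["age10"] / fit1.se["age10"]
        t2 = fit2.params["age10"] / fit2.se["age10"]
        assert t1 == pytest.approx(t2, rel=1e-10)
        assert fit2.params["age10"] == pytest.approx(fit1.params["age10"] / 10)

    def test_interaction_p_uniform_under_null(self):
        """Null calibration: with no true interaction, its p-value is
        uniform across replicates (KS test at alpha 0.01)."""
        rng = np.random.default_rng(314159)
        pvals = []
        for _ in range(500):
            df = self._cohort_frame(rng, 250, dose_slope=0.08, age_slope=0.1)
            fit = fit_log_vaf_regression(
                df, dose_as="continuous", interaction=True
            )
            pvals.append(fit.p["age10:dose_unit"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_missing_subjects_counted_and_excluded(self, rng):
        df = self._cohort_frame(rng, 60)
        df.loc[:9, "max_vaf"] = np.nan
        fit = fit_log_vaf_regression(df)
        assert fit.n_excluded == 10 and fit.n_used == 50

    def test_underdetermined_errors(self, rng):
        df = self._cohort_frame(rng, 5)
        with pytest.raises(ValueError, match="parameters"):
            fit_log_vaf_regression(df, dose_as="group", interaction=True)


class TestDoseCutoff:
    def test_single_candidate_returned(self, rng):
        dose = rng.uniform(0, 30, 200)
        y = (rng.random(200) < 0.2).astype(float)
        df = pd.DataFrame({"dose_gbq": dose, "y": y})
        best, trace = optimize_dose_cutoff(df, "y", [9.9])
        assert best == 9.9 and len(trace) == 1

    def test_min_group_n_enforced(self, rng):
        dose = rng.uniform(0, 5, 50)
        y = (rng.random(50) < 0.2).astype(float)
        df = pd.DataFrame({"dose_gbq": dose, "y": y})
        with pytest.raises(ValueError, match="min_group_n"):
            optimize_dose_cutoff(df, "y", [40.0], min_group_n=5)

    def test_flat_risk_trace_within_permutation_null(self):
        """With no dose effect the trace's maximum statistic exceeds its
        permutation-null 95th percentile at roughly the nominal 5% rate,
        never consistently."""
        rng = np.random.default_rng(2718)
        grid = [5.0, 10.0, 15.0, 20.0]
        exceed = 0
        n_datasets = 10
        for _ in range(n_datasets):
            dose = rng.uniform(0, 30, 300)
            y = (rng.random(300) < 0.15).astype(float)
            df = pd.DataFrame({"dose_gbq": dose, "y": y})
            _, trace = optimize_dose_cutoff(df, "y", grid)
            null_max = []
            for _ in range(40):
                df_p = pd.DataFrame(
                    {"dose_gbq": dose, "y": rng.permutation(y)}
                )
                _, t = optimize_dose_cutoff(df_p, "y", grid)
                null_max.append(t["statistic"].max())
            exceed += trace["statistic"].max() > np.percentile(null_max, 95)
        # Binomial(10, 0.05): P(X > 3) < 0.002
        assert exceed <= 3


class TestCooccurrence:
    def test_fisher_p_matches_hypergeometric_enumeration(self):
        presence = pd.DataFrame(
            {
                "A": [True] * 10 + [False] * 90,
                "B": [True] * 5 + [False] * 5 + [True] * 5 + [False] * 85,
            }
        )
        out = pairwise_cooccurrence(presence)
        row = out.iloc[0]
        assert (row["both"], row["only_a"], row["only_b"], row["neither"]) == (
            5, 5, 5, 85,
        )
        # oracle: two-sided Fisher p by direct hypergeometric enumeration
        M, n, N = 100, 10, 10  # population, successes (A), draws (B)
        probs = [stats.hypergeom.pmf(k, M, n, N) for k in range(0, 11)]
        p_obs = probs[5]
        oracle = sum(p for p in probs if p <= p_obs * (1 + 1e-9))
        assert row["p"] == pytest.approx(oracle, abs=1e-12)

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(55)
        hits = total = 0
        for _ in range(30):
            presence = pd.DataFrame(
                rng.random((80, 6)) < 0.25,
                columns=[f"G{i}" for i in range(6)],
            )
            out = pairwise_cooccurrence(presence)
            hits += (out["p"] < 0.05).sum()
            total += len(out)
        assert hits / total <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / total)

    def test_self_pairs_excluded(self):
        presence = pd.DataFrame({"A": [True, False] * 10, "B": [True] * 20})
        out = pairwise_cooccurrence(presence)
        assert not (out["gene_a"] == out["gene_b"]).any()

    def test_fewer_than_two_genes_rejected(self):
        with pytest.raises(ValueError, match="two genes"):
            pairwise_cooccurrence(pd.DataFrame({"A": [True] * 5}))


class TestPathogenicityAssociation:
    def test_nine_scores_make_equal_tertiles(self, variant_factory):
        variants = [
            variant_factory(pos=i + 1, scores={"CADD": float(i)},
                            vaf=0.01, alt_count=20)
            for i in range(9)
        ]
        out = pathogenicity_vaf_association(variants)
        assert [out["tertiles"][t]["n"] for t in ("T1", "T2", "T3")] == [3, 3, 3]

    def test_positive_coupling_recovered(self, variant_factory, rng):
        variants = []
        for i in range(300):
            score = float(rng.uniform(0, 40))
            vaf_pct = float(
                np.exp(0.03 * score + rng.normal(0, 0.5))
            )
            vaf = min(vaf_pct / 100.0, 0.5)
            variants.append(
                variant_factory(
                    pos=i + 1, scores={"CADD": score}, vaf=vaf,
                    alt_count=int(vaf * 2000),
                )
            )
        out = pathogenicity_vaf_association(variants)
        assert out["slope"] > 0 and out["slope_p"] < 0.05

    def test_constant_scores_rejected(self, variant_factory):
        variants = [
            variant_factory(pos=i + 1, scores={"CADD": 10.0})
            for i in range(5)
        ]
        with pytest.raises(ValueError, match="no score variation"):
            pathogenicity_vaf_association(variants)

    def test_too_few_scored_rejected(self, variant_factory):
        with pytest.raises(ValueError, match=">= 3"):
            pathogenicity_vaf_association(
                [variant_factory(scores={"CADD": 5.0})]
            )
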