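"""dN/dS machinery: opportunity enumeration, neutral model, inference."""

import numpy as np
import pytest
from Bio.Seq import Seq

from chclone.dnds import (
    IMPACTS,
    N_CLASSES,
    adjust_fdr,
    class_index,
    count_observed,
    enumerate_site_opportunities,
    estimate_dnds,
    estimate_dnds_table,
    fit_neutral_context_model,
    global_dnds,
    simulate_counts,
)
from chclone.records import GeneModel
from chclone.simulate import simulate_cds_panel


def brute_force_opportunities(gene: GeneModel) -> dict:
    """Independent oracle: classify each substitution via Biopython."""
    seq = gene.cds_sequence
    counts = dict.fromkeys(IMPACTS, 0)
    for i in range(len(seq)):
        for alt in "ACGT":
            if alt == seq[i]:
                continue
            mutated = seq[:i] + alt + seq[i + 1 :]
            old = str(Seq(seq).translate())
            new = str(Seq(mutated).translate())
            codon = i // 3
            if old[codon] == new[codon]:
                counts["synonymous"] += 1
            elif new[codon] == "*" or old[codon] == "*":
                counts["truncating"] += 1
            else:
                counts["missense"] += 1
    return counts


class TestOpportunities:
    def test_gct_codon_third_position_synonymy(self):
        """Alanine codon GCT: the 3 third-position changes are synonymous,
        the other 6 are missense (brute-forced over all 9)."""
        gene = GeneModel(gene="G", cds_sequence="ATGGCTTGA")
        opp = enumerate_site_opportunities(gene)
        # restrict the oracle to the GCT codon (positions 3..5)
        syn = mis = 0
        for i in range(3, 6):
            for alt in "ACGT":
                ref = gene.cds_sequence[i]
                if alt == ref:
                    continue
                codon = gene.cds_sequence[3:6]
                new = codon[: i - 3] + alt + codon[i - 2 :]
                if str(Seq(new).translate()) == "A":
                    syn += 1
                else:
                    mis += 1
        assert (syn, mis) == (3, 6)

    def test_atg_codon_fully_nonsynonymous(self):
        """Methionine is a single-codon amino acid: all 9 changes of ATG
        are nonsynonymous."""
        gene = GeneModel(gene="G", cds_sequence="ATGATGTGA")
        opp = enumerate_site_opportunities(gene)
        # oracle over the middle ATG codon
        nonsyn = 0
        for i in range(3, 6):
            for alt in "ACGT":
                if alt == gene.cds_sequence[i]:
                    continue
                codon = "ATG"[: i - 3] + alt + "ATG"[i - 2 :]
                if str(Seq(codon).translate()) != "M":
                    nonsyn += 1
        assert nonsyn == 9

    def test_total_is_three_per_base(self, small_panel):
        for g in small_panel:
            opp = enumerate_site_opportunities(g)
            assert opp.total == 3 * len(g.cds_sequence)

    def test_matches_brute_force_oracle_exactly(self):
        panel = simulate_cds_panel(n_genes=6, length_codons=29, seed=77)
        for g in panel:
            opp = enumerate_site_opportunities(g)
            assert opp.by_impact() == pytest.approx(
                brute_force_opportunities(g)
            )

    def test_class_index_strand_collapse(self):
        # a G>A change equals its reverse complement C>T class
        assert class_index("AGT", "A") == class_index("ACT", "T")
        assert 0 <= class_index("TCG", "A") < N_CLASSES


class TestNeutralModel:
    def test_rates_recovered_within_3se(self, rng):
        panel = simulate_cds_panel(n_genes=30, length_codons=500, seed=8)
        opps = {g.gene: enumerate_site_opportunities(g) for g in panel}
        syn_opp = sum(o.counts[:, 0] for o in opps.values())
        assert syn_opp.sum() > 3e4
        true_rate = 0.5  # uniform across classes
        obs = rng.poisson(true_rate * syn_opp)
        rates = fit_neutral_context_model(obs.astype(float), opps.values())
        se = np.sqrt(true_rate / np.maximum(syn_opp, 1))
        ok = syn_opp > 0
        # ~0.3% of classes expected outside 3 SE; allow a handful
        assert (np.abs(rates[ok] - true_rate) < 3 * se[ok]).mean() >= 0.95

    def test_empty_class_falls_back_to_global_mean(self, small_panel):
        opps = [enumerate_site_opportunities(g) for g in small_panel]
        syn_opp = sum(o.counts[:, 0] for o in opps)
        obs = np.ones(N_CLASSES)
        obs[syn_opp == 0] = 0.0
        rates = fit_neutral_context_model(obs, opps)
        global_rate = obs.sum() / syn_opp.sum()
        assert np.allclose(rates[syn_opp == 0], global_rate)

    def test_scale_equivariance(self, small_panel):
        opps = [enumerate_site_opportunities(g) for g in small_panel]
        obs = np.arange(N_CLASSES, dtype=float)
        r1 = fit_neutral_context_model(obs, opps)
        r2 = fit_neutral_context_model(2 * obs, opps)
        assert np.allclose(r2, 2 * r1)

    def test_no_synonymous_observations_errors(self, small_panel):
        opps = [enumerate_site_opportunities(g) for g in small_panel]
        with pytest.raises(ValueError, match="larger input"):
            fit_neutral_context_model(np.zeros(N_CLASSES), opps)


@pytest.fixture(scope="module")
def calibrated():
    panel = simulate_cds_panel(n_genes=8, length_codons=200, seed=21)
    opps = {g.gene: enumerate_site_opportunities(g) for g in panel}
    rates = np.full(N_CLASSES, 0.05)
    return opps, rates


class TestEstimates:

    def test_observed_equal_expected_is_neutral(self, calibrated):
        opps, rates = calibrated
        opp = next(iter(opps.values()))
        exp_mis = float(rates @ opp.counts[:, 1])
        est = estimate_dnds({"missense": exp_mis}, opp, rates)
        assert est.omega_mis == pytest.approx(1.0)
        assert est.p_mis == pytest.approx(1.0, abs=1e-6)

    def test_zero_observed_gives_zero_omega(self, calibrated):
        opps, rates = calibrated
        opp = next(iter(opps.values()))
        est = estimate_dnds({"truncating": 0}, opp, rates)
        assert est.omega_tru == 0.0

    def test_infinite_omega_excluded_from_fdr(self, calibrated):
        opps, rates = calibrated
        opp = next(iter(opps.values()))
        est = estimate_dnds({"missense": 5}, opp, np.zeros(N_CLASSES))
        assert np.isinf(est.omega_mis) and np.isnan(est.p_mis)

    def test_selection_recovery(self, calibrated, rng):
        """omega_tru = 5 at ~50 expected truncating sites: the estimate
        lands in [3, 7] with p < 0.001 in at least 90% of replicates."""
        opps, _ = calibrated
        gene = next(iter(opps))
        e_tru_target = 50.0
        rate = e_tru_target / opps[gene].counts[:, 2].sum()
        rates = np.full(N_CLASSES, rate)
        hits = 0
        reps = 200
        for _ in range(reps):
            obs = int(rng.poisson(5.0 * e_tru_target))
            est = estimate_dnds({"truncating": obs}, opps[gene], rates)
            hits += 3.0 <= est.omega_tru <= 7.0 and est.p_tru < 1e-3
        assert hits / reps >= 0.90

    def test_global_dnds_pools_counts(self, calibrated):
        opps, rates = calibrated
        ests = [
            estimate_dnds(
                {
                    "missense": float(rates @ o.counts[:, 1]),
                    "truncating": float(rates @ o.counts[:, 2]),
                },
                o, rates,
            )
            for o in opps.values()
        ]
        assert global_dnds(ests) == pytest.approx(1.0)


class TestFdr:
    def test_bh_worked_example(self):
        # by hand: q_i = min over j>=i of p_(j) * m / j
        q = adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert np.allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])

    def test_monotone_in_sorted_order(self, rng):
        p = rng.random(50)
        q = adjust_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()


class TestCountObserved:
    def test_observed_counts_match_planted_classes(self, small_panel, variant_factory):
        gene = small_panel[0]
        chrom, start, end = gene.exon_coordinates[0]
        # plant a known synonymous change: find one by brute force
        seq = gene.cds_sequence
        planted = None
        for i in range(3, len(seq) - 3):
            codon_i, within = divmod(i, 3)
            codon = gene.codon(codon_i)
            for alt in "ACGT":
                if alt == seq[i]:
                    continue
                new = codon[:within] + alt + codon[within + 1 :]
                if str(Seq(new).translate()) == str(Seq(codon).translate()):
                    planted = (i, alt)
                    break
            if planted:
                break
        off, alt = planted
        v = variant_factory(
            chrom=chrom, pos=start + off, ref=seq[off], alt=alt,
            gene=gene.gene, consequence="synonymous",
        )
        observed, syn_by_class = count_observed([v], small_panel)
        assert observed[gene.gene]["synonymous"] == 1
        assert syn_by_class.sum() == 1

    def test_simulate_counts_round_trip_neutral(self, rng):
        panel = simulate_cds_panel(n_genes=10, length_codons=250, seed=31)
        opps = {g.gene: enumerate_site_opportunities(g) for g in panel}
        rates = np.full(N_CLASSES, 0.3)
        obs, syn = simulate_counts(opps, rates, rng=rng)
        fitted = fit_neutral_context_model(syn, opps.values())
        ests = estimate_dnds_table(obs, opps, fitted)
        assert 0.9 < global_dnds(ests) < 1.1
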