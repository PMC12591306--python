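"""Filtering rules: boundaries, audit conservation, order invariance."""

import numpy as np
import pytest
from scipy import stats

from chclone.config import PipelineConfig
from chclone.filters import (
    apply_confidence_filters,
    apply_germline_filters,
    apply_recurrence_filter,
    apply_region_mask,
    assess_sequence_bias,
    run_filter_pipeline,
    select_nonsynonymous,
)
from chclone.records import RegionMask


class TestSequenceBias:
    def test_balanced_orientation_passes(self, variant_factory):
        ok, flags = assess_sequence_bias(
            variant_factory(orientation_counts=(10, 10))
        )
        assert ok and not flags

    def test_fully_oriented_fails_with_closed_form_p(self, variant_factory):
        # two-sided exact binomial: p = 2 * 0.5^20
        v = variant_factory(
            alt_count=20, orientation_counts=(20, 0),
            strand_counts=(990, 990, 10, 10),
        )
        ok, flags = assess_sequence_bias(v, alpha_orientation=0.05)
        assert not ok and flags == ["bias_orientation"]
        assert stats.binomtest(20, 20, 0.5).pvalue == pytest.approx(
            2 * 0.5**20
        )

    def test_proportional_strands_pass(self, variant_factory):
        v = variant_factory(strand_counts=(50, 50, 15, 15), alt_count=30)
        ok, flags = assess_sequence_bias(v)
        assert ok

    def test_one_sided_strand_fails(self, variant_factory):
        v = variant_factory(strand_counts=(1000, 1000, 30, 0), alt_count=30)
        ok, flags = assess_sequence_bias(v)
        assert flags == ["bias_strand"]

    def test_missing_counts_untestable_passes(self, variant_factory):
        v = variant_factory(strand_counts=None, orientation_counts=None)
        ok, flags = assess_sequence_bias(v)
        assert ok and flags == ["untestable"]

    def test_significant_but_mild_imbalance_passes(self, variant_factory):
        """Effect-size guard: a 60:40 split at high depth is significant
        but not a bias call."""
        v = variant_factory(
            alt_count=1000, depth=4000, orientation_counts=(600, 400),
            strand_counts=(1500, 1500, 500, 500),
        )
        assert stats.binomtest(600, 1000, 0.5).pvalue < 0.05
        ok, _ = assess_sequence_bias(v)
        assert ok

    def test_negative_counts_rejected(self, variant_factory):
        v = variant_factory()
        v.orientation_counts = (-1, 5)
        with pytest.raises(ValueError):
            assess_sequence_bias(v)


class TestGermline:
    def test_population_frequency_rule(self, variant_factory):
        keep, reason = apply_germline_filters(
            variant_factory(popaf_exome=0.02)
        )
        assert not keep and reason == "germline_popaf"

    def test_vaf35_rule_with_missing_popaf(self, variant_factory):
        v = variant_factory(
            vaf=0.36, alt_count=720, popaf_exome=None, popaf_genome=None
        )
        keep, reason = apply_germline_filters(v)
        assert not keep and reason == "germline_vaf35"

    def test_clean_high_vaf_kept(self, variant_factory):
        v = variant_factory(vaf=0.34, alt_count=680, popaf_exome=0.0001)
        keep, reason = apply_germline_filters(v)
        assert keep

    def test_review_resource_automates_manual_inspection(self, variant_factory):
        v = variant_factory(vaf=0.25, alt_count=500)
        keep, reason = apply_germline_filters(v, review_resource={v.key})
        assert not keep and reason == "germline_review"
        keep, _ = apply_germline_filters(v, review_resource=set())
        assert keep


class TestRegionMaskFilter:
    def test_direct_hit_removed(self, variant_factory):
        mask = RegionMask([("chr1", 99, 100)], flank_bp=0)
        retained, removed = apply_region_mask(
            [variant_factory(pos=100)], mask
        )
        assert not retained and len(removed) == 1

    def test_flank_reach(self, variant_factory):
        mask = RegionMask([("chr1", 105, 120)], flank_bp=5)
        retained, removed = apply_region_mask(
            [variant_factory(pos=104), variant_factory(pos=50)], mask
        )
        assert [v.pos for v in removed] == [104]
        assert [v.pos for v in retained] == [50]

    def test_deletion_span_intersects(self, variant_factory):
        mask = RegionMask([("chr1", 105, 120)], flank_bp=0)
        v = variant_factory(
            pos=103, ref="AAAAA", alt="A", variant_class="deletion"
        )
        _, removed = apply_region_mask([v], mask)
        assert removed  # span 103..107 reaches 1-based 106..

class TestConfidence:
    @pytest.mark.parametrize(
        "depth,alt,vclass,kept",
        [
            (400, 40, "SNV", False),   # depth must strictly exceed 400
            (500, 3, "SNV", True),
            (500, 2, "SNV", False),
            (500, 6, "deletion", True),
            (500, 5, "deletion", False),
            (500, 6, "insertion", True),
        ],
    )
    def test_strict_boundaries(self, variant_factory, depth, alt, vclass, kept):
        v = variant_factory(
            depth=depth, alt_count=alt, vaf=alt / depth, variant_class=vclass,
            strand_counts=None, orientation_counts=None,
        )
        keep, _ = apply_confidence_filters(v)
        assert keep == kept


class TestRecurrence:
    def _make(self, variant_factory, sample, pos):
        return variant_factory(sample_id=sample, pos=pos)

    def test_sample_fraction_rule(self, variant_factory):
        variants = [
            self._make(variant_factory, f"S{i}", 100) for i in range(3)
        ] + [self._make(variant_factory, f"S{i}", 200) for i in range(2)]
        retained, removed = apply_recurrence_filter(
            variants, n_samples=20, fraction=0.10
        )
        # 3/20 = 15% removed everywhere; 2/20 = 10% kept (strict >)
        assert {v.pos for v in removed} == {100}
        assert {v.pos for v in retained} == {200}

    def test_singleton_kept(self, variant_factory):
        retained, removed = apply_recurrence_filter(
            [variant_factory()], n_samples=20
        )
        assert retained and not removed


class TestNonsynonymous:
    def test_synonymous_excluded_but_stream_preserved(self, variant_factory):
        variants = [
            variant_factory(consequence="synonymous"),
            variant_factory(pos=600, consequence="missense"),
        ]
        nonsyn = select_nonsynonymous(variants)
        assert [v.consequence for v in nonsyn] == ["missense"]
        # original stream untouched for dN/dS
        assert len(variants) == 2

    def test_unknown_consequence_retained(self, variant_factory):
        out = select_nonsynonymous([variant_factory(consequence="other")])
        assert len(out) == 1


class TestPipeline:
    def test_empty_input(self, config):
        filtered, audit = run_filter_pipeline({"S1": []}, None, config)
        assert filtered == {"S1": []}
        assert audit.n_input == 0 and audit.check_conservation()

    def test_disabled_thresholds_identity(self, variant_factory):
        cfg = PipelineConfig(
            vaf_floor=1e-9, vaf_germline=1.0, vaf_review=1.0,
            popaf_max=0.999, min_depth_exclusive=0,
            min_alt_snv_exclusive=0, min_alt_indel_exclusive=0,
            recurrence_fraction=1.0,
            alpha_orientation=1e-12, alpha_strand=1e-12,
        )
        variants = {
            "S1": [variant_factory(), variant_factory(pos=7, vaf=0.5,
                                                      alt_count=1000)],
        }
        filtered, audit = run_filter_pipeline(variants, None, cfg)
        assert audit.n_retained == 2

    def test_audit_conservation_and_reasons(self, variant_factory, config):
        mask = RegionMask([("chr1", 5000, 5100)], flank_bp=5)
        variants = {
            "S1": [
                variant_factory(),                         # clean
                variant_factory(pos=5050),                 # masked
                variant_factory(pos=9, popaf_exome=0.05),  # germline
                variant_factory(pos=11, depth=300, alt_count=6, vaf=0.02),
            ],
            # empty samples so no key exceeds the 10% recurrence fraction
            **{f"S{i}": [] for i in range(2, 11)},
        }
        filtered, audit = run_filter_pipeline(variants, mask, config)
        assert audit.check_conservation()
        assert audit.n_retained == 1
        reasons = {k[2]: v[0] for k, v in audit.failures.items()}
        assert reasons == {
            5050: "region_mask", 9: "germline_popaf", 11: "confidence",
        }

    def test_monotonicity_relaxing_popaf_grows_retained(self, variant_factory):
        variants = {
            "S1": [variant_factory(pos=p, popaf_exome=0.005 * p)
                   for p in range(1, 6)],
        }
        sizes = []
        for popaf_max in (0.004, 0.012, 0.03):
            filtered, _ = run_filter_pipeline(
                {s: [v.copy() for v in vs] for s, vs in variants.items()},
                None, PipelineConfig(popaf_max=popaf_max),
            )
            sizes.append(len(filtered["S1"]))
        assert sizes == sorted(sizes)

    def test_retained_set_matches_predicate_oracle(self, variant_factory, rng):
        """The pipeline's retained set equals a brute-force evaluation of
        all predicates, independent of application order."""
        cfg = PipelineConfig()
        mask = RegionMask([("chr1", 300, 320)], flank_bp=5)
        variants = {}
        for s in range(8):
            sample = f"S{s}"
            variants[sample] = []
            for i in range(25):
                pos = int(rng.integers(1, 1000))
                depth = int(rng.integers(200, 3000))
                vaf = float(rng.uniform(0.001, 0.5))
                alt = min(depth, max(1, int(vaf * depth)))
                variants[sample].append(
                    variant_factory(
                        sample_id=sample, pos=pos, depth=depth,
                        alt_count=alt, vaf=alt / depth,
                        popaf_exome=float(rng.choice([0.0, 0.0001, 0.02])),
                        strand_counts=None, orientation_counts=None,
                    )
                )
        copies = {
            s: [v.copy() for v in vs] for s, vs in variants.items()
        }
        filtered, audit = run_filter_pipeline(copies, mask, cfg)
        retained_keys = {
            (v.sample_id, *v.key) for vs in filtered.values() for v in vs
        }

        # brute-force oracle: independent predicate evaluation
        def germline_ok(v):
            return (
                (v.popaf_exome or 0) <= cfg.popaf_max
                and (v.popaf_genome or 0) <= cfg.popaf_max
                and v.vaf <= cfg.vaf_germline
            )

        def confident(v):
            thr = (
                cfg.min_alt_indel_exclusive
                if v.variant_class in ("insertion", "deletion")
                else cfg.min_alt_snv_exclusive
            )
            return v.depth > cfg.min_depth_exclusive and v.alt_count > thr

        post_germ = [
            v for vs in variants.values() for v in vs if germline_ok(v)
        ]
        key_samples = {}
        for v in post_germ:
            key_samples.setdefault(v.key, set()).add(v.sample_id)
        recurrent = {
            k for k, ss in key_samples.items()
            if len(ss) / len(variants) > cfg.recurrence_fraction
        }
        expected = {
            (v.sample_id, *v.key)
            for vs in variants.values()
            for v in vs
            if germline_ok(v)
            and not mask.overlaps_variant(v)
            and confident(v)
            and v.vaf > cfg.vaf_floor
            and v.key not in recurrent
        }
        assert retained_keys == expected
        assert audit.check_conservation()
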