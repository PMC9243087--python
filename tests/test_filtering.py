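"""Two-step contamination-aware filter: criteria, profile, somatic calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonopanel import (
    ContaminationProfile,
    FilterCriteria,
    VariantCall,
    apply_base_criteria,
    build_artifact_pool,
    call_normal_contamination,
    classify_variant_site_origin,
    filter_somatic,
)


def make_call(
    vaf=0.10, depth=600, ref="A", alt="T", maf=0.0, pooled=False, hotspot=False,
    fwd_only=False, one_orientation=False, sample="S1", pos=100, contig="chr1",
):
    alt_total = int(round(vaf * depth))
    fwd = alt_total if fwd_only else alt_total // 2
    f1r2 = alt_total if one_orientation else alt_total // 2
    return VariantCall(
        sample=sample, contig=contig, pos=pos, ref=ref, alt=alt,
        alt_fwd=fwd, alt_rev=alt_total - fwd, depth=depth,
        alt_f1r2=f1r2, alt_f2r1=alt_total - f1r2,
        pop_maf=maf, pooled_artifact=pooled, hotspot=hotspot,
    )


class TestBaseCriteria:
    def test_low_support_below_five_reads(self):
        call = make_call(vaf=4 / 600)
        assert "low_support" in apply_base_criteria(call).reasons
        assert apply_base_criteria(make_call(vaf=5 / 600)).reasons == ()

    def test_common_polymorphism_rejected(self):
        assert "germline_common" in apply_base_criteria(make_call(maf=0.0005)).reasons
        assert "germline_common" not in apply_base_criteria(make_call(maf=0.0004)).reasons

    def test_pooled_artifact_unless_whitelisted_hotspot(self):
        assert "pooled_artifact" in apply_base_criteria(make_call(pooled=True)).reasons
        verdict = apply_base_criteria(make_call(pooled=True, hotspot=True))
        assert "pooled_artifact" not in verdict.reasons

    def test_strand_bias_only_below_low_vaf_cutoff(self):
        # 3% VAF all-forward: the ultra-low-VAF both-strand rule fires
        low = make_call(vaf=0.03, fwd_only=True)
        assert "strand_bias" in apply_base_criteria(low).reasons
        # 8% VAF all-forward, otherwise clean: extra checks are not applied
        high = make_call(vaf=0.08, fwd_only=True)
        assert apply_base_criteria(high).passed

    def test_oxog_orientation_rule_only_for_damage_class(self):
        oxo = make_call(vaf=0.03, ref="C", alt="A", one_orientation=True)
        assert "oxog_artifact" in apply_base_criteria(oxo).reasons
        not_damage = make_call(vaf=0.03, ref="C", alt="T", one_orientation=True)
        assert "oxog_artifact" not in apply_base_criteria(not_damage).reasons
        disabled = apply_base_criteria(oxo, criteria=FilterCriteria(oxog_enabled=False))
        assert "oxog_artifact" not in disabled.reasons

    def test_long_indels_skip_strand_checks(self):
        call = VariantCall(sample="S1", contig="chr1", pos=5, ref="ATTTTTTT", alt="A",
                           alt_fwd=18, alt_rev=0, depth=600)
        assert apply_base_criteria(call).passed

    def test_verdict_pass_iff_no_reasons(self):
        v = apply_base_criteria(make_call())
        assert v.passed and v.decision == "pass"
        v = apply_base_criteria(make_call(maf=0.01))
        assert not v.passed and v.decision == "reject"


class TestContaminationProfile:
    def test_threshold_is_max_included_vaf(self):
        calls = [make_call(vaf=v, pos=100 + i) for i, v in enumerate((0.08, 0.31, 0.02))]
        profile = call_normal_contamination(calls)
        assert profile.threshold == pytest.approx(0.31, abs=1e-3)

    def test_four_read_call_excluded(self):
        profile = call_normal_contamination([make_call(vaf=4 / 600)])
        assert profile.threshold is None

    def test_no_passing_call_gives_absent_threshold(self):
        profile = call_normal_contamination([make_call(maf=0.01, vaf=0.4)])
        assert profile.threshold is None

    def test_mixed_samples_rejected(self):
        with pytest.raises(ValueError):
            call_normal_contamination([make_call(sample="S1"), make_call(sample="S2", pos=7)])


class TestSomaticFilter:
    def test_default_two_percent_tolerance_when_no_contamination(self):
        tumor = [make_call(vaf=0.3)]
        normal = [make_call(vaf=0.015)]
        profile = ContaminationProfile(sample="S1")
        somatic, rejected = filter_somatic(tumor, normal, profile)
        assert len(somatic) == 1 and not rejected

    def test_normal_vaf_above_default_rejected(self):
        tumor = [make_call(vaf=0.3)]
        normal = [make_call(vaf=0.10)]
        somatic, rejected = filter_somatic(tumor, normal, ContaminationProfile(sample="S1"))
        assert not somatic
        assert rejected[0][1].reasons == ("normal_contaminated",)

    def test_contamination_threshold_tolerates_high_normal_vaf(self):
        tumor = [make_call(vaf=0.3)]
        normal = [make_call(vaf=0.10)]
        profile = ContaminationProfile(sample="S1",
                                       contaminated_calls=[make_call(vaf=0.31, pos=999)])
        somatic, rejected = filter_somatic(tumor, normal, profile)
        assert len(somatic) == 1 and not rejected

    def test_threshold_is_inclusive(self):
        tumor = [make_call(vaf=0.3)]
        normal = [make_call(vaf=0.31)]
        profile = ContaminationProfile(sample="S1",
                                       contaminated_calls=[make_call(vaf=0.31, pos=999)])
        somatic, _ = filter_somatic(tumor, normal, profile)
        assert len(somatic) == 1

    def test_missing_normal_site_treated_as_zero(self):
        somatic, _ = filter_somatic([make_call(vaf=0.3)], [], ContaminationProfile(sample="S1"))
        assert len(somatic) == 1


class TestOriginClassification:
    def test_blood_only_shared_and_biopsy(self):
        shared = make_call(vaf=0.3, pos=1)
        biopsy = make_call(vaf=0.2, pos=2)
        blood = make_call(vaf=0.25, pos=3)
        profile = ContaminationProfile(sample="S1", contaminated_calls=[shared, blood])
        origin = classify_variant_site_origin([shared, biopsy], profile)
        assert origin[shared.key] == "shared"
        assert origin[biopsy.key] == "biopsy"
        assert origin[blood.key] == "blood_only"

    def test_empty_profile_all_biopsy(self):
        calls = [make_call(pos=p) for p in (1, 2)]
        origin = classify_variant_site_origin(calls, ContaminationProfile(sample="S1"))
        assert set(origin.values()) == {"biopsy"}


class TestArtifactPool:
    def _sets(self, n_with, n_total, pos=50):
        out = {}
        for i in range(n_total):
            calls = [make_call(sample=f"N{i}", pos=pos)] if i < n_with else []
            out[f"N{i}"] = calls
        return out

    def test_recurrent_site_pooled(self):
        pool = build_artifact_pool(self._sets(5, 10), min_recurrence=3)
        assert ("chr1", 50, "A", "T") in pool

    def test_single_occurrence_not_pooled(self):
        assert not build_artifact_pool(self._sets(1, 10), min_recurrence=3)

    def test_hotspot_whitelisted_out(self):
        pool = build_artifact_pool(self._sets(9, 10), min_recurrence=3,
                                   hotspot_whitelist={("chr1", 50)})
        assert not pool

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            build_artifact_pool(self._sets(5, 10), min_recurrence=1)
        with pytest.raises(ValueError):
            build_artifact_pool({"only": []}, min_recurrence=3)


# -- properties ---------------------------------------------------------

call_strategy = st.builds(
    make_call,
    vaf=st.floats(0.0, 0.6),
    depth=st.integers(20, 800),
    ref=st.sampled_from("ACGT"),
    alt=st.sampled_from("ACGT"),
    maf=st.sampled_from([0.0, 0.0002, 0.0005, 0.01, 0.1]),
    pooled=st.booleans(),
    hotspot=st.booleans(),
    fwd_only=st.booleans(),
    one_orientation=st.booleans(),
)


@settings(max_examples=300, deadline=None)
@given(call_strategy, st.integers(1, 10), st.sampled_from([0.0001, 0.0005, 0.001]))
def test_stricter_criteria_never_convert_reject_to_pass(call, min_alt, maf_cut):
    base = apply_base_criteria(call, criteria=FilterCriteria())
    stricter = apply_base_criteria(
        call,
        criteria=FilterCriteria(
            min_alt_reads=max(5, min_alt + 5), max_population_maf=min(0.0005, maf_cut)
        ),
    )
    if not base.passed:
        assert not stricter.passed


@settings(max_examples=200, deadline=None)
@given(call_strategy)
def test_verdicts_are_deterministic(call):
    assert apply_base_criteria(call) == apply_base_criteria(call)
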