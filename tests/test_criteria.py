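"""Criterion verdicts: published worked examples and structural properties."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsarval import (
    DegenerateInputError,
    ND,
    SyntheticSpec,
    batch_summary,
    evaluate_model,
    evaluate_summary,
    generate_dataset,
    load_table1_fixture,
    load_table2_reference,
    method1_verdict,
    method2_verdict,
    method3_verdict,
    method4_verdict,
    method5_classify,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


class TestMethod1:
    def test_published_valid_model(self):
        v = method1_verdict(0.917, 1.00, 1.00, 0.909, 0.917)
        assert v.outcome == "valid"

    def test_published_invalid_both_ratios_high(self):
        # both relative gaps exceed 0.1 (0.278 and 0.101, strict comparison)
        v = method1_verdict(0.960, 0.98, 1.02, 0.693, 0.863)
        assert v.outcome == "invalid"
        assert v.subcheck("ratio_lt_0.1").passed is False

    def test_perfect_model(self):
        v = method1_verdict(1.0, 1.0, 1.0, 1.0, 1.0)
        assert v.outcome == "valid"
        assert all(sc.passed for sc in v.subchecks)

    def test_negative_ratio_satisfies_rule(self):
        # r0'^2 above r^2 gives a negative gap, which passes "< 0.1"
        v = method1_verdict(0.703, 0.97, 1.01, 0.514, 0.914)
        assert v.subcheck("ratio_lt_0.1").passed is True

    def test_slope_rule_is_a_disjunction(self):
        v = method1_verdict(0.834, 0.74, 1.11, 0.823, 0.818)
        assert v.subcheck("slope_in_band").passed is True

    def test_zero_r2_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            method1_verdict(0.0, 1.0, 1.0, 0.0, 0.0)

    def test_unknown_slopes_propagate_unavailable(self):
        v = method1_verdict(0.9, None, None, 0.88, 0.89)
        assert v.subcheck("slope_in_band").passed is None
        assert v.outcome == "unavailable"


class TestMethod2:
    @pytest.mark.parametrize(
        "rm2,outcome",
        [(0.75, "valid"), (ND, "invalid"), (0.5, "invalid"), (0.51, "valid")],
    )
    def test_threshold(self, rm2, outcome):
        assert method2_verdict(rm2).outcome == outcome


class TestMethod3:
    @pytest.mark.parametrize(
        "ccc,outcome",
        [(0.95, "valid"), (0.8, "invalid"), (-0.25, "invalid")],
    )
    def test_threshold(self, ccc, outcome):
        assert method3_verdict(ccc).outcome == outcome


class TestMethod4:
    @pytest.mark.parametrize(
        "r2,p,outcome",
        [
            (0.917, 0.14, "valid"),
            (0.906, 0.01, "invalid"),
            (0.5, 0.5, "invalid"),
        ],
    )
    def test_joint_rule(self, r2, p, outcome):
        assert method4_verdict(r2, p).outcome == outcome


class TestMethod5:
    @pytest.mark.parametrize(
        "aae,sd,rng,outcome",
        [
            (0.221, 0.110, 4.07, "good"),
            (0.195, 0.146, 2.68, "moderate"),
            (1.630, 1.256, 14.46, "bad"),
        ],
    )
    def test_published_letters(self, aae, sd, rng, outcome):
        assert method5_classify(aae, sd, rng).outcome == outcome

    def test_nonpositive_range_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            method5_classify(0.1, 0.1, 0.0)

    @given(
        st.floats(0.0, 5.0),
        st.floats(0.0, 3.0),
        st.floats(0.1, 15.0),
    )
    @settings(max_examples=500)
    def test_good_and_bad_mutually_exclusive(self, aae, sd, rng):
        v = method5_classify(aae, sd, rng)
        good = v.subcheck("aae_le_0.10_range").passed and v.subcheck(
            "aae3sd_le_0.20_range"
        ).passed
        bad = v.subcheck("aae_gt_0.15_range").passed or v.subcheck(
            "aae3sd_gt_0.25_range"
        ).passed
        assert not (good and bad)
        assert v.outcome in ("good", "moderate", "bad")

    @given(st.floats(0.0, 2.0), st.floats(0.0, 1.0), st.floats(0.5, 10.0),
           st.floats(0.0, 1.0))
    @settings(max_examples=300)
    def test_decreasing_aae_never_degrades_good_to_bad(self, aae, sd, rng, frac):
        before = method5_classify(aae, sd, rng).outcome
        after = method5_classify(aae * frac, sd, rng).outcome
        if before == "good":
            assert after == "good"
        if before == "moderate":
            assert after != "bad"


class TestEvaluateModel:
    def test_perfect_synthetic_model(self):
        ds = generate_dataset(SyntheticSpec(noise_sd=0.0, seed=3))
        rep = evaluate_model(ds)
        for mid in ("m1_golbraikh_tropsha", "m2_rm2", "m3_ccc", "m4_error_ttest"):
            assert rep.verdicts[mid].outcome == "valid"
        assert rep.m5_class == "good"
        assert rep.test_errors.aae == pytest.approx(0.0)

    def test_deterministic_for_fixed_input(self):
        ds = generate_dataset(SyntheticSpec(seed=11))
        a, b = evaluate_model(ds), evaluate_model(ds)
        assert a == b

    def test_error_carries_model_id(self):
        from qsarval import ActivityPairs, ModelDataset

        flat = ModelDataset(
            model_id="flat-exp",
            train=ActivityPairs([1, 1, 1], [1, 2, 3]),
            test=ActivityPairs([1, 2, 3], [1, 2, 3]),
        )
        with pytest.raises(DegenerateInputError, match="flat-exp"):
            evaluate_model(flat)


@pytest.fixture(scope="module")
def fixture_reports():
    return [
        evaluate_summary(rec, ref)
        for rec, ref in zip(load_table1_fixture(), load_table2_reference())
    ]


class TestSummaryModeAndBatch:
    def test_low_r2_count(self, fixture_reports):
        summary = batch_summary(fixture_reports)
        assert summary["r2_below_0.6"] == 7

    def test_rm2_valid_count(self, fixture_reports):
        assert batch_summary(fixture_reports)["m2_rm2"]["valid"] == 26

    def test_m5_letters_match_published_except_boundary_row(self, fixture_reports):
        """Every printed GOOD/MODERATE/BAD letter reproduces from the summary
        inputs except model 30, which sits exactly on the AAE+3SD = 0.2*range
        boundary (0.470 = 0.470) where the published table prints M."""
        letter = {"good": "G", "moderate": "M", "bad": "B"}
        mismatches = {
            rep.model_id: (letter[rep.m5_class], ref.m5_class)
            for rep, ref in zip(fixture_reports, load_table2_reference())
            if letter[rep.m5_class] != ref.m5_class
        }
        assert mismatches == {"30": ("G", "M")}

    def test_summary_without_reference_marks_unavailable(self):
        rep = evaluate_summary(load_table1_fixture()[0])
        assert rep.verdicts["m3_ccc"].outcome == "unavailable"
        assert rep.verdicts["m4_error_ttest"].outcome == "unavailable"
        # the range-based classifier needs no raw data
        assert rep.m5_class == "good"

    def test_ccc_implies_method1_valid_except_documented_exception(
        self, fixture_reports
    ):
        """Models with published CCC > 0.8 pass the slope/ratio rule set,
        with the single exception of model 27 whose ratio terms (0.278,
        0.101) both sit above the 0.1 threshold."""
        exceptions = [
            rep.model_id
            for rep, ref in zip(fixture_reports, load_table2_reference())
            if ref.ccc > 0.8
            and rep.verdicts["m1_golbraikh_tropsha"].outcome != "valid"
        ]
        assert exceptions == ["27"]

    def test_batch_summary_single_perfect_model(self):
        rep = evaluate_model(generate_dataset(SyntheticSpec(noise_sd=0.0, seed=5)))
        summary = batch_summary([rep])
        assert summary["m5_percent"]["good"] == 100
        assert summary["m1_golbraikh_tropsha"]["valid"] == 1

    def test_batch_summary_empty_errors(self):
        from qsarval import InsufficientDataError

        with pytest.raises(InsufficientDataError):
            batch_summary([])
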