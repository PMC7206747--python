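import math

import pytest
from statsmodels.stats.proportion import proportion_confint

from adhf_phenotype import (
    TwoByTwo,
    compare_strategies,
    confusion_matrix,
    discordance_report,
    exact_binomial_ci,
    sensitivity,
    specificity,
)
from adhf_phenotype.evaluation import (
    comparison_to_frame,
    predictive_values,
    render_comparison_markdown,
)


class TestConfusionMatrix:
    def test_perfect_agreement(self):
        ref = {f"A{i}": i < 4 for i in range(10)}
        tt = confusion_matrix(ref, ref)
        assert (tt.tp, tt.fp, tt.fn, tt.tn) == (4, 0, 0, 6)

    def test_all_negative_predictions(self):
        ref = {f"A{i}": i < 3 for i in range(8)}
        preds = {k: False for k in ref}
        tt = confusion_matrix(preds, ref)
        assert (tt.fn, tt.tn) == (3, 5)
        assert tt.n == 8

    def test_reference_without_prediction_is_an_error(self):
        with pytest.raises(ValueError, match="A2"):
            confusion_matrix({"A1": True}, {"A1": True, "A2": False})

    def test_extra_predictions_ignored_with_log(self, caplog):
        import logging

        with caplog.at_level(logging.INFO, logger="adhf_phenotype.evaluation"):
            tt = confusion_matrix({"A1": True, "A9": True}, {"A1": True})
        assert tt.n == 1
        assert "1 predictions outside" in caplog.text

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(tp=-1, fp=0, fn=0, tn=0)


class TestSensitivitySpecificity:
    def test_sensitivity_point_value(self):
        est = sensitivity(TwoByTwo(tp=39, fp=0, fn=1, tn=60))
        assert est.point == pytest.approx(0.975)
        assert est.percent == 97.5

    def test_perfect_sensitivity(self):
        est = sensitivity(TwoByTwo(tp=29, fp=0, fn=0, tn=10))
        assert est.point == 1.0 and est.ci_high == 1.0

    def test_zero_sensitivity_has_zero_lower_bound(self):
        est = sensitivity(TwoByTwo(tp=0, fp=0, fn=5, tn=5))
        assert est.point == 0.0 and est.ci_low == 0.0

    def test_sensitivity_undefined_without_reference_positives(self):
        with pytest.raises(ValueError, match="undefined"):
            sensitivity(TwoByTwo(tp=0, fp=1, fn=0, tn=5))

    def test_perfect_specificity(self):
        est = specificity(TwoByTwo(tp=40, fp=0, fn=0, tn=60))
        assert est.point == 1.0

    def test_specificity_rounding_to_one_decimal(self):
        est = specificity(TwoByTwo(tp=29, fp=1, fn=0, tn=70))
        assert est.point == pytest.approx(70 / 71)
        assert est.percent == 98.6

    def test_zero_specificity(self):
        est = specificity(TwoByTwo(tp=1, fp=3, fn=0, tn=0))
        assert est.point == 0.0

    def test_specificity_undefined_without_reference_negatives(self):
        with pytest.raises(ValueError, match="undefined"):
            specificity(TwoByTwo(tp=3, fp=0, fn=1, tn=0))

    def test_interval_brackets_point(self):
        est = sensitivity(TwoByTwo(tp=7, fp=0, fn=3, tn=5))
        assert est.ci_low <= est.point <= est.ci_high


class TestExactCI:
    def test_zero_successes_closed_form(self):
        low, high = exact_binomial_ci(0, 10)
        assert low == 0.0
        assert high == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-12)
        assert high == pytest.approx(0.3085, abs=5e-5)

    def test_all_successes_upper_bound_is_one(self):
        low, high = exact_binomial_ci(10, 10)
        assert high == 1.0
        assert low == pytest.approx(0.025 ** (1 / 10), abs=1e-12)

    def test_half_successes_bracket_half(self):
        low, high = exact_binomial_ci(5, 10)
        assert low < 0.5 < high

    def test_agrees_with_beta_quantile_oracle_over_grid(self):
        for n in range(1, 51):
            for k in range(n + 1):
                low, high = exact_binomial_ci(k, n)
                olow, ohigh = proportion_confint(k, n, alpha=0.05, method="beta")
                assert math.isclose(low, float(olow), abs_tol=1e-10)
                assert math.isclose(high, float(ohigh), abs_tol=1e-10)

    @pytest.mark.parametrize("k,n,alpha", [(-1, 5, 0.05), (6, 5, 0.05), (0, 0, 0.05),
                                           (1, 5, 0.0), (1, 5, 1.0)])
    def test_invalid_inputs_rejected(self, k, n, alpha):
        with pytest.raises(ValueError):
            exact_binomial_ci(k, n, alpha)


class TestCompareStrategies:
    def test_one_row_per_strategy(self):
        ref = {f"A{i}": i % 2 == 0 for i in range(10)}
        rows = compare_strategies(ref, {"s1": ref, "s2": {k: True for k in ref}},
                                  cohort_label="demo")
        assert len(rows) == 2
        assert {r.strategy for r in rows} == {"s1", "s2"}

    def test_self_comparison_rejected(self):
        ref = {"A1": True, "A2": False}
        with pytest.raises(ValueError, match="itself"):
            compare_strategies(ref, {"reference standard": ref})

    def test_strategy_as_reference_for_table4_shape(self):
        eadhf = {f"A{i}": i < 5 for i in range(10)}
        icd9 = {f"A{i}": i < 3 for i in range(10)}
        rows = compare_strategies(eadhf, {"icd9": icd9}, reference_name="eADHF")
        assert rows[0].reference == "eADHF"
        assert rows[0].sensitivity.point == pytest.approx(3 / 5)

    def test_empty_strategy_mapping_rejected(self):
        with pytest.raises(ValueError):
            compare_strategies({"A1": True}, {})

    def test_rerun_is_identical(self):
        ref = {f"A{i}": i % 3 == 0 for i in range(30)}
        preds = {f"A{i}": i % 2 == 0 for i in range(30)}
        r1 = compare_strategies(ref, {"s": preds})
        r2 = compare_strategies(ref, {"s": preds})
        assert r1 == r2

    def test_frame_and_markdown_renderings(self):
        ref = {f"A{i}": i < 4 for i in range(10)}
        rows = compare_strategies(ref, {"eADHF": ref}, cohort_label="derivation")
        df = comparison_to_frame(rows)
        assert df.loc[0, "sensitivity_pct"] == 100.0
        assert df.loc[0, "n"] == 10
        md = render_comparison_markdown(rows, title="demo")
        assert "100.0%" in md and "derivation" in md


class TestDiscordance:
    def test_perfect_agreement_is_empty(self):
        ref = {"A1": True, "A2": False}
        assert discordance_report(ref, ref) == []

    def test_single_false_negative_reported(self):
        ref = {"A1": True, "A2": False}
        preds = {"A1": False, "A2": False}
        report = discordance_report(preds, ref)
        assert len(report) == 1
        d = report[0]
        assert (d.admission_id, d.predicted, d.reference_label) == ("A1", False, True)

    def test_sorted_by_admission_id_with_evidence(self):
        ref = {"A2": True, "A1": True, "A3": False}
        preds = {"A1": False, "A2": False, "A3": False}
        store = {"A1": "ev1", "A2": "ev2"}
        report = discordance_report(preds, ref, evidence_store=store)
        assert [d.admission_id for d in report] == ["A1", "A2"]
        assert report[0].evidence == "ev1"


def test_predictive_values_available_on_request():
    ppv, npv = predictive_values(TwoByTwo(tp=8, fp=2, fn=1, tn=9))
    assert ppv.point == pytest.approx(0.8)
    assert npv.point == pytest.approx(0.9)
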