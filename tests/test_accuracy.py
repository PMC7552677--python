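import itertools

import pytest
from hypothesis import given, settings, strategies as st

from bmhvflow import (CaseSpec, DopplerReport, Grouping, accuracy_table,
                      classify, default_criteria, ground_truth,
                      sensitivity_specificity, summarize_by_lvot)
from bmhvflow.errors import (ClassificationError, DegenerateInputError,
                             DomainError)
from _oracles import confusion_counts_bruteforce


def _report(v_peak=1.36, tpg=3.3, dvi=0.6, eoa=2.7, case=None):
    return DopplerReport(v_peak=v_peak, v_lvot=dvi * v_peak, tpg_mean=tpg,
                         dvi=dvi, eoa=eoa, case=case)


class TestClassify:
    def test_severe_jet_triggers_both_velocity_criteria(self):
        flags = classify(_report(v_peak=4.37))
        assert flags["Vpeak >= 4 m/s"] and flags["Vpeak >= 3 m/s"]

    def test_boundary_equality_counts_as_positive(self):
        flags = classify(_report(v_peak=3.0))
        assert flags["Vpeak >= 3 m/s"]
        assert not flags["Vpeak >= 4 m/s"]
        assert classify(_report(dvi=0.35))["DVI <= 0.35"]

    def test_healthy_range_report_all_negative(self):
        flags = classify(_report(v_peak=1.36, tpg=3.3, dvi=0.6, eoa=2.7))
        assert not any(flags.values())

    def test_missing_metric_rejected(self):
        with pytest.raises(ClassificationError):
            classify(_report(v_peak=float("nan")))


class TestGroundTruth:
    @pytest.mark.parametrize("grouping", list(Grouping))
    def test_healthy_always_negative(self, grouping):
        assert not ground_truth(CaseSpec(27.0, 0.0, 5.0), grouping)

    def test_mild_grouping_counts_50pct(self):
        case = CaseSpec(23.0, 50.0, 3.0)
        assert ground_truth(case, Grouping.MILD_TO_SEVERE)
        assert not ground_truth(case, Grouping.MODERATE_TO_SEVERE)

    def test_moderate_positives_subset_of_mild(self):
        from bmhvflow import enumerate_cases
        for case in enumerate_cases():
            if ground_truth(case, Grouping.MODERATE_TO_SEVERE):
                assert ground_truth(case, Grouping.MILD_TO_SEVERE)


class TestSensitivitySpecificity:
    def test_perfect_classifier(self):
        ss = sensitivity_specificity([True, False], [True, False])
        assert (ss.sensitivity_pct, ss.specificity_pct) == (100.0, 100.0)

    def test_all_negative_classifier(self):
        ss = sensitivity_specificity([False] * 4, [True, True, False, False])
        assert (ss.sensitivity_pct, ss.specificity_pct) == (0.0, 100.0)

    def test_hand_counted_example(self):
        ss = sensitivity_specificity([True, False, True, False, False],
                                     [True, True, False, False, False])
        assert ss.sensitivity_pct == pytest.approx(50.0)
        assert ss.specificity_pct == pytest.approx(66.7, abs=0.05)
        assert (ss.tp, ss.fn, ss.tn, ss.fp) == (1, 1, 2, 1)

    def test_exhaustive_agreement_with_bruteforce_up_to_length_6(self):
        for n in range(1, 7):
            for flags in itertools.product([False, True], repeat=n):
                for labels in itertools.product([False, True], repeat=n):
                    if all(labels) or not any(labels):
                        continue
                    tp, fp, tn, fn = confusion_counts_bruteforce(flags, labels)
                    ss = sensitivity_specificity(flags, labels)
                    assert (ss.tp, ss.fp, ss.tn, ss.fn) == (tp, fp, tn, fn)
                    assert ss.sensitivity_pct == pytest.approx(100 * tp / (tp + fn))
                    assert ss.specificity_pct == pytest.approx(100 * tn / (tn + fp))
                    assert ss.tp + ss.fp + ss.tn + ss.fn == n

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=2, max_size=12))
    def test_polarity_swap_exchanges_rates(self, pairs):
        flags = [f for f, _ in pairs]
        labels = [l for _, l in pairs]
        if all(labels) or not any(labels):
            return
        ss = sensitivity_specificity(flags, labels)
        inv = sensitivity_specificity([not f for f in flags], labels)
        assert inv.sensitivity_pct == pytest.approx(100.0 - ss.sensitivity_pct)
        assert inv.specificity_pct == pytest.approx(100.0 - ss.specificity_pct)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(DegenerateInputError, match="positive"):
            sensitivity_specificity([True, False], [True, True])
        with pytest.raises(DegenerateInputError, match="negative"):
            sensitivity_specificity([True, False], [False, False])

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            sensitivity_specificity([True], [True, False])


class TestAccuracyTable:
    def _reports(self):
        reports = []
        for d in (27.0, 19.0):
            for f, v in ((0.0, 1.4), (50.0, 2.5), (100.0, 4.5)):
                case = CaseSpec(d, f, 5.0)
                reports.append(_report(v_peak=v, tpg=4 * (v / 2) ** 2,
                                       dvi=0.6 - 0.003 * f, eoa=2.7 - 0.015 * f,
                                       case=case))
        return reports

    def test_table_structure_and_counts(self):
        df = accuracy_table(self._reports())
        assert len(df) == len(default_criteria()) * 2
        assert set(df["grouping"]) == {"mild_to_severe", "moderate_to_severe"}
        n = len(self._reports())
        assert ((df.tp + df.fp + df.tn + df.fn) == n).all()

    def test_specificity_100_when_no_negative_crosses(self):
        df = accuracy_table(self._reports())
        row = df[(df.criterion == "Vpeak >= 4 m/s")
                 & (df.grouping == "moderate_to_severe")].iloc[0]
        assert row.specificity_pct == 100
        assert row.sensitivity_pct == 100  # both 100%-dysfunction jets >= 4 m/s


class TestSummarizeByLvot:
    def test_identical_reports_have_zero_sd(self):
        case = CaseSpec(27.0, 0.0, 5.0)
        df = summarize_by_lvot([_report(case=case), _report(case=case)])
        assert df.iloc[0].v_peak_sd == 0.0
        assert df.iloc[0].v_peak_min == df.iloc[0].v_peak_max

    def test_sample_standard_deviation_convention(self):
        case = CaseSpec(27.0, 0.0, 5.0)
        df = summarize_by_lvot([_report(v_peak=1.0, case=case),
                                _report(v_peak=3.0, case=case)])
        assert df.iloc[0].v_peak_mean == pytest.approx(2.0)
        assert df.iloc[0].v_peak_sd == pytest.approx(1.414, abs=0.001)

    def test_row_per_diameter_descending(self):
        reports = []
        for d in (19.0, 27.0, 23.0):
            case = CaseSpec(d, 0.0, 5.0)
            reports += [_report(case=case), _report(case=case)]
        df = summarize_by_lvot(reports)
        assert list(df.lvot_diameter_mm) == [27.0, 23.0, 19.0]

    def test_single_report_per_diameter_rejected(self):
        with pytest.raises(DegenerateInputError):
            summarize_by_lvot([_report(case=CaseSpec(27.0, 0.0, 5.0))])
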