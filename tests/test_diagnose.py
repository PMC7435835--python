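import numpy as np
import pytest

import apneakit as ak


def make_cohort(n_osa=23, n_control=12, missed=1):
    """A screening cohort: OSA records (one optionally missed) + controls."""
    diagnoses, truth = [], []
    for i in range(n_osa):
        rid = f"osa{i:02d}"
        est = 2.0 if i < missed else 30.0  # missed patients called non-OSA
        n_apnea = int(round(est * 480 / 60))
        diagnoses.append(ak.RecordingDiagnosis(
            rid, 480, n_apnea, ak.estimate_ahi(480, n_apnea),
            ak.classify_recording(ak.estimate_ahi(480, n_apnea))))
        truth.append({"record_id": rid, "reference_ahi": 25.0 + i})
    for i in range(n_control):
        rid = f"ctl{i:02d}"
        diagnoses.append(ak.RecordingDiagnosis(
            rid, 480, 8, 1.0, "non-OSA"))
        truth.append({"record_id": rid, "reference_ahi": 1.5})
    return diagnoses, truth


class TestEstimateAhi:
    @pytest.mark.parametrize("L,N,expected", [
        (480, 40, 5.0),
        (480, 0, 0.0),
        (120, 120, 60.0),
        (401, 100, 60.0 * 100 / 401),
    ])
    def test_events_per_hour(self, L, N, expected):
        assert ak.estimate_ahi(L, N) == pytest.approx(expected)

    def test_zero_minutes_rejected(self):
        with pytest.raises(ValueError):
            ak.estimate_ahi(0, 0)

    def test_count_beyond_length_rejected(self):
        with pytest.raises(ValueError):
            ak.estimate_ahi(10, 11)

    def test_monotone_in_apnea_count(self):
        values = [ak.estimate_ahi(480, n) for n in range(0, 481, 40)]
        assert all(a <= b for a, b in zip(values, values[1:]))


class TestClassifyRecording:
    @pytest.mark.parametrize("ahi,call", [
        (5.0, "OSA"),       # threshold is inclusive
        (4.999, "non-OSA"),
        (0.0, "non-OSA"),
        (60.0, "OSA"),
    ])
    def test_threshold_boundary(self, ahi, call):
        assert ak.classify_recording(ahi) == call

    def test_negative_ahi_rejected(self):
        with pytest.raises(ValueError):
            ak.classify_recording(-0.1)

    def test_monotone_never_flips_downward(self):
        calls = [ak.classify_recording(a) for a in np.linspace(0, 20, 81)]
        first_osa = calls.index("OSA")
        assert all(c == "OSA" for c in calls[first_osa:])


class TestCohortSummary:
    def test_reference_cohort_one_missed_patient(self):
        """23 OSA + 12 controls with one miss: 97.1 / 95.7 / 100."""
        diagnoses, truth = make_cohort(missed=1)
        s = ak.cohort_summary(diagnoses, truth)
        assert s.accuracy == 97.1
        assert s.sensitivity == 95.7
        assert s.specificity == 100.0
        assert (s.confusion.TP, s.confusion.FN, s.confusion.TN,
                s.confusion.FP) == (22, 1, 12, 0)

    @pytest.mark.parametrize("missed", [0, 1, 2])
    def test_sensitivity_steps_by_one_23rd_per_miss(self, missed):
        diagnoses, truth = make_cohort(missed=missed)
        s = ak.cohort_summary(diagnoses, truth)
        expected = round(100 * (23 - missed) / 23, 1)
        assert s.sensitivity == pytest.approx(expected, abs=0.051)

    def test_perfect_agreement_gives_unit_correlation(self):
        diagnoses, truth = [], []
        for i, ahi in enumerate([2.0, 8.0, 15.0, 30.0]):
            n = int(round(ahi * 60 / 60))
            diagnoses.append(ak.RecordingDiagnosis(
                f"r{i}", 60, n, ahi, ak.classify_recording(ahi)))
            truth.append({"record_id": f"r{i}", "reference_ahi": ahi})
        s = ak.cohort_summary(diagnoses, truth)
        assert s.r_reference == pytest.approx(1.0)

    def test_pearson_against_closed_form(self):
        est = [3.0, 7.5, 12.0, 20.0, 44.0]
        ref = [2.0, 9.0, 10.0, 25.0, 40.0]
        diagnoses = [ak.RecordingDiagnosis(f"r{i}", 60, int(e), e,
                                           ak.classify_recording(e))
                     for i, e in enumerate(est)]
        truth = [{"record_id": f"r{i}", "reference_ahi": r}
                 for i, r in enumerate(ref)]
        s = ak.cohort_summary(diagnoses, truth)
        # closed-form Pearson r from sums
        x, y = np.array(est), np.array(ref)
        n = len(x)
        r_oracle = ((n * (x * y).sum() - x.sum() * y.sum())
                    / np.sqrt(n * (x ** 2).sum() - x.sum() ** 2)
                    / np.sqrt(n * (y ** 2).sum() - y.sum() ** 2))
        assert s.r_reference == pytest.approx(r_oracle, abs=1e-12)

    def test_annotation_correlation_reported_when_available(self):
        diagnoses, truth = make_cohort(n_osa=4, n_control=3, missed=0)
        for t in truth:
            t["annotation_ahi"] = t["reference_ahi"] * 1.05
        s = ak.cohort_summary(diagnoses, truth)
        assert s.r_annotation is not None
        assert -1.0 <= s.r_annotation <= 1.0

    def test_id_mismatch_rejected(self):
        diagnoses, truth = make_cohort(n_osa=2, n_control=2)
        truth[0]["record_id"] = "stranger"
        with pytest.raises(ValueError, match="stranger"):
            ak.cohort_summary(diagnoses, truth)

    def test_report_table_columns(self, tmp_path):
        diagnoses, truth = make_cohort(n_osa=3, n_control=2)
        s = ak.cohort_summary(diagnoses, truth)
        out = tmp_path / "cohort.csv"
        s.to_csv(out)
        import pandas as pd
        table = pd.read_csv(out)
        assert list(table.columns) == [
            "record_id", "L", "N_apnea", "estimated_ahi", "reference_ahi",
            "annotation_ahi", "call", "truth"]
        assert len(table) == 5


def test_diagnose_recording_from_predictions():
    preds = ["A"] * 6 + ["N"] * 54  # 6 apneic minutes in an hour
    d = ak.diagnose_recording("rec1", preds, reference_ahi=7.0)
    assert d.L == 60 and d.N_apnea == 6
    assert d.estimated_ahi == pytest.approx(6.0)
    assert d.osa_call == "OSA"
    assert d.reference_ahi == 7.0
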