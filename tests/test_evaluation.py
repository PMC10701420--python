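"""Metric formulas, split harness laws, localization and export."""

import json
import math

import numpy as np
import pytest

from focusloc.evaluation import (ConfusionCounts, LocalizationResult,
                                 export_results, kfold_split,
                                 kfold_split_by_patient,
                                 localization_accuracy, localize,
                                 loocv_by_patient, metrics)
from focusloc.synthetic import (SyntheticConfig,
                                generate_multichannel_recording)

RNG = np.random.default_rng(23)


class TestMetrics:
    def test_direct_substitution(self):
        m = metrics(ConfusionCounts(tp=3, tn=4, fp=1, fn=2))
        assert m.acc == pytest.approx(0.7)
        assert m.sn == pytest.approx(0.6)
        assert m.sp == pytest.approx(0.8)
        assert m.ppv == pytest.approx(0.75)
        assert m.npv == pytest.approx(4 / 6)

    def test_all_correct(self):
        m = metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (m.acc, m.sn, m.sp, m.ppv, m.npv) == (1, 1, 1, 1, 1)

    def test_degenerate_reported_missing_not_zero(self):
        m = metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
        assert m.acc == 1.0 and m.sp == 1.0 and m.npv == 1.0
        assert math.isnan(m.sn) and math.isnan(m.ppv)

    def test_against_independent_oracle(self):
        """1,000 random confusion matrices against scikit-learn's
        metric implementations, reconstructed from label vectors."""
        from sklearn.metrics import (accuracy_score, precision_score,
                                     recall_score)
        for _ in range(1000):
            tp, tn, fp, fn = RNG.integers(0, 20, size=4)
            if tp + tn + fp + fn == 0:
                continue
            y_true = np.r_[np.ones(tp), np.zeros(tn),
                           np.zeros(fp), np.ones(fn)]
            y_pred = np.r_[np.ones(tp), np.zeros(tn),
                           np.ones(fp), np.zeros(fn)]
            m = metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            assert m.acc == pytest.approx(
                accuracy_score(y_true, y_pred), abs=1e-12)
            if tp + fn:
                assert m.sn == pytest.approx(
                    recall_score(y_true, y_pred, zero_division=0)
                    if tp + fn else 0, abs=1e-12)
            if tp + fp:
                assert m.ppv == pytest.approx(
                    precision_score(y_true, y_pred), abs=1e-12)
            if tn + fp:
                assert m.sp == pytest.approx(
                    recall_score(1 - y_true, 1 - y_pred), abs=1e-12)
            if tn + fn:
                assert m.npv == pytest.approx(
                    precision_score(1 - y_true, 1 - y_pred), abs=1e-12)

    def test_accuracy_identity(self):
        # acc == (sn*P + sp*N) / (P + N) with P = TP+FN, N = TN+FP
        for _ in range(100):
            tp, tn, fp, fn = RNG.integers(1, 20, size=4)
            m = metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            P, N = tp + fn, tn + fp
            assert m.acc == pytest.approx((m.sn * P + m.sp * N) / (P + N),
                                          abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=1, fp=0, fn=0)


class TestKFold:
    def test_equal_fold_sizes(self):
        splits = kfold_split(100, k=10, seed=0)
        assert all(len(test) == 10 for _, test in splits)

    def test_partition_laws(self):
        splits = kfold_split(103, k=10, seed=1)
        tests = [set(test.tolist()) for _, test in splits]
        union = set().union(*tests)
        assert union == set(range(103))
        for i in range(10):
            for j in range(i + 1, 10):
                assert not tests[i] & tests[j]
        sizes = sorted(len(t) for t in tests)
        assert sizes[-1] - sizes[0] <= 1
        for train, test in splits:
            assert not set(train.tolist()) & set(test.tolist())
            assert len(train) + len(test) == 103

    def test_seed_reproducibility(self):
        a = kfold_split(50, k=5, seed=9)
        b = kfold_split(50, k=5, seed=9)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            np.testing.assert_array_equal(te1, te2)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(5, k=10)

    def test_patient_stratified_no_leakage(self):
        ids = [f"P{i % 6}" for i in range(60)]
        for train, test in kfold_split_by_patient(ids, k=3, seed=0):
            train_p = {ids[i] for i in train}
            test_p = {ids[i] for i in test}
            assert not train_p & test_p


class TestLoocv:
    IDS = [f"P{i}" for i in range(6) for _ in range(4)]

    def test_one_split_per_patient(self):
        splits = loocv_by_patient(self.IDS)
        assert len(splits) == 6
        for patient, train, test in splits:
            assert {self.IDS[i] for i in test} == {patient}
            assert patient not in {self.IDS[i] for i in train}

    def test_average_is_mean_of_per_patient(self):
        accs = {f"P{i}": a for i, a in enumerate(
            [0.889, 0.833, 0.857, 1.0, 0.83, 1.0])}
        assert np.mean(list(accs.values())) == pytest.approx(
            sum(accs.values()) / 6, abs=1e-12)

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            loocv_by_patient(["P0", "P0"])


class FakeModel:
    """Scores each channel by the mean of its samples."""

    def predict_proba(self, X):
        p1 = np.clip(X.mean(axis=1), 0.0, 1.0)
        return np.stack([1 - p1, p1], axis=1)


def make_recording(probs_by_channel, focal_channel=None, width=8):
    from focusloc.synthetic import FOCAL, NON_FOCAL, LabeledSegment
    segs = []
    for name, p in probs_by_channel.items():
        segs.append(LabeledSegment(
            samples=np.full(width, p), fs=256.0, patient_id="P0",
            channel_name=name,
            class_label=FOCAL if name == focal_channel else NON_FOCAL))
    return segs


class TestLocalize:
    def test_argmax_channel(self):
        rec = make_recording({"F3": 0.9, "F4": 0.2, "C3": 0.1}, "F3")
        res = localize(rec, FakeModel())
        assert res.predicted_channel == "F3"
        assert res.correct is True
        assert res.probabilities["F4"] == pytest.approx(0.2)

    def test_tie_breaks_to_first_with_warning(self):
        rec = make_recording({"F4": 0.5, "C3": 0.5}, "C3")
        with pytest.warns(UserWarning, match="tie"):
            res = localize(rec, FakeModel())
        assert res.predicted_channel == "F4"
        assert res.correct is False

    def test_order_invariance(self):
        probs = {"F3": 0.3, "F4": 0.8, "C3": 0.1, "O1": 0.55}
        rec = make_recording(probs, "F4")
        forward = localize(rec, FakeModel())
        backward = localize(rec[::-1], FakeModel())
        assert forward.predicted_channel == backward.predicted_channel
        assert forward.probabilities == backward.probabilities

    def test_channel_mismatch_rejected(self):
        rec = make_recording({"F3": 0.9, "F4": 0.2}, "F3")
        with pytest.raises(ValueError, match="match"):
            localize(rec, FakeModel(), channel_order=["F3", "C3"])

    def test_multiple_segments_averaged(self):
        rec = (make_recording({"F3": 0.2}, "F3")
               + make_recording({"F3": 0.8}, "F3")
               + make_recording({"F4": 0.4}, None))
        res = localize(rec, FakeModel())
        assert res.probabilities["F3"] == pytest.approx(0.5)
        assert res.predicted_channel == "F3"

    def test_accuracy_over_synthetic_recordings(self):
        cfg = SyntheticConfig(n_patients=2, n_channels=4, seed=31)
        recs = [generate_multichannel_recording(cfg, p, recording_index=r)
                for p in range(2) for r in range(2)]

        class OracleModel:
            """Scores by θ+α band share — matches the generative focal
            signature, so localization must be perfect."""

            def predict_proba(self, X):
                spec = np.abs(np.fft.rfft(X, axis=1)) ** 2
                f = np.fft.rfftfreq(X.shape[1], 1 / 256.0)
                band = spec[:, (f >= 4) & (f < 16)].sum(axis=1)
                share = band / spec.sum(axis=1)
                return np.stack([1 - share, share], axis=1)

        acc = localization_accuracy([localize(r, OracleModel())
                                     for r in recs])
        assert acc == 1.0


class TestExport:
    def _results(self, n_patients=6, n_channels=16):
        cfg = SyntheticConfig(n_patients=n_patients, n_channels=n_channels,
                              segment_seconds=1.0, seed=2)
        out = []
        for p in range(n_patients):
            names = cfg.channel_names()
            probs = dict(zip(names, RNG.uniform(size=n_channels)))
            best = max(probs, key=probs.get)
            out.append((f"P{p:02d}", LocalizationResult(
                probabilities=probs, predicted_channel=best,
                true_channel=names[cfg.focus_channel(p)])))
        return out

    def test_row_count(self, tmp_path):
        import pandas as pd
        export_results(self._results(), str(tmp_path))
        table = pd.read_csv(tmp_path / "channel_probabilities.csv")
        assert len(table) == 96

    def test_mean_equals_mean_of_per_patient(self, tmp_path):
        summary = export_results(self._results(), str(tmp_path))
        per = list(summary["per_patient_accuracy"].values())
        assert summary["mean_accuracy"] == pytest.approx(np.mean(per),
                                                         abs=1e-12)
        with open(tmp_path / "summary.json") as fh:
            on_disk = json.load(fh)
        assert on_disk["mean_accuracy"] == summary["mean_accuracy"]

    def test_empty_results_valid_csv(self, tmp_path):
        import pandas as pd
        export_results([], str(tmp_path))
        table = pd.read_csv(tmp_path / "channel_probabilities.csv")
        assert len(table) == 0
        assert list(table.columns) == ["patient", "channel", "probability",
                                       "predicted_flag", "true_flag"]
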