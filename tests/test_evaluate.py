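"""Evaluation metrics, estimator comparison, temporal profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest

import painface as pf
from painface.errors import InvalidArgumentError


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        truth = ["happiness"] * 3 + ["sadness"] * 2
        cm = pf.confusion(truth, truth)
        assert cm.values.sum() == 5
        assert cm.loc["happiness", "happiness"] == 3
        assert cm.loc["sadness", "sadness"] == 2
        assert np.all(cm.values - np.diag(np.diag(cm.values)) == 0)

    def test_single_column_when_one_class_predicted(self):
        truth = ["fear", "anger", "sadness"]
        pred = ["anger"] * 3
        cm = pf.confusion(truth, pred)
        nonzero_cols = (cm.values.sum(axis=0) > 0).sum()
        assert nonzero_cols == 1 and cm["anger"].sum() == 3

    def test_hand_tallied_fixture(self):
        truth = ["a", "a", "a", "b", "b", "c", "c", "c", "c", "a"]
        pred = ["a", "b", "a", "b", "b", "c", "a", "c", "c", "a"]
        cm = pf.confusion(truth, pred, labels=["a", "b", "c"])
        expected = pd.DataFrame(
            [[3, 1, 0], [0, 2, 0], [1, 0, 3]], index=["a", "b", "c"], columns=["a", "b", "c"]
        )
        pd.testing.assert_frame_equal(cm, expected)

    def test_length_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            pf.confusion(["a"], ["a", "b"])

    def test_total_and_micro_recall(self, rng):
        labels = list("abc")
        truth = [labels[i] for i in rng.integers(0, 3, 60)]
        pred = [labels[i] for i in rng.integers(0, 3, 60)]
        cm = pf.confusion(truth, pred, labels=labels)
        assert cm.values.sum() == 60
        micro_recall = np.trace(cm.values) / cm.values.sum()
        overall_acc = np.mean([t == p for t, p in zip(truth, pred)])
        assert micro_recall == pytest.approx(overall_acc)


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        truth = ["happiness"] * 4 + ["sadness"] * 4
        cm = pf.confusion(truth, truth, labels=["happiness", "sadness"])
        scores = pd.DataFrame(
            {"happiness": [1.0] * 4 + [0.0] * 4, "sadness": [0.0] * 4 + [1.0] * 4}
        )
        rep = pf.classification_metrics(cm, scores=scores, truth=truth)
        for col in ("precision", "recall", "accuracy", "f1", "auc", "map"):
            assert rep.loc["happiness", col] == pytest.approx(1.0)
            assert rep.loc["macro", col] == pytest.approx(1.0)

    def test_binary_hand_arithmetic(self):
        # TP=2 FP=1 FN=2 TN=6: precision 2/3, recall 1/2, F1 4/7
        truth = ["pos"] * 4 + ["neg"] * 7
        pred = ["pos", "pos", "neg", "neg", "pos"] + ["neg"] * 6
        cm = pf.confusion(truth, pred, labels=["pos", "neg"])
        rep = pf.classification_metrics(cm)
        assert rep.loc["pos", "precision"] == pytest.approx(2 / 3)
        assert rep.loc["pos", "recall"] == pytest.approx(1 / 2)
        assert rep.loc["pos", "f1"] == pytest.approx(4 / 7)
        assert rep.loc["pos", "accuracy"] == pytest.approx(8 / 11)

    def test_f1_is_harmonic_mean(self, rng):
        labels = list("abcd")
        truth = [labels[i] for i in rng.integers(0, 4, 80)]
        pred = [labels[i] for i in rng.integers(0, 4, 80)]
        rep = pf.classification_metrics(pf.confusion(truth, pred, labels=labels))
        for lab in labels:
            p, r, f1 = rep.loc[lab, ["precision", "recall", "f1"]]
            if np.isnan(f1):
                continue
            assert f1 == pytest.approx(2 * p * r / (p + r), abs=1e-12)

    def test_auc_equals_concordant_pair_fraction(self, rng):
        # brute force over all positive-negative pairs, ties counted half
        truth = ["pos"] * 4 + ["neg"] * 4
        s = list(rng.random(8))
        cm = pf.confusion(truth, ["pos"] * 8, labels=["pos", "neg"])
        scores = pd.DataFrame({"pos": s, "neg": [1 - v for v in s]})
        rep = pf.classification_metrics(cm, scores=scores, truth=truth)
        pos, neg = s[:4], s[4:]
        conc = sum(
            1.0 if sp > sn else 0.5 if sp == sn else 0.0
            for sp, sn in itertools.product(pos, neg)
        ) / 16
        assert rep.loc["pos", "auc"] == pytest.approx(conc, abs=1e-12)

    def test_empty_class_reported_as_missing(self):
        truth = ["a", "a", "b"]
        pred = ["a", "a", "a"]
        cm = pf.confusion(truth, pred, labels=["a", "b", "c"])
        rep = pf.classification_metrics(cm)
        assert np.isnan(rep.loc["c", "recall"])  # zero support
        assert np.isnan(rep.loc["b", "precision"])  # never predicted
        assert not np.isnan(rep.loc["macro", "recall"])


class TestPainAccuracy:
    def test_exact_match_and_half(self):
        assert pf.pain_accuracy([1, 2, 3], [1, 2, 3]) == 100.0
        assert pf.pain_accuracy([1, 2, 3, 4], [1, 2, 0, 0]) == 50.0

    def test_manual_tally_fixture(self, rng):
        pred = list(rng.integers(0, 6, 20))
        truth = list(rng.integers(0, 6, 20))
        expected = 100.0 * sum(p == t for p, t in zip(pred, truth)) / 20
        assert pf.pain_accuracy(pred, truth) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pf.pain_accuracy([], [])


class TestCompareEstimators:
    def test_noiseless_weighted_zone_estimator_is_exact(
        self, zone_cfg, cal, weight_matrix, weight_table
    ):
        frames = pf.generate_dataset(pf.GenConfig(n_frames=70, seed=6))
        tbl = pf.compare_estimators(frames, zone_cfg, cal, weight_matrix, weight_table)
        for cls in tbl.index:
            if cls == "average":
                continue
            assert tbl.loc[cls, "PLEWz"] == pytest.approx(100.0)

    def test_single_class_dataset(self, zone_cfg, cal, weight_matrix, weight_table):
        frames = pf.generate_dataset(
            pf.GenConfig(n_frames=10, emotion_mix={"disgust": 1.0}, seed=6)
        )
        tbl = pf.compare_estimators(frames, zone_cfg, cal, weight_matrix, weight_table)
        assert list(tbl.index) == ["disgust", "average"]

    def test_matches_per_frame_recomputation(self, zone_cfg, cal, weight_matrix, weight_table):
        frames = pf.generate_dataset(pf.GenConfig(n_frames=35, noise_sigma=0.01, seed=8))
        tbl = pf.compare_estimators(frames, zone_cfg, cal, weight_matrix, weight_table)
        # independent per-frame staged recomputation of the PLEWz column
        by_class = {}
        for f in frames:
            zi = pf.compute_zone_intensities(f.neutral, f.active, zone_cfg, cal)
            vec = pf.reduce_to_vector(zi)
            ps = pf.zone_max_ple(zi)
            label, _ = pf.classify_au_vector(vec, weight_matrix)
            lvl = pf.bin_pain_level(pf.weighted_ple(ps, label, weight_table))
            by_class.setdefault(f.true_emotion, []).append(lvl == f.true_level)
        for cls, hits in by_class.items():
            assert tbl.loc[cls, "PLEWz"] == pytest.approx(100.0 * np.mean(hits))


class TestTemporalProfile:
    def test_constant_series_constant_output(self, template, zone_cfg, cal, weight_matrix, weight_table):
        active = pf.apply_activation(template, {"AU9": 2.0}, cal)
        series = [(float(t), template.landmarks, active) for t in range(5)]
        prof = pf.temporal_profile(series, zone_cfg, cal, weight_matrix, weight_table)
        assert prof["ps"].nunique() == 1 and prof["plew"].nunique() == 1

    def test_sadness_series_scales_by_1p7(self, template, zone_cfg, cal, weight_matrix, weight_table):
        series = pf.make_temporal_series("sadness", duration=60, fps=1, tpl=template, cal=cal)
        prof = pf.temporal_profile(series, zone_cfg, cal, weight_matrix, weight_table)
        np.testing.assert_allclose(prof["plew"], 1.7 * prof["ps"], atol=1e-9)

    def test_happiness_series_never_exceeds_raw(self, template, zone_cfg, cal, weight_matrix, weight_table):
        series = pf.make_temporal_series("happiness", duration=60, fps=1, tpl=template, cal=cal)
        prof = pf.temporal_profile(series, zone_cfg, cal, weight_matrix, weight_table)
        assert (prof["plew"] <= prof["ps"] + 1e-12).all()

    def test_unordered_timestamps_rejected(self, template, zone_cfg, cal, weight_matrix, weight_table):
        active = pf.apply_activation(template, {"AU9": 2.0}, cal)
        series = [(1.0, template.landmarks, active), (0.5, template.landmarks, active)]
        with pytest.raises(InvalidArgumentError):
            pf.temporal_profile(series, zone_cfg, cal, weight_matrix, weight_table)
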