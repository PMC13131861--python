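"""Tests for repeated-CV multinomial classification and its reports."""

import numpy as np
import pandas as pd
import pytest

from sundown.classify import (
    BehaviorClassifier,
    CVScheme,
    confusion_matrix,
    f1_report,
    roc_curve,
)

CLASSES = ["AD Sundown", "AD Sunrise", "Ctrl Sundown", "Ctrl Sunrise"]


def separable_table(n_per_class=10, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for ci, c in enumerate(CLASSES):
        centers = np.zeros(4)
        centers[ci] = 5.0
        X = centers + noise * rng.standard_normal((n_per_class, 4))
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(4)])
        df.insert(0, "class", c)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def uninformative_table(n_per_class=10, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_per_class * len(CLASSES), 3))
    df = pd.DataFrame(X, columns=list("abc"))
    df.insert(0, "class", np.repeat(CLASSES, n_per_class))
    return df


class TestCrossvalPredict:
    def test_separable_data_perfect(self):
        model = BehaviorClassifier(separable_table())
        report = model.fit(CVScheme(n_folds=5, n_repeats=3, seed=1))
        assert report.accuracy > 0.99
        assert (report.f1()["f1"] > 0.99).all()

    def test_uninformative_data_near_chance(self):
        model = BehaviorClassifier(uninformative_table(n_per_class=20, seed=2))
        report = model.fit(CVScheme(n_folds=5, n_repeats=10, seed=3))
        assert abs(report.accuracy - 0.25) < 0.12

    def test_each_subject_predicted_once_per_repeat(self):
        model = BehaviorClassifier(separable_table())
        report = model.fit(CVScheme(n_folds=5, n_repeats=4, seed=4))
        counts = report.predictions.groupby(["repeat", "subject_id"]).size()
        assert (counts == 1).all()

    def test_stratification_balanced_within_one(self):
        data = separable_table(n_per_class=11, seed=5)
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=0)
        y = data["class"].to_numpy()
        for _, test in skf.split(np.zeros((len(y), 1)), y):
            counts = pd.Series(y[test]).value_counts()
            for c in CLASSES:
                expect = 11 / 4
                assert abs(counts.get(c, 0) - expect) < 1

    def test_deterministic_given_seed(self):
        model = BehaviorClassifier(separable_table())
        r1 = model.fit(CVScheme(n_folds=5, n_repeats=2, seed=7))
        r2 = model.fit(CVScheme(n_folds=5, n_repeats=2, seed=7))
        pd.testing.assert_frame_equal(r1.predictions, r2.predictions)

    def test_class_smaller_than_folds_rejected(self):
        data = separable_table(n_per_class=3)
        with pytest.raises(ValueError, match="smaller than n_folds"):
            BehaviorClassifier(data).fit(CVScheme(n_folds=5, n_repeats=1))

    def test_planted_signal_features_beat_unrelated(self):
        # class signal lives only on 3 "syllable" features
        rng = np.random.default_rng(8)
        n_per = 12
        sig = np.zeros((n_per * 4, 3))
        for ci in range(4):
            sig[ci * n_per:(ci + 1) * n_per] = [ci, -ci, ci % 2]
        sig = sig + 0.5 * rng.standard_normal(sig.shape)
        noise = rng.standard_normal((n_per * 4, 3))
        df = pd.DataFrame(np.hstack([sig, noise]),
                          columns=["syl_a", "syl_b", "syl_c", "x0", "x1", "x2"])
        df.insert(0, "class", np.repeat(CLASSES, n_per))
        scheme = CVScheme(n_folds=4, n_repeats=10, seed=9)
        f1_sig = BehaviorClassifier(df, features=["syl_a", "syl_b", "syl_c"]).fit(scheme).f1()
        f1_noise = BehaviorClassifier(df, features=["x0", "x1", "x2"]).fit(scheme).f1()
        assert f1_sig.loc["AD Sundown", "f1"] > f1_noise.loc["AD Sundown", "f1"]


class TestShuffleNull:
    def test_confusion_rows_near_uniform(self):
        model = BehaviorClassifier(uninformative_table(n_per_class=16, seed=10))
        report = model.fit_shuffled(n_shuffles=10, repeats_per_shuffle=2,
                                    scheme=CVScheme(n_folds=4, seed=11))
        conf = report.confusion()
        assert np.allclose(conf.to_numpy(), 0.25, atol=0.12)
        assert np.allclose(conf.sum(axis=1), 1.0)

    def test_total_repeats(self):
        model = BehaviorClassifier(separable_table())
        report = model.fit_shuffled(n_shuffles=5, repeats_per_shuffle=4,
                                    scheme=CVScheme(n_folds=5, seed=12))
        assert report.predictions["repeat"].nunique() == 20
        assert report.predictions["shuffle"].nunique() == 5

    def test_null_auc_near_half(self):
        model = BehaviorClassifier(uninformative_table(n_per_class=16, seed=13))
        report = model.fit_shuffled(n_shuffles=10, repeats_per_shuffle=2,
                                    scheme=CVScheme(n_folds=4, seed=14))
        assert abs(report.auc(CLASSES[0]) - 0.5) < 0.1


class TestConfusionMatrix:
    def test_arithmetic_oracle(self):
        preds = pd.DataFrame({
            "repeat": 0,
            "true": ["a"] * 40 + ["b"] * 60,
            "predicted": ["a"] * 30 + ["b"] * 10 + ["a"] * 20 + ["b"] * 40,
        })
        conf = confusion_matrix(preds, ["a", "b"])
        assert np.allclose(conf.to_numpy(), [[0.75, 0.25], [1 / 3, 2 / 3]])

    def test_perfect_predictions_identity(self):
        preds = pd.DataFrame({"repeat": 0, "true": list("abab"),
                              "predicted": list("abab")})
        conf = confusion_matrix(preds, ["a", "b"])
        assert np.allclose(conf.to_numpy(), np.eye(2))

    def test_single_column_predictor(self):
        preds = pd.DataFrame({"repeat": 0, "true": list("abab"),
                              "predicted": ["a"] * 4})
        conf = confusion_matrix(preds, ["a", "b"])
        assert np.allclose(conf["a"], 1.0)
        assert np.allclose(conf["b"], 0.0)

    def test_empty_true_class_raises(self):
        preds = pd.DataFrame({"repeat": 0, "true": ["a"], "predicted": ["a"]})
        with pytest.raises(ValueError, match="no predictions"):
            confusion_matrix(preds, ["a", "b"])


class TestROC:
    def test_perfect_scores_auc_one(self):
        preds = pd.DataFrame({"true": list("aabb"), "p_a": [1.0, 1.0, 0.0, 0.0]})
        roc = roc_curve(preds, "a")
        assert roc.attrs["auc"] == pytest.approx(1.0)
        assert (roc[["fpr", "tpr"]].iloc[0] == 0).all()
        assert (roc[["fpr", "tpr"]].iloc[-1] == 1).all()

    def test_matches_exhaustive_threshold_oracle(self):
        rng = np.random.default_rng(15)
        truth = rng.random(40) < 0.4
        score = np.clip(truth * 0.3 + rng.random(40), 0, 1)
        preds = pd.DataFrame({"true": np.where(truth, "pos", "neg"), "p_pos": score})
        roc = roc_curve(preds, "pos")
        # oracle: enumerate every distinct score as a threshold
        pts = {(0.0, 0.0)}
        for thr in np.unique(score):
            pred_pos = score >= thr
            tpr = (pred_pos & truth).sum() / truth.sum()
            fpr = (pred_pos & ~truth).sum() / (~truth).sum()
            pts.add((round(fpr, 12), round(tpr, 12)))
        got = {(round(f, 12), round(t, 12)) for f, t in zip(roc["fpr"], roc["tpr"])}
        assert got == pts

    def test_single_class_raises(self):
        preds = pd.DataFrame({"true": ["a", "a"], "p_a": [0.5, 0.6]})
        with pytest.raises(ValueError):
            roc_curve(preds, "a")


class TestF1Report:
    def test_harmonic_mean_arithmetic(self):
        # precision 0.5, recall 1 -> F1 = 2/3
        preds = pd.DataFrame({
            "repeat": 0,
            "true": ["a", "a", "b", "b"],
            "predicted": ["a", "a", "a", "a"],
        })
        rep = f1_report(preds, ["a", "b"])
        assert rep.loc["a", "precision"] == pytest.approx(0.5)
        assert rep.loc["a", "recall"] == pytest.approx(1.0)
        assert rep.loc["a", "f1"] == pytest.approx(2 / 3)

    def test_constant_f1_zero_width_ci(self):
        preds = pd.DataFrame({
            "repeat": np.repeat([0, 1, 2], 4),
            "true": ["a", "a", "b", "b"] * 3,
            "predicted": ["a", "a", "b", "b"] * 3,
        })
        rep = f1_report(preds, ["a", "b"])
        assert rep.loc["a", "f1"] == 1.0
        assert rep.loc["a", "f1_lo"] == pytest.approx(rep.loc["a", "f1_hi"])

    def test_undefined_f1_recorded_as_zero_with_flag(self):
        preds = pd.DataFrame({
            "repeat": 0,
            "true": ["a", "b"],
            "predicted": ["a", "a"],
        })
        rep = f1_report(preds, ["a", "b"])
        assert rep.loc["b", "f1"] == 0.0
        assert rep.loc["b", "n_undefined"] == 1
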