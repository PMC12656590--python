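"""Grouped fold construction, grid search, model fitting, metric
identities and cross-location application."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bcgaf import Family, RhythmLabel, SensorPlacement
from bcgaf.classify import (
    audit_no_leakage,
    cross_location_apply,
    evaluate,
    fit_model,
    fit_predict,
    full_grid,
    grid_search,
    loocv_by_participant,
    make_group_stratified_folds,
    predict_blocks,
)
from bcgaf.metrics import f1_from, round_half_away
from bcgaf.preprocess import FeatureDataset
from bcgaf.types import (
    BlockPrediction,
    ClassifierConfig,
    EvalReport,
    SpectrumSetting,
)

SETTING = SpectrumSetting(0.0, 10.0, 30)


def toy_dataset(n_af=4, n_non_af=6, blocks_per=8, nbins=30, separation=3.0,
                seed=0, setting=SETTING) -> FeatureDataset:
    """Separable synthetic feature table: AF rows shifted in one bin."""
    rng = np.random.default_rng(seed)
    rows, X = [], []
    for i in range(n_af + n_non_af):
        label = RhythmLabel.AF if i < n_af else RhythmLabel.NON_AF
        for b in range(blocks_per):
            x = np.abs(rng.normal(1.0, 0.3, size=nbins))
            if label is RhythmLabel.AF:
                x[0] += separation
            rows.append(
                {
                    "participant_id": f"P{i:02d}",
                    "placement": "BCG2",
                    "start_sample": b * 2048,
                    "label": label.value,
                }
            )
            X.append(x)
    meta = pd.DataFrame(rows)
    return FeatureDataset(meta=meta, features={setting: np.vstack(X)},
                          n_total_blocks=len(rows))


class TestGroupedFolds:
    def test_cohort_of_67_balances_af_across_five_folds(self):
        participants = [(f"A{i}", RhythmLabel.AF) for i in range(23)] + [
            (f"N{i}", RhythmLabel.NON_AF) for i in range(44)
        ]
        folds = make_group_stratified_folds(participants, k=5, seed=3)
        sizes = [sum(1 for f in folds.values() if f == j) for j in range(5)]
        af_counts = [
            sum(1 for (pid, lbl) in participants if folds[pid] == j and lbl is RhythmLabel.AF)
            for j in range(5)
        ]
        assert sorted(folds.values()) == sorted(f for f in folds.values())
        assert set(folds) == {pid for pid, _ in participants}
        assert all(13 <= s <= 14 for s in sizes)
        assert all(4 <= c <= 5 for c in af_counts)

    def test_single_fold_contains_everyone(self):
        participants = [("a", RhythmLabel.AF), ("b", RhythmLabel.NON_AF)]
        folds = make_group_stratified_folds(participants, k=1, seed=0)
        assert set(folds.values()) == {0}

    def test_folds_partition_participants(self):
        participants = [(f"p{i}", RhythmLabel.AF if i % 3 == 0 else RhythmLabel.NON_AF)
                        for i in range(17)]
        folds = make_group_stratified_folds(participants, k=5, seed=1)
        assert len(folds) == 17  # each participant in exactly one fold

    def test_too_many_folds_is_an_error(self):
        with pytest.raises(ValueError):
            make_group_stratified_folds([("a", RhythmLabel.AF)], k=2, seed=0)

    def test_leakage_audit_raises_on_overlap(self):
        with pytest.raises(AssertionError):
            audit_no_leakage(["a", "b"], ["b", "c"])
        audit_no_leakage(["a"], ["b"])  # disjoint -> silent


class TestGridSearch:
    def test_singleton_grid_returns_that_config(self):
        ds = toy_dataset()
        config = ClassifierConfig.make(Family.DT, SETTING, max_depth=3)
        best = grid_search(ds, [config], k=3, seed=0)
        assert best.config == config
        assert 0.0 <= best.mean_accuracy <= 1.0
        assert best.mean_accuracy == pytest.approx(best.fold_accuracies.mean())

    def test_informative_features_beat_noise_features(self, bcg2_features):
        # Same classifier, two featurizations: harmonic band (0-10 Hz)
        # vs pure-noise band (100-250 Hz of standardized BCG).
        harmonic, noise = bcg2_features.settings
        configs = [
            ClassifierConfig.make(Family.DT, noise, max_depth=3),
            ClassifierConfig.make(Family.DT, harmonic, max_depth=3),
        ]
        best, results = grid_search(bcg2_features, configs, k=3, seed=0,
                                    return_all=True)
        assert best.config.setting == harmonic
        by_setting = {r.config.setting: r.mean_accuracy for r in results}
        assert by_setting[harmonic] > by_setting[noise]

    def test_empty_grid_is_an_error(self):
        with pytest.raises(ValueError):
            grid_search(toy_dataset(), [], k=2, seed=0)

    def test_full_grid_order_is_deterministic(self):
        settings = [SETTING]
        a = full_grid(settings=settings)
        b = full_grid(settings=settings)
        assert a == b
        assert a[0].family is Family.DT and a[-1].family is Family.ADA
        # Table grid sizes: DT 6 + RF 10 + LR 9 + ADA 24 per setting.
        assert len(a) == 49


class TestFitPredict:
    def test_random_forest_refits_separable_training_data(self):
        ds = toy_dataset(seed=5)
        config = ClassifierConfig.make(Family.RF, SETTING, max_depth=5)
        preds = fit_predict(
            ds.features[SETTING], ds.meta["label"], ds.features[SETTING],
            config, seed=0, test_meta=ds.meta,
        )
        correct = np.mean(
            [p.predicted.value == l for p, l in zip(preds, ds.meta["label"])]
        )
        assert correct >= 0.95

    def test_single_class_training_yields_constant_prediction(self):
        X = np.abs(np.random.default_rng(0).normal(size=(10, 30)))
        config = ClassifierConfig.make(Family.DT, SETTING, max_depth=1)
        model = fit_model(X, ["AF"] * 10, config)
        labels, scores = model.predict(X[:3])
        assert set(labels) == {"AF"} and set(scores) == {1.0}
        model2 = fit_model(X, ["NON_AF"] * 10, config)
        _, scores2 = model2.predict(X[:3])
        assert set(scores2) == {0.0}

    def test_adaboost_best_table_config_runs(self):
        ds = toy_dataset(seed=6)
        config = ClassifierConfig.make(
            Family.ADA, SETTING, max_depth=7, learning_rate=0.9
        )
        model = fit_model(ds.features[SETTING], ds.meta["label"], config, seed=0)
        labels, scores = model.predict(ds.features[SETTING])
        assert len(labels) == ds.n_included
        assert np.all((scores >= 0) & (scores <= 1))

    def test_feature_width_mismatch_is_an_error(self):
        config = ClassifierConfig.make(Family.DT, SETTING, max_depth=1)
        with pytest.raises(ValueError):
            fit_model(np.ones((4, 7)), ["AF", "AF", "NON_AF", "NON_AF"], config)

    def test_hyperparameter_keys_validated(self):
        with pytest.raises(ValueError):
            ClassifierConfig.make(Family.LR, SETTING, max_depth=3)


class TestEvaluate:
    @staticmethod
    def preds_from_counts(tp, fp, tn, fn):
        preds, labels = [], {}
        i = 0
        for count, truth, predicted in (
            (tp, RhythmLabel.AF, RhythmLabel.AF),
            (fn, RhythmLabel.AF, RhythmLabel.NON_AF),
            (tn, RhythmLabel.NON_AF, RhythmLabel.NON_AF),
            (fp, RhythmLabel.NON_AF, RhythmLabel.AF),
        ):
            for _ in range(count):
                pid = f"p{i}"
                labels[pid] = truth
                preds.append(BlockPrediction(pid, None, 0, predicted))
                i += 1
        return preds, labels

    def test_metric_identities_on_random_confusion_matrices(self):
        import warnings

        rng = np.random.default_rng(11)
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(0, 30, size=4)
            if tp + fp + tn + fn == 0:
                continue
            with warnings.catch_warnings():
                # zero-margin draws legitimately trigger the
                # undefined-recall warning under test elsewhere
                warnings.simplefilter("ignore")
                r = EvalReport.from_counts(int(tp), int(fp), int(tn), int(fn))
            assert r.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))
            if tp + fn:
                assert r.recall == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert r.specificity == pytest.approx(tn / (tn + fp))
            if tp + fp:
                assert r.precision == pytest.approx(tp / (tp + fp))
            if r.recall and r.precision:
                assert r.f1 == pytest.approx(f1_from(r.recall, r.precision))

    def test_no_positive_blocks_reports_missing_recall(self):
        preds, labels = self.preds_from_counts(0, 2, 5, 0)
        with pytest.warns(UserWarning):
            report = evaluate(preds, labels)
        assert report.recall is None and report.f1 is None
        assert report.specificity == pytest.approx(5 / 7)

    def test_printed_f1_rounding_example(self):
        # recall 0.72, precision 0.92 -> F1 = 0.8078... -> 0.81
        assert round_half_away(f1_from(0.72, 0.92), 2) == 0.81

    def test_half_away_rounding_differs_from_bankers(self):
        assert round_half_away(0.805, 2) == 0.81
        assert round_half_away(-0.805, 2) == -0.81

    def test_all_correct_predictions_hit_ceiling(self):
        preds, labels = self.preds_from_counts(3, 0, 4, 0)
        for p, truth in zip(preds, (labels[p.participant_id] for p in preds)):
            p.score = 1.0 if truth is RhythmLabel.AF else 0.0
        report = evaluate(preds, labels)
        assert report.accuracy == 1.0 and report.auc == 1.0

    def test_auc_equals_normalized_mann_whitney(self):
        rng = np.random.default_rng(13)
        for trial in range(20):
            n_pos, n_neg = rng.integers(3, 40, size=2)
            preds, labels = self.preds_from_counts(int(n_pos), 0, int(n_neg), 0)
            scores = rng.normal(size=n_pos + n_neg)
            for p, s in zip(preds, scores):
                p.score = float(s)
            report = evaluate(preds, labels)
            pos = scores[:n_pos]
            neg = scores[n_pos:]
            u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
            assert report.auc == pytest.approx(u / (n_pos * n_neg))

    def test_empty_predictions_is_an_error(self):
        with pytest.raises(ValueError):
            evaluate([], {})


class TestLOOCV:
    def test_two_participant_majority_trace(self):
        # Constant features: each held-out fit sees one class only and
        # predicts it, so both held-out participants score 0.
        rows, X = [], []
        for pid, label, n in (("a", "AF", 3), ("b", "NON_AF", 5)):
            for j in range(n):
                rows.append({"participant_id": pid, "placement": "BCG2",
                             "start_sample": j, "label": label})
                X.append(np.ones(30))
        ds = FeatureDataset(pd.DataFrame(rows), {SETTING: np.vstack(X)}, 8)
        config = ClassifierConfig.make(Family.DT, SETTING, max_depth=1)
        table, mean, sd = loocv_by_participant(ds, config)
        assert list(table["accuracy"]) == [0.0, 0.0]
        assert mean == 0.0

    def test_perfectly_separable_cohort_hits_ceiling(self):
        ds = toy_dataset(separation=8.0, seed=9)
        config = ClassifierConfig.make(Family.DT, SETTING, max_depth=1)
        table, mean, sd = loocv_by_participant(ds, config)
        assert len(table) == 10
        assert mean == 1.0 and sd == 0.0

    def test_requires_two_participants(self):
        ds = toy_dataset(n_af=1, n_non_af=0)
        config = ClassifierConfig.make(Family.DT, SETTING, max_depth=1)
        with pytest.raises(ValueError):
            loocv_by_participant(ds, config)


class TestCrossLocation:
    def test_self_application_matches_direct_evaluation(self):
        ds = toy_dataset(seed=21)
        config = ClassifierConfig.make(Family.RF, SETTING, max_depth=5)
        model = fit_model(ds.features[SETTING], ds.meta["label"], config, seed=0)
        report, preds = cross_location_apply(model, ds)
        direct = evaluate(predict_blocks(model, ds.meta, ds.features[SETTING]),
                          ds.labels_by_participant())
        assert report == direct

    def test_setting_mismatch_is_an_error(self):
        ds = toy_dataset()
        other = SpectrumSetting(0.0, 20.0, 10)
        config = ClassifierConfig.make(Family.DT, other, max_depth=3)
        model = fit_model(np.ones((4, 10)), ["AF", "AF", "NON_AF", "NON_AF"],
                          config)
        with pytest.raises(ValueError):
            cross_location_apply(model, ds)

    def test_chest_model_transfers_better_toward_head_than_lumbar(self):
        # The head-side sensor shares the chest sensor's cardiac-dominant
        # mix; the sacral sensor is respiration-dominant, so a chest-
        # trained model degrades more there.
        from bcgaf.preprocess import featurize_recordings
        from bcgaf.synth import generate_cohort
        from bcgaf import SynthParams

        params = SynthParams(duration_s=150.0)
        train = generate_cohort(3, 4, params, 55, placements=[SensorPlacement.BCG2])
        test = generate_cohort(2, 3, params, 56)
        for rec in test:
            rec.participant_id = "T" + rec.participant_id
        tr = featurize_recordings(train, None, [SETTING])
        config = ClassifierConfig.make(Family.ADA, SETTING, max_depth=7,
                                       learning_rate=0.9)
        model = fit_model(tr.features[SETTING], tr.meta["label"], config, seed=0)
        accs = {}
        for pl in (SensorPlacement.BCG1, SensorPlacement.BCG4):
            ds = featurize_recordings(test, [pl], [SETTING])
            report, _ = cross_location_apply(model, ds)
            accs[pl] = report.accuracy
        assert accs[SensorPlacement.BCG1] >= accs[SensorPlacement.BCG4]
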