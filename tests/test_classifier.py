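import numpy as np
import pandas as pd
import pytest

from mbsub.classifier import (
    TrainConfig,
    predict_proba,
    load_model,
    save_model,
    stratified_split,
    train_binary_model,
    train_model,
)
from mbsub.ssgsea import SsgseaParams, ssgsea_matrix
from mbsub.synthetic import CohortSpec, simulate_cohort

from conftest import SMALL_SPEC


def _profile(cohort):
    return ssgsea_matrix(cohort.expression, cohort.gene_sets, SsgseaParams())


class TestStratifiedSplit:
    def test_seventy_thirty_arithmetic(self):
        labels = ["A"] * 10 + ["B"] * 10
        train, test = stratified_split(labels, 0.7, seed=1)
        tr = pd.Series(labels)[train]
        assert (tr == "A").sum() == 7 and (tr == "B").sum() == 7
        assert len(test) == 6

    def test_partition_and_determinism(self):
        rng = np.random.default_rng(0)
        labels = list(rng.choice(["A", "B", "C"], size=47))
        t1, s1 = stratified_split(labels, 0.7, seed=9)
        t2, s2 = stratified_split(labels, 0.7, seed=9)
        assert np.array_equal(t1, t2) and np.array_equal(s1, s2)
        assert sorted(set(t1) | set(s1)) == list(range(47))
        assert set(t1).isdisjoint(s1)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_split(["A", "A", "B"], 0.7, seed=0)


class TestTrainModel:
    def test_recovers_planted_subgroups(self, small_cohort):
        profile = _profile(small_cohort)
        model = train_model(profile, small_cohort.labels, TrainConfig(seed=3, n_trees=300))
        assert model.test_accuracy >= 0.9
        markers = {s for names in small_cohort.marker_map.values() for s in names}
        recovered = markers & set(model.selected_features)
        assert len(recovered) >= len(markers) / 2

    def test_deterministic_given_seed(self, small_cohort):
        profile = _profile(small_cohort)
        cfg = TrainConfig(seed=5, n_trees=100)
        m1 = train_model(profile, small_cohort.labels, cfg)
        m2 = train_model(profile, small_cohort.labels, cfg)
        assert m1.selected_features == m2.selected_features
        assert m1.test_accuracy == m2.test_accuracy
        p1 = predict_proba(m1, profile)
        p2 = predict_proba(m2, profile)
        assert np.array_equal(p1.to_numpy(), p2.to_numpy())

    def test_pruning_monotone_in_threshold(self, small_cohort):
        profile = _profile(small_cohort)
        counts = []
        for thr in (2.0, 8.0, 30.0):
            model = train_model(
                profile,
                small_cohort.labels,
                TrainConfig(seed=4, n_trees=100, importance_threshold=thr),
            )
            counts.append(len(model.selected_features))
        assert counts == sorted(counts, reverse=True)

    def test_no_surviving_feature_is_informative_error(self, small_cohort):
        profile = _profile(small_cohort)
        with pytest.raises(ValueError, match="importance_threshold"):
            train_model(
                profile,
                small_cohort.labels,
                TrainConfig(seed=4, n_trees=50, importance_threshold=100.0),
            )

    def test_importance_scale_max_reached(self, small_cohort):
        profile = _profile(small_cohort)
        model = train_model(profile, small_cohort.labels, TrainConfig(seed=2, n_trees=100))
        assert model.importances["scaled_importance"].max() == pytest.approx(100.0)

    def test_accuracy_nondecreasing_in_effect_size(self):
        # planted effect 0 -> 1 -> 2 should not reduce accuracy, allowing a
        # single sampling-noise violation across five seeds
        violations = 0
        for seed in range(5):
            accs = []
            for delta in (0.0, 1.0, 2.0):
                spec = CohortSpec(
                    n_subgroups=3,
                    samples_per_subgroup=14,
                    n_genes=400,
                    marker_sets_per_subgroup=2,
                    n_gene_sets=40,
                    genes_per_set=10,
                    effect_size_delta=delta,
                    seed=100 + seed,
                )
                cohort = simulate_cohort(spec)
                profile = _profile(cohort)
                model = train_model(
                    profile, cohort.labels,
                    TrainConfig(seed=seed, n_trees=150, importance_threshold=2.0),
                )
                accs.append(model.test_accuracy)
            violations += sum(b < a for a, b in zip(accs, accs[1:]))
        assert violations <= 1


class TestPredictProba:
    def test_rows_on_probability_simplex(self, small_cohort):
        profile = _profile(small_cohort)
        model = train_model(profile, small_cohort.labels, TrainConfig(seed=1, n_trees=100))
        probs = predict_proba(model, profile)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert ((probs >= 0) & (probs <= 1)).all().all()

    def test_training_samples_called_correctly(self, small_cohort):
        profile = _profile(small_cohort)
        model = train_model(profile, small_cohort.labels, TrainConfig(seed=1, n_trees=200))
        train_rows = profile.scores.loc[model.train_index]
        calls = predict_proba(model, train_rows).idxmax(axis=1)
        truth = small_cohort.labels.loc[model.train_index]
        assert (calls == truth).mean() >= 0.95

    def test_missing_feature_error_lists_names(self, small_cohort):
        profile = _profile(small_cohort)
        model = train_model(profile, small_cohort.labels, TrainConfig(seed=1, n_trees=50))
        dropped = model.selected_features[0]
        with pytest.raises(ValueError, match=dropped):
            predict_proba(model, profile.scores.drop(columns=[dropped]))

    def test_extra_columns_ignored(self, small_cohort):
        profile = _profile(small_cohort)
        model = train_model(profile, small_cohort.labels, TrainConfig(seed=1, n_trees=50))
        widened = profile.scores.copy()
        widened["EXTRA"] = 0.0
        probs = predict_proba(model, widened)
        assert list(probs.columns) == model.classes


class TestBinaryModel:
    def test_mb_vs_other_recovery(self, small_cohort):
        profile = _profile(small_cohort)
        is_mb = (small_cohort.labels == "SG1").map({True: "MB", False: "non-MB"})
        model = train_binary_model(profile, is_mb, TrainConfig(seed=6, n_trees=300))
        assert set(model.classes) == {"MB", "non-MB"}
        assert model.test_accuracy >= 0.9

    def test_single_class_rejected(self, small_cohort):
        profile = _profile(small_cohort)
        with pytest.raises(ValueError, match="2 label values"):
            train_binary_model(profile, ["MB"] * len(profile.scores), TrainConfig())


class TestPersistence:
    def test_save_load_roundtrip(self, small_cohort, tmp_path):
        profile = _profile(small_cohort)
        model = train_model(profile, small_cohort.labels, TrainConfig(seed=8, n_trees=50))
        save_model(model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        assert back.selected_features == model.selected_features
        assert back.config == model.config
        p1 = predict_proba(model, profile)
        p2 = predict_proba(back, profile)
        assert np.allclose(p1.to_numpy(), p2.to_numpy())
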