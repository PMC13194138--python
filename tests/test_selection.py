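import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from eegselect.optimize import OptimizerConfig
from eegselect.selection import (ChannelSelectionModel, FitnessRecord,
                                 classification_metrics, epoch_indices,
                                 fitness_accuracy, make_cv_splits,
                                 select_channels)


def subjects_groups(n_per_group=15):
    subj = np.array([f"{g}{i:02d}" for g in ("A", "C") for i in range(n_per_group)])
    groups = np.repeat(["AD", "CN"], n_per_group)
    return subj, groups


class TestCVSplits:
    def test_kfold5_partitions_subjects_stratified(self):
        subj, groups = subjects_groups()
        splits = make_cv_splits(subj, groups, "kfold5", seed=0)
        assert len(splits) == 5
        test_union = np.concatenate([te for _, te in splits])
        assert sorted(test_union) == sorted(subj)
        for tr, te in splits:
            assert len(te) == 6
            assert set(tr) | set(te) == set(subj)
            assert not set(tr) & set(te)
            # stratification: 3 subjects per group in each test fold
            te_groups = [g for s, g in zip(subj, groups) if s in set(te)]
            assert te_groups.count("AD") == 3

    def test_loso_one_subject_per_fold(self):
        subj, groups = subjects_groups()
        splits = make_cv_splits(subj, groups, "loso")
        assert len(splits) == 30
        assert all(len(te) == 1 for _, te in splits)
        assert sorted(np.concatenate([te for _, te in splits])) == sorted(subj)

    def test_no_epoch_level_leakage(self):
        subj, groups = subjects_groups(5)
        epoch_subjects = np.repeat(subj, 3)
        for split in make_cv_splits(subj, groups, "kfold5", seed=1):
            tr, te = epoch_indices(split, epoch_subjects)
            assert not set(epoch_subjects[tr]) & set(epoch_subjects[te])
            assert len(tr) + len(te) == len(epoch_subjects)

    def test_errors(self):
        with pytest.raises(ValueError):
            make_cv_splits(np.array(["a", "a"]), np.array(["AD", "CN"]), "kfold5")
        subj, groups = subjects_groups(1)
        with pytest.raises(ValueError):
            make_cv_splits(subj, groups, "kfold5")
        with pytest.raises(ValueError):
            make_cv_splits(subj, groups, "bogus")


class TestMetrics:
    def test_arithmetic_case(self):
        y_true = np.array([1] * 10 + [0] * 10)
        y_pred = np.array([1] * 9 + [0] + [1] + [0] * 9)
        m = classification_metrics(y_true, y_pred)
        assert (m.tp, m.fp, m.tn, m.fn) == (9, 1, 9, 1)
        for v in (m.precision, m.sensitivity, m.specificity, m.f1, m.accuracy):
            assert v == pytest.approx(0.9)

    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0, 1])
        m = classification_metrics(y, y, scores=y.astype(float))
        assert m.precision == m.sensitivity == m.specificity == m.f1 == 1.0
        assert m.auc == 1.0

    def test_rank_auc_matches_sklearn(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        scores = rng.standard_normal(200) + y
        m = classification_metrics(y, (scores > 0.5).astype(int), scores)
        assert m.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_random_scores_give_chance_auc(self):
        inside = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1], 100)
            m = classification_metrics(y, y, scores=rng.standard_normal(200))
            inside += 0.4 <= m.auc <= 0.6
        assert inside >= 18

    def test_zero_denominator_flagged_nan(self):
        m = classification_metrics([0, 0], [0, 0])
        assert np.isnan(m.precision) and np.isnan(m.sensitivity)
        assert m.specificity == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            classification_metrics([0, 1], [0])


def planted_fused(seed=0, n_subj_per_group=10, epochs=4, n_channels=8,
                  informative=(0, 1), sep=2.0):
    rng = np.random.default_rng(seed)
    n = 2 * n_subj_per_group * epochs
    labels = np.repeat(["AD", "CN"], n_subj_per_group * epochs)
    subjects = np.repeat([f"{g}{i}" for g in "AC"
                          for i in range(n_subj_per_group)], epochs)
    shift = (labels == "AD").astype(float)
    cols = {}
    for c in range(n_channels):
        base = rng.standard_normal(n)
        if c in informative:
            base = base + sep * shift
        cols[f"CH{c}"] = base
    return pd.DataFrame(cols), labels, subjects


class TestFitness:
    def test_all_zero_mask_penalized(self):
        fused, labels, subjects = planted_fused()
        subj, first = np.unique(subjects, return_index=True)
        splits = make_cv_splits(subj, labels[first], "kfold5", seed=0)
        rec = fitness_accuracy(np.zeros(8, int), fused, labels, subjects,
                               splits, "logistic")
        assert rec.fitness == 0.0

    def test_fitness_bounded_by_optimal_accuracy(self):
        fused, labels, subjects = planted_fused(seed=1)
        subj, first = np.unique(subjects, return_index=True)
        splits = make_cv_splits(subj, labels[first], "kfold5", seed=1)
        rec = fitness_accuracy(np.ones(8, int), fused, labels, subjects,
                               splits, "logistic")
        assert 0.0 <= rec.fitness <= rec.optimal_accuracy <= 1.0
        assert rec.fitness == pytest.approx(rec.per_fold.mean())

    def test_separable_features_reach_high_accuracy(self):
        fused, labels, subjects = planted_fused(seed=2, sep=4.0)
        subj, first = np.unique(subjects, return_index=True)
        splits = make_cv_splits(subj, labels[first], "kfold5", seed=2)
        rec = fitness_accuracy(np.ones(8, int), fused, labels, subjects,
                               splits, "logistic")
        assert rec.fitness >= 0.95

    def test_label_independent_features_stay_at_chance(self):
        accs = []
        for seed in range(20):
            fused, labels, subjects = planted_fused(seed=seed, informative=(),
                                                    sep=0.0)
            subj, first = np.unique(subjects, return_index=True)
            splits = make_cv_splits(subj, labels[first], "kfold5", seed=seed)
            accs.append(fitness_accuracy(np.ones(8, int), fused, labels,
                                         subjects, splits, "logistic").fitness)
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_subject_artifact_does_not_inflate_accuracy(self):
        """Adversarial leakage guard: a feature encoding subject identity
        but no group signal must leave subject-level CV at chance."""
        rng = np.random.default_rng(7)
        n_subj, epochs = 20, 5
        subjects = np.repeat([f"s{i}" for i in range(n_subj)], epochs)
        labels = np.repeat(rng.permutation(np.repeat(["AD", "CN"], n_subj // 2)),
                           epochs)
        subject_code = np.repeat(rng.standard_normal(n_subj) * 5, epochs)
        fused = pd.DataFrame({
            "CH0": subject_code + 0.1 * rng.standard_normal(n_subj * epochs),
            "CH1": rng.standard_normal(n_subj * epochs),
        })
        subj, first = np.unique(subjects, return_index=True)
        splits = make_cv_splits(subj, labels[first], "kfold5", seed=7)
        rec = fitness_accuracy(np.ones(2, int), fused, labels, subjects,
                               splits, "logistic")
        assert 0.25 <= rec.fitness <= 0.75

    def test_record_invariant_enforced(self):
        with pytest.raises(ValueError):
            FitnessRecord(mask=np.ones(2, int), fitness=0.9,
                          optimal_accuracy=0.5, per_fold=np.array([0.9]))


class TestModel:
    cfg = OptimizerConfig(pop_size=10, max_iter=15, seed=0)

    def test_selects_informative_channels(self):
        fused, labels, subjects = planted_fused(seed=3, sep=2.5)
        res = select_channels(fused, labels, subjects, k_channels=2,
                              classifier="logistic", seed=3, config=self.cfg)
        assert res.cardinality == 2
        assert set(res.channel_names) == {"CH0", "CH1"}
        assert res.record.fitness > 0.8

    def test_cardinality_repair_for_all_seeds(self):
        fused, labels, subjects = planted_fused(seed=4)
        for seed in range(3):
            cfg = OptimizerConfig(pop_size=8, max_iter=8, seed=seed)
            res = select_channels(fused, labels, subjects, k_channels=3,
                                  classifier="logistic", seed=seed, config=cfg)
            assert res.cardinality == 3

    def test_deterministic_given_seed(self):
        fused, labels, subjects = planted_fused(seed=5)
        r1 = select_channels(fused, labels, subjects, k_channels=2,
                             classifier="logistic", seed=5, config=self.cfg)
        r2 = select_channels(fused, labels, subjects, k_channels=2,
                             classifier="logistic", seed=5, config=self.cfg)
        np.testing.assert_array_equal(r1.mask, r2.mask)
        assert r1.record.fitness == r2.record.fitness

    def test_threshold_mode_and_summary(self):
        fused, labels, subjects = planted_fused(seed=6, sep=3.0)
        model = ChannelSelectionModel(fused, labels, subjects,
                                      classifier="logistic", seed=6)
        res = model.fit(algorithm="woa_gwo", config=self.cfg)
        assert 1 <= res.cardinality <= 8
        text = res.summary()
        assert "fitness" in text and "channels" in text
        # cache was exercised and masks map to recorded fitness values
        assert len(res.cache) >= 1
        key = tuple(res.mask.tolist())
        if key in res.cache:
            assert res.cache[key] == pytest.approx(res.record.fitness)

    def test_from_dataframe_and_k_validation(self):
        fused, labels, subjects = planted_fused(seed=8)
        frame = fused.copy()
        frame["group"] = labels
        frame["subject"] = subjects
        model = ChannelSelectionModel.from_dataframe(frame,
                                                     classifier="logistic")
        with pytest.raises(ValueError):
            model.fit(k_channels=99)

    def test_gbdt_classifier_spec_smoke(self):
        fused, labels, subjects = planted_fused(seed=9, sep=4.0,
                                                n_subj_per_group=6, epochs=3)
        subj, first = np.unique(subjects, return_index=True)
        splits = make_cv_splits(subj, labels[first], "kfold5", seed=9)
        rec = fitness_accuracy(np.ones(8, int), fused, labels, subjects,
                               splits, "gbdt")
        assert rec.fitness > 0.7
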