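"""Splitting, cross-validation, training, metrics, grid search, baselines."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score as sk_auc

from breathdx.traineval import (
    Confusion,
    SplitSpec,
    TrainConfig,
    accuracy,
    confusion_counts,
    cross_validate,
    cross_validate_predictor,
    evaluate_predictions,
    f1_score,
    grid_search,
    make_folds,
    mse,
    reference_classifiers,
    roc_auc,
    split_dataset,
    train,
)


def blob_data(n=40, dim=5, sep=3.0, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack(
        [rng.normal(0.0, 1.0, size=(half, dim)), rng.normal(sep, 1.0, size=(n - half, dim))]
    )
    y = np.array([0] * half + [1] * (n - half))
    groups = np.array([f"S{i}" for i in range(n)])
    return X, y, groups


class TestSplit:
    def test_fraction_sizes_on_100_subjects(self):
        subjects = [f"S{i}" for i in range(100)]
        labels = [i % 2 for i in range(100)]
        tr, va, te = split_dataset((subjects, labels), SplitSpec(seed=1))
        assert (len(tr), len(va), len(te)) == (60, 30, 10)
        assert set(tr) | set(va) | set(te) == set(subjects)
        assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))

    def test_seed_determinism(self):
        subjects = [f"S{i}" for i in range(30)]
        labels = [i % 2 for i in range(30)]
        a = split_dataset((subjects, labels), SplitSpec(seed=5))
        b = split_dataset((subjects, labels), SplitSpec(seed=5))
        c = split_dataset((subjects, labels), SplitSpec(seed=6))
        assert a == b
        assert a != c

    def test_stratified_split_keeps_class_ratio(self):
        subjects = [f"A{i}" for i in range(20)] + [f"C{i}" for i in range(25)]
        labels = [1] * 20 + [0] * 25
        tr, va, te = split_dataset((subjects, labels), SplitSpec(seed=0, stratified=True))
        for portion, frac in ((tr, 0.6), (va, 0.3), (te, 0.1)):
            n_pos = sum(1 for s in portion if s.startswith("A"))
            assert abs(n_pos - 20 * frac) <= 1
            assert abs((len(portion) - n_pos) - 25 * frac) <= 1

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SplitSpec(train_fraction=0.5, val_fraction=0.3, test_fraction=0.1)

    def test_subject_level_split_of_records(self, small_cohort):
        tr, va, te = split_dataset(small_cohort, SplitSpec(seed=2))
        assert len(tr) + len(va) + len(te) == 20  # subjects, not records


class TestFolds:
    def test_five_folds_of_45_subjects_are_balanced(self):
        subjects = [f"S{i}" for i in range(45)]
        labels = [1] * 20 + [0] * 25
        folds = make_folds(subjects, labels, k=5, seed=0)
        assert [len(f) for f in folds] == [9] * 5
        union = sorted(s for fold in folds for s in fold)
        assert union == sorted(subjects)  # disjoint + exhaustive

    def test_k_larger_than_cohort_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_folds(["a", "b"], [0, 1], k=5)

    def test_subject_level_folding_blocks_replicate_leakage(self):
        """A memorizer that looks up subject identity scores at chance under
        subject-level folds but cheats under naive row-level folds."""
        rng = np.random.default_rng(0)
        n_subjects, reps = 30, 3
        labels_by_subject = rng.integers(0, 2, size=n_subjects)
        rows, y, groups = [], [], []
        for s in range(n_subjects):
            for _ in range(reps):
                rows.append([float(s)])  # the only feature: subject identity
                y.append(labels_by_subject[s])
                groups.append(f"S{s:02d}")
        X, y, groups = np.array(rows), np.array(y), np.array(groups)

        def memorizer(X_tr, y_tr, X_te):
            lookup = {x[0]: lab for x, lab in zip(X_tr, y_tr)}
            return np.array([lookup.get(x[0], 0.5) for x in X_te])

        honest = cross_validate_predictor(X, y, groups, 3, memorizer, seed=0)
        cheating = cross_validate_predictor(
            X, y, groups, 3, memorizer, seed=0, group_level=False
        )
        honest_auc = np.mean([r.auc for r in honest])
        assert abs(honest_auc - 0.5) <= 0.1
        assert np.mean([r.auc for r in cheating]) > 0.9


class TestMetrics:
    @pytest.mark.parametrize(
        "y,p,expected",
        [([1, 0], [1.0, 0.0], 0.0), ([1, 0], [0.5, 0.5], 0.25), ([1], [0.0], 1.0)],
    )
    def test_mse_values(self, y, p, expected):
        assert mse(y, p) == pytest.approx(expected)

    def test_mse_length_mismatch(self):
        with pytest.raises(ValueError):
            mse([1, 0], [0.5])

    @pytest.mark.parametrize(
        "conf,expected",
        [
            (Confusion(10, 0, 0, 0), 1.0),
            (Confusion(0, 0, 3, 2), 0.0),
            (Confusion(8, 0, 2, 4), 0.7273),
        ],
    )
    def test_f1_values(self, conf, expected):
        assert f1_score(conf) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize(
        "conf,expected",
        [
            (Confusion(5, 5, 0, 0), 1.0),
            (Confusion(0, 0, 5, 5), 0.0),
            (Confusion(45, 45, 5, 5), 0.9),
        ],
    )
    def test_accuracy_values(self, conf, expected):
        assert accuracy(conf) == pytest.approx(expected)

    def test_accuracy_is_tp_tn_over_total_by_construction(self):
        y = [1, 1, 0, 0, 1]
        s = [0.9, 0.2, 0.8, 0.1, 0.7]
        report = evaluate_predictions(y, s)
        c = report.confusion
        assert report.accuracy == (c.tp + c.tn) / c.total

    def test_auc_perfect_ties_and_worked_example(self):
        assert roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])[0] == 1.0
        assert roc_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])[0] == 0.5
        assert roc_auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])[0] == 0.75

    def test_auc_matches_bruteforce_pairs_and_sklearn(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = np.round(rng.uniform(size=n), 2)  # rounding forces ties
            auc, _curve = roc_auc(y, s)
            pos, neg = s[y == 1], s[y == 0]
            brute = np.mean(
                (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
            )
            assert auc == pytest.approx(brute, abs=1e-12)
            assert auc == pytest.approx(sk_auc(y, s), abs=1e-12)

    def test_auc_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 1], [0.5, 0.6])


class TestTraining:
    def test_zero_learning_rate_freezes_weights_flat_history(self):
        from breathdx.nn.model import ADENA, ModelConfig

        X, y, _ = blob_data(n=12)
        # disable the stochastic regularizers so epoch losses are comparable
        mcfg = ModelConfig(spatial_dropout_rate=0.0, stochastic_depth_survival=1.0)
        cfg = TrainConfig(learning_rate=0.0, epochs=3, batch_size=12, seed=0)
        model, history = train(mcfg, (X, y), None, cfg)
        np.testing.assert_array_equal(
            model.predict_proba(X), ADENA(mcfg, seed=0).predict_proba(X)
        )
        assert history.train_loss.nunique() == 1

    def test_loss_descends_on_separable_data(self):
        X, y, _ = blob_data(n=24, sep=4.0)
        cfg = TrainConfig(learning_rate=5e-4, epochs=40, batch_size=8, seed=0)
        _model, history = train(None, (X, y), None, cfg)
        assert history.train_loss.iloc[-1] < history.train_loss.iloc[0]

    def test_overfit_toy_set_below_005_within_500_steps(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(loc=c, size=(4, 6)) for c in (0.0, 4.0)])
        y = np.array([0.0] * 4 + [1.0] * 4)
        cfg = TrainConfig(learning_rate=5e-4, epochs=500, batch_size=8, seed=0)
        _model, history = train(None, (X, y), None, cfg)
        assert history.train_loss.iloc[-1] < 0.05

    def test_seeded_history_reproducible(self):
        X, y, _ = blob_data(n=12)
        cfg = TrainConfig(learning_rate=1e-3, epochs=3, batch_size=4, seed=9)
        _m1, h1 = train(None, (X, y), None, cfg)
        _m2, h2 = train(None, (X, y), None, cfg)
        pd.testing.assert_frame_equal(h1, h2)

    def test_validation_history_recorded(self):
        X, y, _ = blob_data(n=16)
        cfg = TrainConfig(epochs=2, batch_size=8, seed=0)
        _m, history = train(None, (X, y), (X, y), cfg)
        assert history.val_loss.notna().all()


class TestCrossValidateAndGrid:
    def test_cv_reports_one_per_fold_on_cohort(self, small_cohort):
        cfg = TrainConfig(learning_rate=1e-3, epochs=10, batch_size=8, seed=0)
        reports = cross_validate(small_cohort, k=4, train_config=cfg, seed=0)
        assert len(reports) == 4
        for r in reports:
            assert 0.0 <= r.accuracy <= 1.0 and 0.0 <= r.auc <= 1.0

    def test_single_config_grid_returns_it(self):
        X, y, groups = blob_data(n=20, sep=4.0)
        ranking, winner = grid_search(
            X, y, groups, k=2, lr_grid=[1e-3], epoch_grid=[5], batch_grid=[8], seed=0
        )
        assert len(ranking) == 1
        assert winner.learning_rate == 1e-3 and winner.epochs == 5

    def test_ranking_is_permutation_of_grid(self):
        X, y, groups = blob_data(n=20, sep=4.0)
        ranking, _ = grid_search(
            X, y, groups, k=2, lr_grid=[1e-3, 1e-2], epoch_grid=[3, 5], batch_grid=[8], seed=0
        )
        combos = {
            (row.learning_rate, row.epochs, row.batch_size) for row in ranking.itertuples()
        }
        assert combos == {(lr, e, 8) for lr in (1e-3, 1e-2) for e in (3, 5)}

    def test_huge_learning_rate_ranks_below_chosen_one(self):
        """On overlapping classes, lr 0.1 destabilizes Adam on tiny batches
        and scores a lower mean F1 than the production lr 5e-4."""
        X, y, groups = blob_data(n=40, dim=5, sep=1.2, seed=4)
        ranking, _ = grid_search(
            X, y, groups, k=3, lr_grid=[1e-1, 5e-4], epoch_grid=[30], batch_grid=[2], seed=0
        )
        f1 = {row.learning_rate: row.mean_f1 for row in ranking.itertuples()}
        assert f1[5e-4] > f1[1e-1]


class TestReferenceClassifiers:
    def test_every_model_beats_chance_on_separable_data(self):
        X, y, groups = blob_data(n=30, sep=4.0)
        table = reference_classifiers(X, y, groups, k=3, seed=0)
        assert len(table) == 6
        assert not table.failed.any()
        assert (table.accuracy > 0.5).all()

    def test_adena_row_appended(self):
        X, y, groups = blob_data(n=30, sep=4.0)
        table = reference_classifiers(
            X, y, groups, k=3, seed=0,
            adena_report={"accuracy": 0.99, "f1": 0.99, "mse": 0.01, "auc": 1.0},
        )
        assert "adena" in set(table.model)
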