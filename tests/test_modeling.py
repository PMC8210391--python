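import numpy as np
import pandas as pd
import pytest

from exopred.features import encode_dataset
from exopred.modeling import (
    ExosomeSecretionModel,
    ModelingError,
    TrainConfig,
    cross_validate,
    default_tree_grid,
    grid_select,
    predict_scores,
    sweep,
    train_forest,
)
from exopred.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="module")
def separable_features(separable_dataset):
    records, _ = separable_dataset
    return records, encode_dataset(records, "AA", require_labels=True)


class TestTrainForest:
    def test_deterministic_for_fixed_seed(self, separable_features):
        records, (X, y) = separable_features
        probe = X.iloc[:20]
        a = train_forest(X, y, n_trees=50, seed=9, scheme="AA")
        b = train_forest(X, y, n_trees=50, seed=9, scheme="AA")
        np.testing.assert_array_equal(a.predict_matrix(probe), b.predict_matrix(probe))

    def test_seed_changes_forest(self, separable_features):
        records, (X, y) = separable_features
        probe = X.iloc[:50]
        a = train_forest(X, y, n_trees=50, seed=1, scheme="AA")
        b = train_forest(X, y, n_trees=50, seed=2, scheme="AA")
        assert not np.array_equal(a.predict_matrix(probe), b.predict_matrix(probe))

    def test_scores_in_unit_interval(self, separable_features):
        records, (X, y) = separable_features
        bundle = train_forest(X, y, n_trees=30, seed=0, scheme="AA")
        scores = bundle.predict_matrix(X)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_single_class_rejected(self, separable_features):
        records, (X, y) = separable_features
        with pytest.raises(ModelingError):
            train_forest(X, np.ones_like(y), n_trees=10, seed=0)

    def test_length_mismatch_rejected(self, separable_features):
        records, (X, y) = separable_features
        with pytest.raises(ModelingError):
            train_forest(X, y[:-1], n_trees=10, seed=0)


class TestTrainConfig:
    def test_default_grid_is_the_31_value_sweep(self):
        grid = default_tree_grid()
        assert len(grid) == 31
        assert grid[0] == 100 and grid[-1] == 10_000
        assert 1000 in grid and 1500 in grid and 8000 in grid
        assert all(b > a for a, b in zip(grid, grid[1:]))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"scheme": "XX"},
            {"tree_grid": (100, 100)},
            {"tree_grid": (500, 100)},
            {"tree_grid": (0,)},
            {"n_folds": 1},
            {"n_repeats": 0},
            {"decision_threshold": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ModelingError):
            TrainConfig(**kwargs)


@pytest.fixture(scope="module")
def cv_small(small_dataset):
    records, _ = small_dataset
    config = TrainConfig(scheme="AA", tree_grid=(30,), n_folds=5, n_repeats=2, seed=4)
    return records, config, cross_validate(records, config)


class TestCrossValidate:
    def test_cell_bookkeeping(self, cv_small):
        records, config, cv = cv_small
        # 2 repeats x 5 folds = 10 cells for the single (scheme, n_trees)
        assert len(cv.cells) == 10
        assert set(cv.cells["repeat"]) == {0, 1}
        assert set(cv.cells["fold"]) == set(range(5))

    def test_folds_partition_dataset(self, cv_small):
        records, config, cv = cv_small
        # each repeat's test folds are disjoint and cover every record
        for repeat in range(config.n_repeats):
            sizes = cv.cells[cv.cells["repeat"] == repeat]["n_test"]
            assert sizes.sum() == len(records)

    def test_folds_are_stratified(self, cv_small):
        records, config, cv = cv_small
        # 50/50 balance with 5 folds: every test fold holds 10+10
        assert set(cv.cells["n_test"]) == {20}

    def test_deterministic_aggregates(self, small_dataset):
        records, _ = small_dataset
        config = TrainConfig(scheme="AA", tree_grid=(25,), n_folds=5, n_repeats=1, seed=2)
        a = cross_validate(records, config).aggregate()
        b = cross_validate(records, config).aggregate()
        pd.testing.assert_frame_equal(a, b)

    def test_class_smaller_than_folds_rejected(self):
        records, _ = generate(SyntheticConfig(n_pos=3, n_neg=30, seed=0))
        config = TrainConfig(scheme="AA", tree_grid=(10,), n_folds=10, n_repeats=1)
        with pytest.raises(ModelingError, match="folds"):
            cross_validate(records, config)

    def test_separable_data_high_accuracy(self, separable_dataset):
        records, _ = separable_dataset
        config = TrainConfig(
            scheme="AA", tree_grid=(100,), n_folds=5, n_repeats=1, seed=0
        )
        agg = cross_validate(records, config).aggregate()
        row = agg.loc[("AA", 100)]
        assert row["acc_mean"] >= 95.0
        assert row["acc_sd"] >= 0.0


class TestGridSelect:
    def _cv_from_rows(self, rows):
        from exopred.modeling import CVResult

        frame = pd.DataFrame(rows)
        for metric in ("auc", "mcc", "se", "sp"):
            frame[metric] = 0.5
        frame["n_test"] = 10
        return CVResult(cells=frame, n_folds=2, n_repeats=1, seed=0)

    def test_single_cell(self):
        cv = self._cv_from_rows(
            [{"scheme": "AA", "n_trees": 100, "repeat": 0, "fold": f, "acc": 70.0} for f in range(2)]
        )
        assert grid_select(cv) == ("AA", 100)

    def test_tie_broken_toward_fewer_trees(self):
        rows = []
        for trees in (500, 3000):
            rows += [
                {"scheme": "DP", "n_trees": trees, "repeat": 0, "fold": f, "acc": 70.0}
                for f in range(2)
            ]
        assert grid_select(self._cv_from_rows(rows)) == ("DP", 500)

    def test_tie_broken_by_scheme_order(self):
        rows = []
        for scheme in ("DP", "PCP"):
            rows += [
                {"scheme": scheme, "n_trees": 100, "repeat": 0, "fold": f, "acc": 70.0}
                for f in range(2)
            ]
        assert grid_select(self._cv_from_rows(rows)) == ("PCP", 100)

    def test_dominant_scheme_selected(self, small_dataset):
        records, _ = small_dataset  # aa_bias: AA should beat PCP-only here
        config = TrainConfig(scheme="AA", tree_grid=(40,), n_folds=5, n_repeats=1, seed=1)
        cv = sweep(records, ["PCP", "AA"], config)
        scheme, _ = grid_select(cv, "ACC")
        assert scheme == "AA"


@pytest.fixture(scope="module")
def bundle(separable_dataset):
    records, _ = separable_dataset
    X, y = encode_dataset(records, "AA", require_labels=True)
    return train_forest(X, y, n_trees=100, seed=0, scheme="AA")


class TestPredictScores:
    def test_positive_class_called_y(self, bundle):
        probe, _ = generate(SyntheticConfig(n_pos=10, n_neg=10, bias_strength=1.0, seed=99))
        result = predict_scores(bundle, probe)
        pos_calls = result.loc[[r.id for r in probe if r.label == 1], "call"]
        assert (pos_calls == "Y").all()

    def test_score_order_invariant(self, bundle):
        probe, _ = generate(SyntheticConfig(n_pos=6, n_neg=6, bias_strength=1.0, seed=5))
        fwd = predict_scores(bundle, probe)
        rev = predict_scores(bundle, probe[::-1])
        for rec in probe:
            assert fwd.loc[rec.id, "score"] == rev.loc[rec.id, "score"]

    def test_threshold_one_never_calls_y(self, bundle):
        probe, _ = generate(SyntheticConfig(n_pos=4, n_neg=4, bias_strength=0.2, seed=6))
        result = predict_scores(bundle, probe, threshold=1.0)
        assert (
            (result["call"] == "N") | (result["score"] >= 1.0)
        ).all()

    def test_duplicate_ids_rejected(self, bundle, tiny_records):
        with pytest.raises(ModelingError, match="duplicate"):
            predict_scores(bundle, tiny_records + tiny_records[:1])


class TestLabelShuffleNull:
    def test_shuffled_labels_give_chance_auc(self):
        """Held-out AUC under label permutation sits at chance level."""
        import dataclasses

        from exopred.metrics import roc_auc

        records, _ = generate(
            SyntheticConfig(n_pos=250, n_neg=250, bias_strength=1.0, seed=21)
        )
        rng = np.random.default_rng(0)
        labels = np.array([r.label for r in records])
        rng.shuffle(labels)
        shuffled = [
            dataclasses.replace(r, label=int(lab)) for r, lab in zip(records, labels)
        ]
        X, y = encode_dataset(shuffled, "AA", require_labels=True)
        from sklearn.model_selection import StratifiedKFold

        scores = np.empty(len(y))
        for train_idx, test_idx in StratifiedKFold(5, shuffle=True, random_state=0).split(X, y):
            bundle = train_forest(X.iloc[train_idx], y[train_idx], 60, seed=0)
            scores[test_idx] = bundle.predict_matrix(X.iloc[test_idx])
        assert 0.45 <= roc_auc(scores, y) <= 0.55


class TestTreeCountStabilization:
    def test_accuracy_stabilizes_with_more_trees(self):
        """Mean |ACC gap| between large tree counts is smaller than between a
        tiny and a large forest — the sweep's stabilization behaviour."""
        gaps_small_large, gaps_large_large = [], []
        for seed in range(5):
            records, _ = generate(
                SyntheticConfig(n_pos=60, n_neg=60, bias_strength=0.35, seed=100 + seed)
            )
            config = TrainConfig(
                scheme="AA", tree_grid=(5, 400, 800), n_folds=5, n_repeats=1, seed=seed
            )
            agg = cross_validate(records, config).aggregate()
            acc = {t: agg.loc[("AA", t)]["acc_mean"] for t in (5, 400, 800)}
            gaps_small_large.append(abs(acc[5] - acc[400]))
            gaps_large_large.append(abs(acc[400] - acc[800]))
        assert np.mean(gaps_large_large) < np.mean(gaps_small_large)


class TestModelResultsApi:
    def test_fit_summary_predict_roundtrip(self, tmp_path):
        records, _ = generate(
            SyntheticConfig(n_pos=40, n_neg=40, bias_strength=0.9, seed=13)
        )
        model = ExosomeSecretionModel(records, scheme="AA")
        results = model.fit(n_trees=60, seed=1, n_folds=4, n_repeats=2)
        est = results.estimates
        assert est is not None and 0 <= est["auc_mean"] <= 1
        text = results.summary()
        assert "AA" in text and "ACC" in text and "±" in text
        out = results.predict(records[:10])
        assert set(out.columns) == {"score", "call"}
        path = tmp_path / "m.joblib"
        results.save(path)
        from exopred.io_formats import load_model

        loaded = load_model(path)
        np.testing.assert_array_equal(
            predict_scores(loaded, records[:10])["score"].to_numpy(),
            out["score"].to_numpy(),
        )

    def test_from_fasta_constructor(self, tmp_path):
        from exopred.io_formats import write_fasta

        records, _ = generate(SyntheticConfig(n_pos=15, n_neg=15, seed=2))
        write_fasta([r for r in records if r.label == 1], tmp_path / "pos.fa")
        write_fasta([r for r in records if r.label == 0], tmp_path / "neg.fa")
        model = ExosomeSecretionModel.from_fasta(
            tmp_path / "pos.fa", tmp_path / "neg.fa", scheme="AA"
        )
        assert model.n_pos == 15 and model.n_neg == 15

    def test_unlabeled_records_rejected(self, tiny_records):
        with pytest.raises(ModelingError):
            ExosomeSecretionModel(tiny_records)
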