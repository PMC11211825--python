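"""Splits, metrics (vs independent oracles) and the training loop."""

import itertools

import numpy as np
import pytest

from dtafusion import DTAModel, ModelConfig
from dtafusion.training_eval import (
    AffinityRecord,
    TrainConfig,
    TrainingDivergedError,
    classification_metrics,
    clustering_metrics,
    concordance_index,
    evaluate_split,
    featurize_entities,
    make_cold_split,
    make_kfold_split,
    make_random_split,
    regression_metrics,
    rm2_metric,
    train_model,
)


def grid_records(n_drugs, n_prots, rng=None):
    rng = rng or np.random.default_rng(0)
    return [
        AffinityRecord(f"d{i}", f"t{j}", float(rng.normal(5, 1)))
        for i in range(n_drugs)
        for j in range(n_prots)
    ]


class TestKFold:
    def test_twelve_records_six_folds_of_two(self):
        records = grid_records(3, 4)
        specs = make_kfold_split(records, k=6, seed=0)
        assert len(specs) == 6
        assert all(len(s.test) == 2 for s in specs)
        assert all(len(s.train) == 10 for s in specs)

    def test_test_folds_cover_all_records(self):
        records = grid_records(4, 5)
        specs = make_kfold_split(records, k=6, seed=1)
        covered = sorted(i for s in specs for i in s.test)
        assert covered == list(range(20))

    def test_fold_sizes_within_one(self):
        specs = make_kfold_split(grid_records(4, 5), k=6, seed=2)
        sizes = [len(s.test) for s in specs]
        assert max(sizes) - min(sizes) <= 1

    def test_seed_reproducible(self):
        records = grid_records(3, 4)
        a = make_kfold_split(records, seed=7)
        b = make_kfold_split(records, seed=7)
        assert all(x.assignments == y.assignments for x, y in zip(a, b))

    def test_too_few_records_raises(self):
        with pytest.raises(ValueError):
            make_kfold_split(grid_records(1, 3), k=6)


class TestColdSplits:
    @pytest.mark.parametrize("mode", ["cold_drug", "cold_protein", "cold_pair"])
    def test_no_entity_overlap(self, mode):
        records = grid_records(8, 8)
        spec = make_cold_split(records, mode, frac_test=0.25, seed=0)
        train_d = {records[i].drug_id for i in spec.train}
        test_d = {records[i].drug_id for i in spec.test}
        train_t = {records[i].target_id for i in spec.train}
        test_t = {records[i].target_id for i in spec.test}
        if mode in ("cold_drug", "cold_pair"):
            assert not (train_d & test_d)
        if mode in ("cold_protein", "cold_pair"):
            assert not (train_t & test_t)

    def test_cold_pair_grid_count_matches_enumeration(self):
        # 4x4 grid, frac 0.25: 1 held-out drug x 1 held-out protein -> exactly
        # 1 test pair; 3x3 = 9 train pairs; 6 mixed pairs unused
        records = grid_records(4, 4)
        spec = make_cold_split(records, "cold_pair", frac_test=0.25, seed=3)
        assert len(spec.test) == 1
        assert len(spec.train) == 9
        assert len(spec.indices("unused")) == 6

    def test_validation_carved_from_train_entities(self):
        records = grid_records(10, 10)
        spec = make_cold_split(records, "cold_drug", frac_test=0.2, seed=1, frac_val=0.1)
        assert spec.val
        test_drugs = {records[i].drug_id for i in spec.test}
        val_drugs = {records[i].drug_id for i in spec.val}
        assert not (test_drugs & val_drugs)

    def test_infeasible_fraction_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            make_cold_split(grid_records(2, 2), "cold_drug", frac_test=0.01)


class TestConcordanceIndex:
    def test_perfect_ranking(self):
        assert concordance_index([1, 2, 3], [0.1, 0.2, 0.3]) == 1.0

    def test_inverted_ranking(self):
        assert concordance_index([1, 2, 3], [0.3, 0.2, 0.1]) == 0.0

    def test_enumerated_three_point_example(self):
        assert concordance_index([1, 2, 3], [0.2, 0.1, 0.3]) == pytest.approx(2 / 3)

    def test_predicted_ties_score_half(self):
        assert concordance_index([1, 2], [0.5, 0.5]) == 0.5

    def test_true_ties_excluded(self):
        # only the (1,2) vs others pairs count; (1,1) pair is dropped
        assert concordance_index([1, 1, 2], [0.1, 0.9, 0.5]) == 0.5

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        p = rng.normal(size=30)
        base = concordance_index(y, p)
        for f in (np.exp, lambda x: 3 * x + 7, np.arctan):
            assert concordance_index(y, f(p)) == pytest.approx(base)

    def test_matches_survival_library(self):
        from lifelines.utils import concordance_index as lifelines_ci

        rng = np.random.default_rng(1)
        for _ in range(10):
            y = rng.normal(size=15)
            p = rng.normal(size=15)
            assert concordance_index(y, p) == pytest.approx(lifelines_ci(y, p))

    def test_pairwise_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 5, size=12).astype(float)  # with ties
        p = rng.normal(size=12)
        num = den = 0.0
        for i, j in itertools.combinations(range(12), 2):
            if y[i] == y[j]:
                continue
            den += 1
            d = (p[j] - p[i]) * (y[j] - y[i])
            num += 1.0 if d > 0 else (0.5 if d == 0 else 0.0)
        assert concordance_index(y, p) == pytest.approx(num / den, abs=1e-8)


class TestRm2:
    def test_perfect_prediction_is_one(self):
        assert rm2_metric([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_constant_prediction_raises(self):
        with pytest.raises(ValueError):
            rm2_metric([1, 2, 3], [2, 2, 2])

    def test_frozen_spreadsheet_example(self):
        # value computed with an independent straight-line evaluation of
        # r2*(1-sqrt(|r2-r0_sq|)) before this implementation existed
        assert rm2_metric([1, 2, 3, 4], [1.1, 1.9, 3.2, 3.8]) == pytest.approx(
            0.9436702363254914, abs=1e-10
        )

    def test_never_exceeds_r_squared(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = rng.normal(size=10)
            p = y + rng.normal(scale=0.5, size=10)
            r2 = np.corrcoef(y, p)[0, 1] ** 2
            assert rm2_metric(y, p) <= r2 + 1e-12


class TestRegressionMetrics:
    def test_identical_vectors(self):
        rep = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.mse == 0.0
        assert rep.pearson == pytest.approx(1.0)
        assert rep.spearman == pytest.approx(1.0)

    def test_swapped_pair_mse(self):
        assert regression_metrics([0.0, 1.0], [1.0, 0.0]).mse == pytest.approx(1.0)

    def test_brute_force_sums_oracle(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=20)
        p = rng.normal(size=20)
        rep = regression_metrics(y, p)
        mse = sum((a - b) ** 2 for a, b in zip(y, p)) / 20
        sy, sp = y - y.mean(), p - p.mean()
        pearson = (sy * sp).sum() / np.sqrt((sy**2).sum() * (sp**2).sum())
        assert rep.mse == pytest.approx(mse, abs=1e-10)
        assert rep.pearson == pytest.approx(pearson, abs=1e-10)


class TestClassificationMetrics:
    def test_perfect_separation(self):
        rep = classification_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert rep.auc == 1.0
        assert rep.f1 == 1.0

    def test_all_positive_predictions(self):
        rep = classification_metrics([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.6])
        assert rep.precision == pytest.approx(0.5)
        assert rep.recall == pytest.approx(1.0)

    def test_auc_pair_counting_oracle(self):
        labels = np.array([0, 1, 0, 1, 1, 0])
        probs = np.array([0.2, 0.7, 0.4, 0.6, 0.3, 0.5])
        wins = total = 0.0
        for i in np.flatnonzero(labels == 1):
            for j in np.flatnonzero(labels == 0):
                total += 1
                wins += 1.0 if probs[i] > probs[j] else (0.5 if probs[i] == probs[j] else 0.0)
        assert classification_metrics(labels, probs).auc == pytest.approx(wins / total)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            classification_metrics([1, 1, 1], [0.5, 0.6, 0.7])


class TestClusteringMetrics:
    def test_tight_far_blobs(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.01, size=(10, 2))
        b = rng.normal(10, 0.01, size=(10, 2))
        rep = clustering_metrics(np.vstack([a, b]), [0] * 10 + [1] * 10)
        assert rep.sc > 0.95
        assert rep.dbi < 0.05
        assert rep.chi > 1000

    def test_degenerate_identical_points_raise(self):
        with pytest.raises(ValueError):
            clustering_metrics(np.ones((8, 3)), [0, 0, 0, 0, 1, 1, 1, 1])

    def test_silhouette_hand_oracle_small(self):
        pts = np.array(
            [[0, 0], [0, 1], [1, 0], [1, 1], [0.5, 0.5], [5, 5], [5, 6], [6, 5], [6, 6], [5.5, 5.5]]
        )
        labels = np.array([0] * 5 + [1] * 5)
        sil = []
        for i in range(10):
            same = [j for j in range(10) if labels[j] == labels[i] and j != i]
            other = [j for j in range(10) if labels[j] != labels[i]]
            a = np.mean([np.linalg.norm(pts[i] - pts[j]) for j in same])
            b = np.mean([np.linalg.norm(pts[i] - pts[j]) for j in other])
            sil.append((b - a) / max(a, b))
        rep = clustering_metrics(pts, labels)
        assert rep.sc == pytest.approx(np.mean(sil), abs=1e-8)


@pytest.fixture(scope="module")
def tiny_setup(tiny_benchmark, small_config):
    records = tiny_benchmark.records
    drug_graphs, protein_reps = featurize_entities(
        tiny_benchmark.ligands, tiny_benchmark.proteins, small_config
    )
    return records, drug_graphs, protein_reps


class TestTraining:
    def test_one_epoch_smoke(self, tiny_setup, small_config):
        records, dg, pr = tiny_setup
        spec = make_random_split(records, seed=0)
        model = DTAModel(small_config)
        history = train_model(
            model, dg, pr, records, spec, TrainConfig(epochs=1, batch_size=16, seed=0)
        )
        assert len(history["train_loss"]) == 1
        assert np.isfinite(history["train_loss"][0])

    def test_memorizes_four_pairs(self, tiny_setup, small_config):
        records, dg, pr = tiny_setup
        subset = records[::6][:4]  # four pairs with distinct drugs and proteins
        spec = make_random_split(subset, fractions=(1.0, 0.0, 0.0), seed=0)
        model = DTAModel(small_config)
        history = train_model(
            model, dg, pr, subset, spec, TrainConfig(epochs=400, batch_size=4, lr=5e-3, seed=0)
        )
        assert history["train_loss"][-1] < 0.05

    def test_divergence_detected(self, tiny_setup, small_config):
        records, dg, pr = tiny_setup
        spec = make_random_split(records, seed=0)
        model = DTAModel(small_config)
        model.head.layers[-1].bias.data = np.array([np.inf])
        with pytest.raises(TrainingDivergedError):
            train_model(model, dg, pr, records, spec, TrainConfig(epochs=1, seed=0))

    def test_evaluate_split_reports_regression_metrics(self, tiny_setup, small_config):
        records, dg, pr = tiny_setup
        spec = make_random_split(records, seed=1)
        model = DTAModel(small_config)
        train_model(model, dg, pr, records, spec, TrainConfig(epochs=2, batch_size=32, seed=0))
        rep = evaluate_split(model, dg, pr, records, spec)
        assert rep.mse is not None and np.isfinite(rep.mse)
        assert 0 <= rep.ci <= 1
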