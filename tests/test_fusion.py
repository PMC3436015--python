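"""Vote/weight algebra, base-classifier training and the fused pipeline."""

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

import swnc
from swnc.features import FeatureMatrix
from swnc.fusion import (
    DegenerateWeightsError,
    FitConfig,
    NodeClassifier,
    StratificationError,
    TrainedSWNC,
    _acceptance_to_scores,
)

TINY_FIT = FitConfig(k_grid=(1, 3), n_features=5, grid_cv_folds=2)


class TestWeights:
    def test_already_normalized_rates_pass_through(self):
        assert np.allclose(swnc.class_weights([0.5, 0.3, 0.2]), [0.5, 0.3, 0.2])

    def test_rates_divided_by_their_sum(self):
        assert np.allclose(swnc.class_weights([0.8, 0.6, 0.6]), [0.4, 0.3, 0.3])
        assert np.allclose(swnc.node_weights([0.9, 0.6]), [0.6, 0.4])

    def test_equal_rates_give_uniform_weights(self):
        assert np.allclose(swnc.class_weights([0.7] * 4), [0.25] * 4)

    def test_single_node_degenerates_to_one(self):
        assert np.allclose(swnc.node_weights([0.42]), [1.0])

    def test_all_zero_rates_rejected(self):
        with pytest.raises(DegenerateWeightsError):
            swnc.class_weights([0.0, 0.0])

    def test_out_of_range_rates_rejected(self):
        with pytest.raises(ValueError):
            swnc.class_weights([0.5, 1.2])


class TestVoteAlgebra:
    def test_acceptance_is_class_indicator(self):
        assert np.array_equal(swnc.vote(True, 1, 3), [1, 0, 0])

    def test_rejection_votes_for_all_other_classes(self):
        assert np.array_equal(swnc.vote(False, 2, 3), [1, 0, 1])

    def test_two_class_complement_coincidence(self):
        assert np.array_equal(swnc.vote(True, 1, 2), swnc.vote(False, 2, 2))

    def test_abstain_encoding_mutes_rejections(self):
        assert np.array_equal(swnc.vote(False, 2, 3, encoding="abstain"), [0, 0, 0])
        assert np.array_equal(swnc.vote(True, 2, 3, encoding="abstain"), [0, 1, 0])

    def test_node_output_weighted_votes(self):
        votes = np.vstack([swnc.vote(True, 1, 2), swnc.vote(False, 2, 2)])
        assert np.allclose(swnc.node_output(votes, [0.6, 0.4]), [1.0, 0.0])

    def test_all_accepting_returns_lambda(self):
        lam = np.array([0.2, 0.3, 0.5])
        votes = np.vstack([swnc.vote(True, n, 3) for n in (1, 2, 3)])
        assert np.allclose(swnc.node_output(votes, lam), lam)

    def test_uniform_weights_reduce_to_vote_share(self):
        votes = np.vstack(
            [swnc.vote(True, 1, 3), swnc.vote(True, 1 + 1, 3), swnc.vote(False, 3, 3)]
        )
        out = swnc.node_output(votes, np.full(3, 1 / 3))
        assert np.allclose(out, votes.sum(axis=0) / 3)

    def test_argmax_and_tie_rules(self):
        assert swnc.node_predict([0.2, 0.7, 0.1]) == 2
        assert swnc.node_predict([0.5, 0.5, 0.0]) == 1
        assert swnc.network_predict([0.85, 0.15]) == 1

    def test_network_output_symmetric_conflict(self):
        assert np.allclose(
            swnc.network_output(np.array([[1.0, 0.0], [0.0, 1.0]]), [0.5, 0.5]),
            [0.5, 0.5],
        )

    def test_single_node_network_is_identity(self):
        o = np.array([[0.3, 0.7]])
        assert np.allclose(swnc.network_output(o, [1.0]), o[0])

    def test_one_hot_majority_recovered(self):
        outputs = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        fused = swnc.network_output(outputs, np.full(3, 1 / 3))
        assert np.allclose(fused, [2 / 3, 1 / 3])
        assert swnc.network_predict(fused) == 1

    def test_vectorized_scores_match_scalar_votes(self):
        rng = np.random.default_rng(0)
        for encoding in ("complement", "abstain"):
            accept = rng.random((20, 4)) < 0.5
            lam = swnc.class_weights(rng.random(4))
            scores = _acceptance_to_scores(accept, lam, encoding)
            for w in range(20):
                votes = np.vstack(
                    [swnc.vote(bool(accept[w, n]), n + 1, 4, encoding) for n in range(4)]
                )
                assert np.allclose(scores[w], swnc.node_output(votes, lam), atol=1e-12)


def brute_force_grid(X, y_bin, k_grid, folds):
    """Exhaustive per-k cross-validation with refits: the grid-search oracle."""
    table = {}
    skf = StratifiedKFold(n_splits=folds, shuffle=False)
    for k in k_grid:
        hits = 0
        for tr, te in skf.split(X, y_bin):
            clf = KNeighborsClassifier(n_neighbors=k).fit(X[tr], y_bin[tr])
            hits += int((clf.predict(X[te]) == y_bin[te]).sum())
        table[k] = hits / len(y_bin)
    best = max(table.values())
    return next(k for k in sorted(k_grid) if table[k] == best), table


class TestTrainBase:
    def _fm(self, values, labels):
        names = tuple(f"f{i}" for i in range(values.shape[1]))
        return FeatureMatrix(values, names, labels, sensor_id=1)

    def test_separable_data_perfect_with_k1(self):
        labels = np.repeat([1, 2], 10)
        values = np.concatenate([np.linspace(0, 1, 10), np.linspace(5, 6, 10)])
        clf = swnc.train_base(self._fm(values[:, None], labels), 1, k_grid=(1,))
        accept = clf.decide(values[:, None])
        assert np.array_equal(accept, labels == 1)

    def test_chosen_k_matches_exhaustive_grid_oracle(self):
        rng = np.random.default_rng(4)
        n = 60
        labels = np.repeat([1, 2], n // 2)
        values = rng.normal(size=(n, 3)) + np.where(labels == 1, 0.0, 1.2)[:, None]
        fm = self._fm(values, labels)
        clf = swnc.train_base(fm, 1, k_grid=(1, 3, 5), n_folds=5)
        mean, scale = values.mean(axis=0), values.std(axis=0)
        k_oracle, table = brute_force_grid(
            (values - mean) / scale, (labels == 1).astype(int), (1, 3, 5), 5
        )
        assert clf.k == k_oracle
        for k in (1, 3, 5):
            assert clf.cv_table[k] == pytest.approx(table[k])

    def test_single_class_input_rejected(self):
        with pytest.raises(ValueError):
            swnc.train_base(self._fm(np.zeros((10, 2)), np.ones(10, dtype=int)), 1)

    def test_even_k_rejected(self):
        labels = np.repeat([1, 2], 5)
        with pytest.raises(ValueError):
            swnc.train_base(self._fm(np.zeros((10, 1)), labels), 1, k_grid=(2,))

    def test_too_few_samples_for_grid_rejected(self):
        labels = np.array([1, 2, 1, 2])
        with pytest.raises(ValueError):
            swnc.train_base(self._fm(np.zeros((4, 1)), labels), 1, k_grid=(9,))


class _StubBase:
    """Base classifier whose decisions come from a fixed per-row table."""

    def __init__(self, accept_col):
        self.accept_col = np.asarray(accept_col, dtype=bool)

    def decide(self, rows):
        return self.accept_col[rows[:, 0].astype(int)]


def make_stub_model(accept, lam, mu, encoding="complement"):
    """A TrainedSWNC with fixed base decisions: accept has shape (W, M, N)."""
    w, m, n = accept.shape
    bank = swnc.FeatureBank(
        tuple(f"f{i}" for i in range(3)), lambda x, y, r: np.zeros((x.shape[0], 3))
    )
    class_labels = np.arange(1, n + 1)
    nodes = [
        NodeClassifier(
            sensor_id=j + 1,
            classifiers=[_StubBase(accept[:, j, q]) for q in range(n)],
            lam=np.asarray(lam[j], dtype=float),
            class_labels=class_labels,
            vote_encoding=encoding,
        )
        for j in range(m)
    ]
    model = TrainedSWNC(
        nodes=nodes,
        mu=np.asarray(mu, dtype=float),
        class_labels=class_labels,
        bank=bank,
        rate=1.0,
        config=FitConfig(),
    )
    feats = [np.repeat(np.arange(w, dtype=float)[:, None], 3, axis=1) for _ in range(m)]
    return model, feats


def brute_force_pipeline(accept_row, lam, mu):
    """Independent straight-line evaluation of the whole vote -> fuse chain."""
    m, n = accept_row.shape
    o_net = np.zeros(n)
    for j in range(m):
        o_node = np.zeros(n)
        for cn in range(n):
            for q in range(n):
                if accept_row[j, cn]:
                    ynq = 1.0 if q == cn else 0.0
                else:
                    ynq = 0.0 if q == cn else 1.0
                o_node[q] += lam[j][cn] * ynq
        o_net += mu[j] * o_node
    return int(np.argmax(o_net)) + 1


class TestPredictPipeline:
    def test_hand_built_two_node_model(self):
        # node 1: accept class 1, reject class 2 -> O1 = (1, 0)
        # node 2: accept both -> O2 = (0.5, 0.5)
        accept = np.array([[[True, False], [True, True]]])
        model, feats = make_stub_model(
            accept, lam=[[0.6, 0.4], [0.5, 0.5]], mu=[0.7, 0.3]
        )
        result = model.predict_from_features(feats)
        assert np.allclose(result.node_scores[0, 0], [1.0, 0.0])
        assert np.allclose(result.node_scores[0, 1], [0.5, 0.5])
        assert np.allclose(result.network_scores[0], [0.85, 0.15])
        assert result.classes[0] == 1

    def test_matches_brute_force_on_random_small_models(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            m = rng.integers(1, 4)
            n = rng.integers(2, 5)
            w = rng.integers(1, 6)
            accept = rng.random((w, m, n)) < 0.5
            lam = [swnc.class_weights(rng.uniform(0.05, 1.0, n)) for _ in range(m)]
            mu = swnc.node_weights(rng.uniform(0.05, 1.0, m))
            model, feats = make_stub_model(accept, lam, mu)
            result = model.predict_from_features(feats)
            for row in range(w):
                assert result.classes[row] == brute_force_pipeline(
                    accept[row], lam, mu
                )

    def test_uniform_weights_reduce_to_plurality_vote(self):
        rng = np.random.default_rng(23)
        for _ in range(300):
            m = rng.integers(1, 6)
            n = rng.integers(2, 6)
            accept = rng.random((1, m, n)) < 0.4
            lam = [np.full(n, 1.0 / n)] * m
            mu = np.full(m, 1.0 / m)
            model, feats = make_stub_model(accept, lam, mu)
            predicted = model.predict_from_features(feats).classes[0]
            counts = accept[0].sum(axis=0)  # acceptances per class across nodes
            winners = np.flatnonzero(counts == counts.max()) + 1
            if winners.size == 1:
                assert predicted == winners[0]
            else:
                # exact count ties: weighted sums differ only by rounding noise
                assert predicted in winners

    def test_unanimous_one_hot_nodes_win_for_any_weights(self):
        rng = np.random.default_rng(5)
        n, m = 4, 3
        target = 3
        accept = np.zeros((1, m, n), dtype=bool)
        accept[0, :, target - 1] = True  # every node accepts only the target class
        for _ in range(10):
            lam = [swnc.class_weights(rng.uniform(0.1, 1.0, n)) for _ in range(m)]
            mu = swnc.node_weights(rng.uniform(0.1, 1.0, m))
            model, feats = make_stub_model(accept, lam, mu)
            assert model.predict_from_features(feats).classes[0] == target


class TestFit:
    def test_weights_sum_to_one_and_scores_bounded(self, tiny_dataset):
        model = swnc.fit(tiny_dataset, TINY_FIT)
        for node in model.nodes:
            assert abs(node.lam.sum() - 1.0) < 1e-12
        assert abs(model.mu.sum() - 1.0) < 1e-12
        result = model.predict(tiny_dataset)
        assert np.all(result.node_scores >= -1e-12)
        assert np.all(result.node_scores <= 1.0 + 1e-12)
        assert np.all(result.network_scores >= -1e-12)
        assert np.all(result.network_scores <= 1.0 + 1e-12)

    def test_refit_same_seed_is_identical(self, tiny_dataset):
        a = swnc.fit(tiny_dataset, TINY_FIT)
        b = swnc.fit(tiny_dataset, TINY_FIT)
        assert np.array_equal(a.mu, b.mu)
        for na, nb in zip(a.nodes, b.nodes):
            assert np.array_equal(na.lam, nb.lam)
            assert [c.k for c in na.classifiers] == [c.k for c in nb.classifiers]
        pa = a.predict(tiny_dataset)
        pb = b.predict(tiny_dataset)
        assert np.array_equal(pa.classes, pb.classes)

    def test_pure_noise_sensor_gets_smallest_node_weight(self, tiny_dataset):
        ds = tiny_dataset.copy()
        rng = np.random.default_rng(99)
        j = ds.sensor_index(2)
        ds.x[:, j] = rng.normal(size=ds.x[:, j].shape)
        ds.y[:, j] = rng.normal(size=ds.y[:, j].shape)
        model = swnc.fit(ds, TINY_FIT)
        assert np.argmin(model.mu) == j

    def test_missing_class_in_subset_raises_stratification_error(self, tiny_dataset):
        keep = np.flatnonzero(tiny_dataset.labels != 3)
        two_of_three = np.concatenate(
            [keep, np.flatnonzero(tiny_dataset.labels == 3)[:2]]
        )
        with pytest.raises(StratificationError):
            swnc.fit(tiny_dataset.select_windows(np.sort(two_of_three)), TINY_FIT)

    def test_single_node_model_mirrors_its_node(self, tiny_dataset):
        sub = tiny_dataset.select_sensors([1])
        model = swnc.fit(sub, TINY_FIT)
        assert np.allclose(model.mu, [1.0])
        result = model.predict(sub)
        assert np.array_equal(result.classes, result.node_classes[:, 0])

    def test_cv_weight_mode_produces_normalized_weights(self, tiny_dataset):
        model = swnc.fit(
            tiny_dataset,
            FitConfig(k_grid=(1, 3), n_features=5, weight_mode="cv", cv_folds=4,
                      grid_cv_folds=2),
        )
        for node in model.nodes:
            assert abs(node.lam.sum() - 1.0) < 1e-12
        assert abs(model.mu.sum() - 1.0) < 1e-12

    def test_feature_selection_is_frozen_after_fit(self, tiny_dataset):
        model = swnc.fit(tiny_dataset, TINY_FIT)
        before = [
            tuple(c.feature_indices) for node in model.nodes for c in node.classifiers
        ]
        model.predict(tiny_dataset)  # scoring new data must not re-rank
        after = [
            tuple(c.feature_indices) for node in model.nodes for c in node.classifiers
        ]
        assert before == after
        for node in model.nodes:
            for c in node.classifiers:
                assert len(c.feature_indices) == TINY_FIT.n_features
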