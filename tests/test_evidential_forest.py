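"""Evidential trees, the conflict-gain criterion and the co-leaf kernel,
checked against exhaustive brute-force oracles on small inputs."""

import numpy as np
import pytest

from fkeerf.belief_core import (
    MassFunction,
    binary_frame,
    categorical_mass,
    conflict,
    jaccard_matrix,
    pignistic,
    vacuous_mass,
)
from fkeerf.evidential_forest import (
    EvidentialForest,
    ForestParams,
    best_split,
    build_tree,
    fit_forest,
    forest_from_dict,
    forest_to_dict,
    kernel_matrix,
    kernel_vector,
    node_info,
    predict_label,
    predict_label_batch,
    predict_mass_erf,
    predict_value,
    predict_value_batch,
    route_batch,
    tree_route,
)

FRAME = binary_frame()
MPOS = categorical_mass(FRAME, 1)
MNEG = categorical_mass(FRAME, -1)


def crisp_masses(y):
    return [MPOS if yi == 1 else MNEG for yi in y]


def pairwise_info(masses):
    """O(s^2) oracle: mean pairwise conflict over ordered pairs."""
    s = len(masses)
    if s <= 1:
        return 0.0
    D = jaccard_matrix(FRAME)
    tot = sum(
        conflict(masses[i], masses[j], D)
        for i in range(s)
        for j in range(s)
        if i != j
    )
    return tot / (s * s - s)


def brute_force_best_split(X, masses, params):
    """Exhaustive maximizer over every (attribute, midpoint threshold)."""
    m, n = X.shape
    best = None
    for j in range(n):
        uvals = np.unique(X[:, j])
        for thr in (uvals[:-1] + uvals[1:]) / 2.0:
            left = X[:, j] <= thr
            nl = int(left.sum())
            if nl < params.min_leaf_samples or m - nl < params.min_leaf_samples:
                continue
            gain = pairwise_info(masses) - (
                nl * pairwise_info([masses[i] for i in np.where(left)[0]])
                + (m - nl) * pairwise_info([masses[i] for i in np.where(~left)[0]])
            ) / m
            if best is None or gain > best[2]:
                best = (j, thr, gain)
    if best is None or best[2] <= params.gain_tol:
        return None
    return best


class TestNodeInfo:
    def test_two_two_node(self):
        assert node_info(crisp_masses([1, 1, -1, -1])) == pytest.approx(8 / 12)

    def test_pure_and_singleton_nodes(self):
        assert node_info(crisp_masses([1, 1, 1])) == 0.0
        assert node_info(crisp_masses([1])) == 0.0
        assert node_info([]) == 0.0

    def test_crisp_fast_path_equals_pairwise(self, rng):
        for _ in range(20):
            y = rng.choice([1, -1], size=rng.integers(2, 10))
            masses = crisp_masses(y)
            assert node_info(masses) == pairwise_info(masses)

    def test_general_masses_path(self):
        # mixed masses force the O(s^2) route; vacuous conflicts with nothing
        masses = [MPOS, MNEG, vacuous_mass(FRAME)]
        assert node_info(masses) == pytest.approx(2 / 6)


class TestBestSplit:
    def test_perfect_1d_separation(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        masses = crisp_masses([1, 1, -1, -1])
        params = ForestParams(min_leaf_samples=1, exhaustive_thresholds=True)
        attr, thr, gain = best_split(X, masses, [0], params)
        assert attr == 0
        assert 1.0 < thr < 10.0
        assert gain == pytest.approx(2 / 3)

    def test_pure_node_returns_none(self):
        X = np.arange(6, dtype=float)[:, None]
        params = ForestParams(min_leaf_samples=1)
        assert best_split(X, crisp_masses([1] * 6), [0], params) is None

    def test_matches_exhaustive_brute_force(self, rng):
        params = ForestParams(min_leaf_samples=1, exhaustive_thresholds=True)
        for trial in range(30):
            m = int(rng.integers(4, 13))
            n = int(rng.integers(1, 4))
            X = np.round(rng.normal(size=(m, n)), 2)
            y = rng.choice([1, -1], size=m)
            if len(np.unique(y)) < 2:
                continue
            masses = crisp_masses(y)
            ours = best_split(X, masses, range(n), params)
            oracle = brute_force_best_split(X, masses, params)
            if oracle is None:
                assert ours is None
                continue
            assert ours is not None
            # the chosen split achieves the brute-force maximum gain
            assert ours[2] == pytest.approx(oracle[2], abs=1e-9)

    def test_tie_breaks_toward_lower_attribute(self):
        # two identical perfectly-separating attributes
        col = np.array([0.0, 0.0, 1.0, 1.0])
        X = np.stack([col, col], axis=1)
        params = ForestParams(min_leaf_samples=1, exhaustive_thresholds=True)
        attr, _, _ = best_split(X, crisp_masses([1, 1, -1, -1]), [1, 0], params)
        assert attr == 0


class TestBuildAndRoute:
    def test_separable_data_gives_pure_leaves(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (20, 2)), rng.normal(5, 0.3, (20, 2))])
        y = np.array([1] * 20 + [-1] * 20)
        tree = build_tree(
            X, crisp_masses(y), ForestParams(min_leaf_samples=2),
            np.random.default_rng(0),
        )
        for xi, yi in zip(X, y):
            leaf = tree_route(tree, xi)
            bet = pignistic(leaf.leaf_mass)
            assert bet.tolist() == ([1.0, 0.0] if yi == 1 else [0.0, 1.0])

    def test_min_leaf_equal_m_gives_root_leaf(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([1] * 6 + [-1] * 4)
        tree = build_tree(
            X, crisp_masses(y), ForestParams(min_leaf_samples=10),
            np.random.default_rng(0),
        )
        assert tree.is_leaf
        assert tree.leaf_mass.masses[1] == pytest.approx(0.6)  # class proportions
        assert tree_route(tree, X[0]) is tree

    def test_same_seed_same_tree(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.choice([1, -1], size=30)
        y[:2] = [1, -1]
        t1 = build_tree(X, crisp_masses(y), ForestParams(), np.random.default_rng(7))
        t2 = build_tree(X, crisp_masses(y), ForestParams(), np.random.default_rng(7))
        from fkeerf.evidential_forest import tree_to_dict

        assert tree_to_dict(t1) == tree_to_dict(t2)

    def test_boundary_value_goes_left(self):
        X = np.array([[0.0], [0.0], [2.0], [2.0]])
        masses = crisp_masses([1, 1, -1, -1])
        tree = build_tree(
            X, masses, ForestParams(min_leaf_samples=1), np.random.default_rng(0)
        )
        assert not tree.is_leaf
        at_thr = np.array([tree.thr])
        leaf = tree_route(tree, at_thr)
        assert leaf is tree_route(tree, np.array([tree.thr - 1e-9]))

    def test_inbag_sample_routes_to_its_leaf(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.choice([1, -1], size=40)
        y[:2] = [1, -1]
        forest = fit_forest(X, y, ForestParams(W=3, seed=5))
        for tree, ids in zip(forest.trees, forest.bootstrap_ids):
            for orig in ids[:10]:
                leaf = tree_route(tree, X[orig])
                assert orig in leaf.inbag_ids

    def test_route_batch_matches_single_routing(self, rng):
        X = rng.normal(size=(25, 3))
        y = rng.choice([1, -1], size=25)
        y[:2] = [1, -1]
        tree = build_tree(X, crisp_masses(y), ForestParams(), np.random.default_rng(1))
        batch = route_batch(tree, X)
        single = [tree_route(tree, xi).leaf_id for xi in X]
        assert batch.tolist() == single


class TestForest:
    def test_single_tree_no_bootstrap_equals_build_tree(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([1] * 10 + [-1] * 10)
        params = ForestParams(W=1, bootstrap=False, seed=3)
        forest = fit_forest(X, y, params)
        tree = build_tree(
            X, crisp_masses(y), params, np.random.default_rng([3, 0]),
            ids=np.arange(20),
        )
        from fkeerf.evidential_forest import tree_to_dict

        assert tree_to_dict(forest.trees[0]) == tree_to_dict(tree)

    def test_separable_training_accuracy(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (30, 3)), rng.normal(6, 0.3, (30, 3))])
        y = np.array([1] * 30 + [-1] * 30)
        forest = fit_forest(X, y, ForestParams(W=30, seed=1))
        assert np.array_equal(predict_label_batch(forest, X), y)

    def test_single_class_rejected(self, rng):
        with pytest.raises(Exception):
            fit_forest(rng.normal(size=(10, 2)), np.ones(10, dtype=int), ForestParams())

    def test_reproducible_from_seed(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.choice([1, -1], size=30)
        y[:2] = [1, -1]
        f1 = fit_forest(X, y, ForestParams(W=5, seed=11))
        f2 = fit_forest(X, y, ForestParams(W=5, seed=11))
        assert forest_to_dict(f1) == forest_to_dict(f2)

    def test_serialization_round_trip(self, rng):
        X = rng.normal(size=(24, 3))
        y = rng.choice([1, -1], size=24)
        y[:2] = [1, -1]
        forest = fit_forest(X, y, ForestParams(W=4, seed=2))
        back = forest_from_dict(forest_to_dict(forest))
        Xq = rng.normal(size=(10, 3))
        assert np.array_equal(
            predict_value_batch(forest, Xq), predict_value_batch(back, Xq)
        )


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(42)
    X = np.vstack([rng.normal(0, 1.0, (15, 4)), rng.normal(2.5, 1.0, (15, 4))])
    y = np.array([1] * 15 + [-1] * 15)
    forest = fit_forest(X, y, ForestParams(W=10, min_leaf_samples=2, seed=8))
    return forest, X, y, rng


class TestKernelPrediction:

    def test_kernel_vector_matches_double_loop(self, trained):
        forest, X, y, rng = trained
        for x in rng.normal(1.0, 1.5, (5, 4)):
            ours = kernel_vector(forest, x)
            brute = np.zeros(len(X))
            for tree in forest.trees:
                leaf = tree_route(tree, x)
                for i, xi in enumerate(X):
                    if tree_route(tree, xi) is leaf:
                        brute[i] += 1.0
            assert np.array_equal(ours, brute / forest.W)

    def test_predict_value_matches_brute_force(self, trained):
        forest, X, y, rng = trained
        for x in rng.normal(1.0, 1.5, (5, 4)):
            K = kernel_vector(forest, x)
            assert predict_value(forest, x) == pytest.approx(
                float((y * K).sum() / K.sum())
            )

    def test_value_bounds_and_kernel_range(self, trained):
        forest, X, y, rng = trained
        Xq = rng.normal(1.0, 2.0, (20, 4))
        K = kernel_matrix(forest, Xq)
        assert np.all((K >= 0) & (K <= 1))
        F = predict_value_batch(forest, Xq)
        assert np.all((F >= -1) & (F <= 1))

    def test_self_kernel_is_one(self, trained):
        forest, X, _, _ = trained
        assert kernel_vector(forest, X[0])[0] == 1.0

    def test_single_leaf_tree_kernel_all_ones(self):
        X = np.arange(8, dtype=float)[:, None]
        y = np.array([1] * 4 + [-1] * 4)
        forest = fit_forest(X, y, ForestParams(W=1, min_leaf_samples=8, seed=0))
        assert np.all(kernel_vector(forest, np.array([3.0])) == 1.0)
        # balanced co-leaf neighbors -> F = 0 -> pinned tie label +1
        assert predict_value(forest, np.array([3.0])) == 0.0
        assert predict_label(forest, np.array([3.0])) == 1

    def test_all_positive_neighbors_give_value_one(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1]])
        y = np.array([1, 1, -1, -1])
        forest = fit_forest(X, y, ForestParams(W=5, min_leaf_samples=1, seed=1))
        assert predict_value(forest, np.array([0.05])) == 1.0


class TestErfPrediction:
    def test_w1_returns_leaf_mass(self, rng):
        X = rng.normal(size=(12, 2))
        y = np.array([1] * 6 + [-1] * 6)
        forest = fit_forest(X, y, ForestParams(W=1, min_leaf_samples=12, seed=0))
        m = predict_mass_erf(forest, X[0])
        assert np.array_equal(m.masses, forest.trees[0].leaf_mass.masses)

    def test_pure_leaf_forest_returns_categorical(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (20, 2)), rng.normal(6, 0.2, (20, 2))])
        y = np.array([1] * 20 + [-1] * 20)
        forest = fit_forest(X, y, ForestParams(W=10, min_leaf_samples=2, seed=4))
        m = predict_mass_erf(forest, np.zeros(2))
        assert m.masses[1] == 1.0  # all mass on {+}

    def test_pignistic_of_output_sums_to_one(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.choice([1, -1], size=30)
        y[:2] = [1, -1]
        forest = fit_forest(X, y, ForestParams(W=5, seed=6))
        m = predict_mass_erf(forest, rng.normal(size=3))
        assert pignistic(m).sum() == pytest.approx(1.0)
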