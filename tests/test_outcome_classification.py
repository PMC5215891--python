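import numpy as np
import pytest

from helpers import cart_oracle, normalize_oracle, tree_structure

from fasworm.outcome_classification import (
    ClassificationError,
    fit_tree,
    implicated_features,
    kfold_cv_error,
    leaf_size_sweep,
    pd_curve_features,
    shuffled_baseline,
    split_endpoints,
)
from fasworm.shape_analysis import PDCurve


# ---------------------------------------------------------------------------
# endpoint split


def test_principal_axis_of_a_line_cloud():
    t = np.linspace(-1, 1, 20)
    pts = np.column_stack([t, t])
    es = split_endpoints(pts)
    assert np.allclose(np.abs(es.principal_axis), 1 / np.sqrt(2), atol=1e-12)
    assert np.linalg.norm(es.principal_axis) == pytest.approx(1.0)


def test_threshold_boundary_is_inclusive_for_upper():
    # construct projections directly: centered cloud along x
    pts = np.column_stack([np.array([-1.0, -0.01, 0.5, 1.0]), np.zeros(4)])
    es = split_endpoints(pts, center=False)
    by_proj = {round(p, 6): lab for p, lab in zip(es.projections, es.labels)}
    assert by_proj[-0.01] == "upper"     # >= -0.01 is upper
    assert by_proj[-1.0] == "lower"


def test_degenerate_cloud_raises():
    with pytest.raises(ClassificationError):
        split_endpoints(np.zeros((5, 2)))


def test_labels_depend_only_on_cloud_geometry_after_refit():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(40, 2)) @ np.diag([3.0, 0.5])
    es = split_endpoints(pts)
    th = 0.7
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    es_rot = split_endpoints(pts @ R.T)
    assert np.array_equal(es.labels, es_rot.labels)


# ---------------------------------------------------------------------------
# CART


def test_tree_matches_exhaustive_oracle_on_random_toys():
    rng = np.random.default_rng(11)
    for trial in range(12):
        n = int(rng.integers(8, 41))
        p = int(rng.integers(1, 4))
        X = np.round(rng.normal(size=(n, p)), 3)
        y = rng.choice(["a", "b"], size=n)
        min_leaf = int(rng.integers(1, 5))
        ours = tree_structure(fit_tree(X, y, min_leaf=min_leaf))
        oracle = normalize_oracle(cart_oracle(X, list(y), min_leaf))
        assert ours == oracle, f"trial {trial}"


def test_perfectly_separable_single_feature_has_zero_training_error():
    X = np.arange(10, dtype=float)[:, None]
    y = np.array(["lo"] * 5 + ["hi"] * 5, dtype=object)
    tree = fit_tree(X, y, min_leaf=1)
    assert np.all(tree.predict(X) == y)


def test_min_leaf_equal_n_gives_root_only_majority():
    X = np.random.default_rng(0).normal(size=(12, 3))
    y = np.array(["a"] * 8 + ["b"] * 4, dtype=object)
    tree = fit_tree(X, y, min_leaf=12)
    assert tree.root.is_leaf
    assert np.all(tree.predict(X) == "a")
    assert implicated_features(tree) == []


def test_every_leaf_respects_min_leaf():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(60, 4))
    y = rng.choice(["u", "l"], size=60)
    for min_leaf in (1, 3, 7, 15):
        tree = fit_tree(X, y, min_leaf=min_leaf)
        assert min(tree.leaf_sizes()) >= min_leaf


def test_single_class_labels_give_single_leaf():
    X = np.random.default_rng(1).normal(size=(10, 2))
    tree = fit_tree(X, np.array(["same"] * 10, dtype=object), min_leaf=1)
    assert tree.root.is_leaf and tree.root.label == "same"


def test_accuracy_comparable_to_sklearn_reference():
    # independent implementation cross-check on learnable data
    from sklearn.tree import DecisionTreeClassifier

    rng = np.random.default_rng(21)
    X = rng.normal(size=(300, 4))
    y = np.where(X[:, 1] > 0.3, "u", "l").astype(object)
    flip = rng.random(300) < 0.1
    y[flip] = np.where(y[flip] == "u", "l", "u")
    tree = fit_tree(X[:200], y[:200], min_leaf=10)
    ours = np.mean(tree.predict(X[200:]) == y[200:])
    sk = DecisionTreeClassifier(min_samples_leaf=10, random_state=0).fit(X[:200], y[:200])
    theirs = sk.score(X[200:], y[200:])
    assert abs(ours - theirs) < 0.08


# ---------------------------------------------------------------------------
# cross-validation, sweeps, baselines


def test_cv_error_near_zero_for_separable_data():
    rng = np.random.default_rng(4)
    X = np.concatenate([rng.normal(-3, 0.3, 60), rng.normal(3, 0.3, 60)])[:, None]
    y = np.array(["a"] * 60 + ["b"] * 60, dtype=object)
    assert kfold_cv_error(X, y, min_leaf=5, seed=0) < 0.05


def test_cv_error_near_half_for_independent_labels():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(200, 3))
    y = rng.choice(["a", "b"], size=200)
    err = kfold_cv_error(X, y, min_leaf=5, seed=1)
    assert 0.3 < err < 0.7


def test_leaf_size_sweep_shape_and_majority_limit():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(40, 2))
    y = np.array(["a"] * 25 + ["b"] * 15, dtype=object)
    table = leaf_size_sweep(X, y, sizes=[1, 5, 40], folds=10, seed=0)
    assert len(table) == 3
    # min_leaf = n forces the majority-class predictor: error = minority fraction
    assert table[-1][1] == pytest.approx(15 / 40)
    with pytest.raises(ClassificationError):
        leaf_size_sweep(X, y, sizes=[])


def test_shuffled_baseline_matches_chance_on_balanced_labels():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(100, 3))
    y = np.array(["a", "b"] * 50, dtype=object)
    mean, std = shuffled_baseline(X, y, min_leaf=5, trials=30, seed=3)
    assert abs(mean - 0.5) < 3 * max(std, 0.02)
    assert std > 0


def test_implicated_features_of_single_split():
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array(["a", "a", "b", "b"], dtype=object)
    tree = fit_tree(X, y, min_leaf=1)
    feats = implicated_features(tree, ["only"])
    assert [f for f, _ in feats] == ["only"]


# ---------------------------------------------------------------------------
# PD-curve features


def _curve(mu_star, pd_vals):
    mu = np.linspace(0, mu_star, len(pd_vals))
    z = np.zeros(len(pd_vals))
    return PDCurve(mu, np.array(pd_vals), np.ones(len(pd_vals)), z, z + 1, mu_star=mu_star)


def test_flat_zero_curve_gives_zero_vector_of_grid_length():
    f = pd_curve_features(_curve(2.0, [0.0] * 6), grid_size=25)
    assert f.shape == (25,)
    assert np.allclose(f, 0.0)


def test_features_invariant_to_mu_and_amplitude_rescaling():
    base = [0.0, 0.1, 0.15, 0.4, 0.3, 0.5]
    f1 = pd_curve_features(_curve(1.0, base))
    f2 = pd_curve_features(_curve(7.3, [3.0 * v for v in base]))
    assert np.allclose(f1, f2, atol=1e-10)
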