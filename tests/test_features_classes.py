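"""Pattern construction, features w(1)-w(3), Gini CART induction."""

import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

from corneadyn import (
    DecisionTree,
    FeatureVector,
    Map2D,
    band_components,
    build_pattern,
    classify,
    feature_w1,
    feature_w2,
    feature_w3,
    gini,
    grayscale_opening,
    pattern_error,
    reference_feature_table,
    train_cart,
)
from corneadyn.io_sequences import DimensionError

DT = 231e-6
I = 140


# ---------------------------------------------------------------------------
# pattern and features
# ---------------------------------------------------------------------------


def test_build_pattern_components(rng):
    shape = (64, 40)
    smooth = Map2D(np.tile(np.linspace(0, 5, 40)[None, :], (64, 1)), "cornea")
    zero = Map2D(np.zeros(shape), "eyeball")
    l_v = build_pattern(zero, smooth, se=(5, 5))
    assert np.allclose(l_v.values, grayscale_opening(smooth, (5, 5)).values)

    eyeball = Map2D(rng.normal(size=shape), "eyeball")
    l_v = build_pattern(eyeball, Map2D(np.zeros(shape), "cornea"), se=(5, 5))
    assert np.allclose(l_v.values, eyeball.values[32, :][None, :])


def test_pattern_error_properties(rng):
    a = Map2D(rng.normal(size=(8, 6)), "deformation")
    assert np.array_equal(pattern_error(a, a).values, np.zeros((8, 6)))
    b = Map2D(rng.normal(size=(8, 6)), "pattern")
    scaled = pattern_error(Map2D(3 * a.values, "deformation"), Map2D(3 * b.values, "pattern"))
    assert np.allclose(scaled.values, 3 * pattern_error(a, b).values)
    with pytest.raises(DimensionError):
        pattern_error(a, Map2D(np.zeros((5, 5)), "pattern"))


def test_w1_max_and_offset_invariance(rng):
    assert feature_w1(Map2D(np.zeros((5, 5)), "error")) == 0.0
    vals = rng.normal(size=(20, 30))
    vals[13, 7] = 37.2
    assert feature_w1(Map2D(vals, "error")) == pytest.approx(37.2)
    l_t = Map2D(rng.normal(size=(9, 9)), "deformation")
    l_v = Map2D(rng.normal(size=(9, 9)), "pattern")
    w = feature_w1(pattern_error(l_t, l_v))
    shifted = feature_w1(
        pattern_error(Map2D(l_t.values + 11.0, "deformation"), Map2D(l_v.values + 11.0, "pattern"))
    )
    assert shifted == pytest.approx(w)


def test_w2_window_edges():
    spec = np.zeros(71)
    assert feature_w2(spec, spec) == 0.0
    left = spec.copy()
    left[10] = 28.6
    right = spec.copy()
    right[12] = 5.0
    assert feature_w2(left, right) == pytest.approx(28.6)
    outside = spec.copy()
    outside[5] = 99.0  # below the oscillation window
    assert feature_w2(outside, spec) == 0.0
    with pytest.raises(DimensionError):
        feature_w2(np.zeros(10), np.zeros(10))


def test_w3_durations():
    frames = np.arange(I)
    t = frames * DT
    boxcar = ((frames >= 40) & (frames <= 69)).astype(float)
    _, cii, _ = band_components(np.sin(2 * np.pi * 300 * t) * boxcar, DT)
    assert feature_w3(cii, np.zeros(I)) == pytest.approx(30.0, abs=1.0)

    tone = np.cos(2 * np.pi * (10 / (I * DT)) * t)  # constant amplitude, crest at frame 0
    _, cii, _ = band_components(tone, DT)
    assert feature_w3(cii, cii) == I

    spike = np.zeros(I)
    spike[77] = 1.0
    assert feature_w3(spike, np.zeros(I)) == 1.0
    assert feature_w3(np.zeros(I), np.zeros(I)) == 0.0


def test_w3_uses_both_sides():
    left = np.zeros(I)
    left[30:40] = 1.0
    right = np.zeros(I)
    right[60:70] = 1.0
    assert feature_w3(left, right) == pytest.approx(40.0)  # 30..69 inclusive


def test_feature_vector_units():
    fv = FeatureVector(10.0, 5.0, 30.0)
    assert fv.w3_ms(DT) == pytest.approx(30 * DT * 1e3)
    with pytest.raises(ValueError):
        FeatureVector(1.0, -0.1, 2.0)


# ---------------------------------------------------------------------------
# CART
# ---------------------------------------------------------------------------


def test_gini_hand_values():
    assert gini(np.array([1, 2])) == pytest.approx(0.5)
    assert gini(np.array([1, 1, 1])) == 0.0
    assert gini(np.array([])) == 0.0


def test_reference_table_classification():
    """The published 10-eye table trains to pure leaves and zero errors."""
    table = reference_feature_table()
    tree = train_cart(table, table["class"].to_numpy())
    preds = [classify(tree, row) for row in table[["w1", "w2", "w3"]].to_numpy()]
    assert preds == list(table["class"])
    # pure leaves everywhere: purity 1 in every leaf
    def leaves(node):
        if node.is_leaf:
            yield node
        else:
            yield from leaves(node.left)
            yield from leaves(node.right)

    assert all(leaf.purity == 1.0 for leaf in leaves(tree.root))
    assert classify(tree, FeatureVector(48.4, 20.3, 25.1)) == 4
    assert classify(tree, FeatureVector(20.2, 28.6, 28.6)) == 3


def test_single_class_and_two_point_trees():
    tree = train_cart(np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]), [2, 2])
    assert tree.root.is_leaf and tree.root.label == 2

    tree = train_cart(np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]), [1, 2])
    assert not tree.root.is_leaf
    assert tree.root.feature == 0
    assert tree.root.threshold == pytest.approx(1.0)  # midpoint
    assert tree.n_leaves() == 2


def test_conflicting_duplicates_give_impure_leaf():
    X = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
    tree = train_cart(X, [1, 2])
    assert tree.root.is_leaf
    assert tree.root.purity == 0.5
    assert tree.root.label == 1  # majority tie breaks toward the lowest label


def test_training_points_classified_correctly(rng):
    """Without conflicting duplicates CART reaches zero training error."""
    X = rng.normal(size=(40, 3))
    y = (X[:, 0] > 0).astype(int) + 2 * (X[:, 2] > 0.5).astype(int)
    tree = train_cart(X, y)
    assert [tree.predict(x) for x in X] == list(y)


def test_matches_sklearn_on_separable_data(rng):
    """Independent check: same training behaviour as sklearn's Gini CART."""
    X = rng.uniform(0, 10, size=(30, 3))
    y = 1 + (X[:, 1] > 5).astype(int)
    ours = train_cart(X, y)
    sk = DecisionTreeClassifier(criterion="gini", random_state=0).fit(X, y)
    assert [ours.predict(x) for x in X] == list(sk.predict(X))


def test_tree_json_round_trip(tmp_path, rng):
    table = reference_feature_table()
    tree = train_cart(table, table["class"].to_numpy())
    path = tmp_path / "tree.json"
    tree.to_json(path)
    back = DecisionTree.from_json(path)
    probes = rng.uniform(0, 50, size=(25, 3))
    assert [tree.predict(p) for p in probes] == [back.predict(p) for p in probes]


def test_train_cart_input_validation():
    with pytest.raises(DimensionError):
        train_cart(np.zeros((3, 3)), [1, 2])
    with pytest.raises(ValueError):
        train_cart(np.array([[np.nan, 1.0, 2.0]]), [1])
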