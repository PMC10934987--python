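import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsiclass import (
    ForestModel,
    HSICube,
    TreeModel,
    classify_cube_rf,
    classify_cube_xgb,
    rf_predict,
    rf_votes,
    softmax,
    traverse_tree,
    xgb_margins,
    xgb_predict,
)
from hsiclass.forest_infer import traverse_tree_batch, xgb_score


def leaf_tree(payload):
    return TreeModel(
        feature_idx=[-1], threshold=[0.0], left_child=[-1], right_child=[-1],
        leaf_payload=[payload],
    )


def stump(feature, threshold, left_payload, right_payload):
    return TreeModel(
        feature_idx=[feature, -1, -1],
        threshold=[threshold, 0.0, 0.0],
        left_child=[1, -1, -1],
        right_child=[2, -1, -1],
        leaf_payload=[np.zeros_like(np.atleast_1d(left_payload)),
                      left_payload, right_payload],
    )


def random_rf_tree(rng, n_bands, n_classes, n_internal=4):
    """A random valid tree laid out so children always point forward."""
    n_nodes = 2 * n_internal + 1
    feature = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    threshold = rng.random(n_nodes)
    for node in range(n_internal):
        feature[node] = int(rng.integers(0, n_bands))
        left[node] = int(rng.integers(node + 1, n_nodes))
        right[node] = int(rng.integers(node + 1, n_nodes))
    return TreeModel(
        feature_idx=feature, threshold=threshold, left_child=left,
        right_child=right, leaf_payload=rng.random((n_nodes, n_classes)),
    )


# ---------------------------------------------------------------------------
# traversal
# ---------------------------------------------------------------------------


def test_single_leaf_returns_its_payload():
    np.testing.assert_array_equal(
        traverse_tree(leaf_tree([0.2, 0.8]), np.array([9.9])), [0.2, 0.8]
    )


def test_hand_traced_depth_two_tree():
    # root: band 0 <= 0.5 -> node 1 (band 1 <= 0.3 -> leafA else leafB), else leafC
    tree = TreeModel(
        feature_idx=[0, 1, -1, -1, -1],
        threshold=[0.5, 0.3, 0.0, 0.0, 0.0],
        left_child=[1, 3, -1, -1, -1],
        right_child=[2, 4, -1, -1, -1],
        leaf_payload=[[0.0], [0.0], [3.0], [1.0], [2.0]],
    )
    assert traverse_tree(tree, np.array([0.4, 0.1]))[0] == 1.0  # left, left
    assert traverse_tree(tree, np.array([0.4, 0.9]))[0] == 2.0  # left, right
    assert traverse_tree(tree, np.array([0.9, 0.0]))[0] == 3.0  # right


def test_value_equal_to_threshold_goes_left():
    tree = stump(0, 0.5, np.array([1.0]), np.array([2.0]))
    assert traverse_tree(tree, np.array([0.5]))[0] == 1.0


def test_batch_traversal_equals_scalar(rng):
    for _ in range(10):
        tree = random_rf_tree(rng, n_bands=5, n_classes=3)
        X = rng.random((40, 5))
        batch = traverse_tree_batch(tree, X)
        scalar = np.array([traverse_tree(tree, x) for x in X])
        np.testing.assert_array_equal(batch, scalar)


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------


def test_identical_trees_are_unanimous(rng):
    tree = random_rf_tree(rng, n_bands=4, n_classes=3)
    forest = ForestModel(mode="rf", n_classes=3, trees=[tree] * 7, n_estimators=7)
    x = rng.random(4)
    expected = int(np.argmax(traverse_tree(tree, x)))
    assert rf_predict(forest, x) == expected
    assert rf_votes(forest, x)[expected] == 7


def test_majority_vote_two_against_one():
    t_c1 = leaf_tree([0.1, 0.9, 0.0])
    t_c2 = leaf_tree([0.0, 0.2, 0.8])
    forest = ForestModel(
        mode="rf", n_classes=3, trees=[t_c1, t_c1, t_c2], n_estimators=3
    )
    assert rf_predict(forest, np.zeros(1)) == 1


def test_rf_against_brute_force_tally(rng):
    """50 random trees, 200 random pixels: the engine must agree with an
    independently coded per-tree argmax tally."""
    trees = [random_rf_tree(rng, n_bands=6, n_classes=4) for _ in range(50)]
    forest = ForestModel(mode="rf", n_classes=4, trees=trees, n_estimators=50)
    for x in rng.random((200, 6)):
        tally = [0, 0, 0, 0]
        for tree in trees:
            node = 0
            while tree.feature_idx[node] != -1:
                if x[tree.feature_idx[node]] <= tree.threshold[node]:
                    node = int(tree.left_child[node])
                else:
                    node = int(tree.right_child[node])
            payload = tree.leaf_payload[node]
            tally[int(np.argmax(payload))] += 1
        assert rf_predict(forest, x) == tally.index(max(tally))
        assert rf_votes(forest, x).sum() == 50


def test_tree_order_invariance_rf(rng, small_rf):
    x = rng.random(12)
    shuffled = ForestModel(
        mode="rf",
        n_classes=small_rf.n_classes,
        trees=[small_rf.trees[i] for i in rng.permutation(small_rf.n_trees)],
        n_estimators=small_rf.n_estimators,
    )
    assert rf_predict(small_rf, x) == rf_predict(shuffled, x)


def test_rf_mode_mismatch_raises(small_xgb):
    with pytest.raises(ValueError, match="rf"):
        rf_predict(small_xgb, np.zeros(12))


# ---------------------------------------------------------------------------
# gradient boosting
# ---------------------------------------------------------------------------


def test_zero_leaves_give_zero_margins():
    trees = [leaf_tree([0.0]) for _ in range(6)]
    forest = ForestModel(mode="xgb", n_classes=3, trees=trees, n_estimators=2)
    np.testing.assert_array_equal(xgb_margins(forest, np.zeros(1)), [0.0, 0.0, 0.0])


def test_single_estimator_margins_equal_leaf_values():
    trees = [leaf_tree([0.3]), leaf_tree([-0.4]), leaf_tree([1.1])]
    forest = ForestModel(mode="xgb", n_classes=3, trees=trees, n_estimators=1)
    np.testing.assert_array_equal(xgb_margins(forest, np.zeros(1)), [0.3, -0.4, 1.1])


def test_margins_match_direct_double_loop(rng):
    n_classes, n_estimators, n_bands = 4, 10, 5
    trees = []
    for _ in range(n_estimators * n_classes):
        t = random_rf_tree(rng, n_bands, n_classes=1)
        trees.append(t)
    forest = ForestModel(
        mode="xgb", n_classes=n_classes, trees=trees, n_estimators=n_estimators
    )
    for x in rng.random((50, n_bands)):
        expected = np.zeros(n_classes)
        for e in range(n_estimators):
            for i in range(n_classes):
                expected[i] += traverse_tree(trees[e * n_classes + i], x)[0]
        np.testing.assert_allclose(xgb_margins(forest, x), expected, atol=1e-12)


def test_xgb_mode_mismatch_raises(small_rf):
    with pytest.raises(ValueError, match="xgb"):
        xgb_margins(small_rf, np.zeros(12))


# ---------------------------------------------------------------------------
# soft-max
# ---------------------------------------------------------------------------


def test_softmax_of_equal_margins_is_uniform():
    np.testing.assert_allclose(softmax(np.full(5, 1.7)), np.full(5, 0.2), atol=1e-15)


def test_softmax_closed_form():
    np.testing.assert_allclose(
        softmax(np.array([0.0, np.log(2.0)])), [1 / 3, 2 / 3], rtol=1e-14
    )


@settings(deadline=None, max_examples=100)
@given(
    Z=st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=8),
    shift=st.floats(-100, 100, allow_nan=False),
)
def test_softmax_normalization_and_shift_invariance(Z, shift):
    Z = np.array(Z)
    P = softmax(Z)
    assert abs(P.sum() - 1.0) <= 1e-9
    assert np.all(P > 0.0)
    np.testing.assert_allclose(softmax(Z + shift), P, rtol=1e-9, atol=1e-12)
    top = np.sort(Z)
    if len(top) < 2 or top[-1] - top[-2] > 1e-9:  # monotone only for strict maxima
        assert int(np.argmax(P)) == int(np.argmax(Z))


def test_xgb_score_invariants(small_xgb, rng):
    score = xgb_score(small_xgb, rng.random(12))
    assert abs(score.P.sum() - 1.0) <= 1e-9
    assert np.all(score.P > 0)
    assert int(np.argmax(score.P)) == int(np.argmax(score.Z))


# ---------------------------------------------------------------------------
# cube paths
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("chunk_size", [1, 13, 425])
def test_rf_cube_path_equals_scalar_loop(small_rf, rng, chunk_size):
    cube = HSICube(reflectance=rng.random((5, 6, 12)))
    labels = classify_cube_rf(small_rf, cube, chunk_size=chunk_size)
    expected = [rf_predict(small_rf, x) for x in cube.pixels()]
    np.testing.assert_array_equal(labels.flat(), expected)


@pytest.mark.parametrize("chunk_size", [1, 13, 425])
def test_xgb_cube_path_equals_scalar_loop(small_xgb, rng, chunk_size):
    cube = HSICube(reflectance=rng.random((5, 6, 12)))
    labels = classify_cube_xgb(small_xgb, cube, chunk_size=chunk_size)
    expected = [xgb_predict(small_xgb, x) for x in cube.pixels()]
    np.testing.assert_array_equal(labels.flat(), expected)


def test_noiseless_cube_recovers_ground_truth(small_rf, small_xgb, small_scene):
    cube, truth = small_scene
    for engine, forest in [(classify_cube_rf, small_rf), (classify_cube_xgb, small_xgb)]:
        labels = engine(forest, cube)
        np.testing.assert_array_equal(labels.labels, truth.labels)


def test_cube_band_shortfall_is_rejected(small_rf, rng):
    cube = HSICube(reflectance=rng.random((3, 3, 2)))  # fewer bands than splits use
    with pytest.raises(ValueError, match="band"):
        classify_cube_rf(small_rf, cube)


# ---------------------------------------------------------------------------
# independent library oracles
# ---------------------------------------------------------------------------


def _from_sklearn_tree(sk_tree, n_classes):
    """Convert a fitted CART tree's node arrays to our encoding."""
    feature = np.where(sk_tree.children_left == -1, -1, sk_tree.feature)
    payload = sk_tree.value[:, 0, :]
    return TreeModel(
        feature_idx=feature,
        threshold=sk_tree.threshold,
        left_child=sk_tree.children_left,
        right_child=sk_tree.children_right,
        leaf_payload=payload,
    )


def test_traversal_matches_fitted_reference_forest(rng):
    """Export a fitted random forest's node arrays: our traversal must
    reproduce every individual tree's prediction (the ensembles differ
    by design — hard voting here vs probability averaging there)."""
    ensemble = pytest.importorskip("sklearn.ensemble")
    X = rng.random((150, 6))
    y = (X[:, 0] + X[:, 3] > 1.0).astype(int) + (X[:, 1] > 0.5)
    clf = ensemble.RandomForestClassifier(n_estimators=12, random_state=0).fit(X, y)
    n_classes = len(clf.classes_)
    Xt = rng.random((80, 6))
    for sk_est in clf.estimators_:
        ours = _from_sklearn_tree(sk_est.tree_, n_classes)
        got = np.array([np.argmax(traverse_tree(ours, x)) for x in Xt])
        np.testing.assert_array_equal(got, sk_est.predict(Xt).astype(int))


def _parse_xgb_dump(node, nodes):
    """Flatten one tree of a JSON booster dump into preorder node lists."""
    idx = len(nodes)
    nodes.append(None)
    if "leaf" in node:
        nodes[idx] = (-1, 0.0, -1, -1, float(node["leaf"]))
        return idx
    children = {c["nodeid"]: c for c in node["children"]}
    left = _parse_xgb_dump(children[node["yes"]], nodes)
    right = _parse_xgb_dump(children[node["no"]], nodes)
    feat = int(str(node["split"]).lstrip("f"))
    nodes[idx] = (feat, float(node["split_condition"]), left, right, 0.0)
    return idx


def test_margins_match_fitted_reference_booster(rng):
    """Export a fitted gradient-boosted model (trees interleaved
    class-fastest across boosting rounds) and compare soft-max
    probabilities; the shared intercept cancels in the soft-max."""
    xgboost = pytest.importorskip("xgboost")
    import json

    n_classes = 3
    X = rng.random((200, 5)).astype(np.float32)
    y = (X[:, 0] > 0.5).astype(int) + (X[:, 2] > 0.6)
    clf = xgboost.XGBClassifier(
        n_estimators=5, max_depth=3, base_score=0.5, objective="multi:softprob",
        tree_method="exact", random_state=0,
    ).fit(X, y)
    dumps = clf.get_booster().get_dump(dump_format="json")
    assert len(dumps) == 5 * n_classes
    trees = []
    for text in dumps:
        nodes: list = []
        _parse_xgb_dump(json.loads(text), nodes)
        trees.append(
            TreeModel(
                feature_idx=[n[0] for n in nodes],
                threshold=[n[1] for n in nodes],
                left_child=[n[2] for n in nodes],
                right_child=[n[3] for n in nodes],
                leaf_payload=[[n[4]] for n in nodes],
            )
        )
    forest = ForestModel(mode="xgb", n_classes=n_classes, trees=trees, n_estimators=5)
    Xt = rng.random((100, 5)).astype(np.float32)
    ours = np.array([xgb_score(forest, x).P for x in Xt.astype(np.float64)])
    theirs = clf.predict_proba(Xt)
    np.testing.assert_allclose(ours, theirs, atol=2e-5)
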