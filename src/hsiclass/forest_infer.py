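"""Tree-ensemble inference: random-forest voting and boosted soft-max.

Both ensembles share one traversal primitive: starting at the root,
descend left iff ``x[feature] <= threshold`` else right, until a leaf,
and return that leaf's payload.

* Random forest (``mode="rf"``): every tree emits a class-probability
  array; the tree's vote is the argmax of that array, and the forest
  prediction is the most-voted class (hard voting, not probability
  averaging).  The vote accumulation is an order-independent integer
  tally, so the sequential tally and any concurrent/chunked
  accumulation agree exactly.

* Gradient boosting (``mode="xgb"``): tree ``e * n_classes + i`` adds
  its single leaf value to the class-i margin ``Z[i]``; the class
  probabilities are the soft-max ``P[i] = exp(Z[i]) / sum_j exp(Z[j])``
  and the prediction is the argmax.

Ties in every argmax go to the smallest class index.  Cube paths are
chunked over pixels and identical to the per-pixel loops for every
chunk size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hsi_io import HSICube, LabelMap
from .models import ForestModel, TreeModel

__all__ = [
    "XgbScore",
    "traverse_tree",
    "traverse_tree_batch",
    "rf_predict",
    "rf_votes",
    "xgb_margins",
    "softmax",
    "xgb_score",
    "xgb_predict",
    "classify_cube_rf",
    "classify_cube_xgb",
]

DEFAULT_CHUNK_SIZE = 32


@dataclass
class XgbScore:
    """Per-class boosted margins and their soft-max probabilities."""

    Z: np.ndarray  # (n_classes,) margin sums
    ZE: np.ndarray  # exp-transformed (max-shifted) margins
    P: np.ndarray  # (n_classes,) probabilities summing to 1


def traverse_tree(tree: TreeModel, x: np.ndarray) -> np.ndarray:
    """Walk one pixel from the root to a leaf and return the leaf payload.

    Left iff ``x[feature] <= threshold`` (ties go left).  Terminates in
    at most n_nodes steps on any validated tree because child indices
    are forward-pointing.
    """
    x = np.asarray(x, dtype=np.float64)
    node = 0
    while not tree.is_leaf(node):
        if x[tree.feature_idx[node]] <= tree.threshold[node]:
            node = int(tree.left_child[node])
        else:
            node = int(tree.right_child[node])
    return tree.leaf_payload[node]


def traverse_tree_batch(tree: TreeModel, spectra: np.ndarray) -> np.ndarray:
    """Vectorized traversal of many pixels; equals per-pixel traversal.

    All pixels advance in lock-step from the root; each step resolves
    the comparison at each pixel's current node.  Returns an
    (n_pixels, payload_dim) array of leaf payloads.
    """
    spectra = np.asarray(spectra, dtype=np.float64)
    n = spectra.shape[0]
    node = np.zeros(n, dtype=np.int64)
    active = tree.left_child[node] != -1
    while np.any(active):
        idx = node[active]
        feat = tree.feature_idx[idx]
        go_left = spectra[active, feat] <= tree.threshold[idx]
        node[active] = np.where(go_left, tree.left_child[idx], tree.right_child[idx])
        active = tree.left_child[node] != -1
    return tree.leaf_payload[node]


# ---------------------------------------------------------------------------
# Random forest
# ---------------------------------------------------------------------------


def rf_votes(forest: ForestModel, x: np.ndarray) -> np.ndarray:
    """Per-class vote counts over all trees; counts sum to n_trees."""
    if forest.mode != "rf":
        raise ValueError(f"rf_votes requires an rf forest, got mode={forest.mode!r}")
    votes = np.zeros(forest.n_classes, dtype=np.int64)
    for tree in forest.trees:
        payload = traverse_tree(tree, x)
        votes[int(np.argmax(payload))] += 1
    return votes


def rf_predict(forest: ForestModel, x: np.ndarray) -> int:
    """Most-voted class over all trees (ties to the smallest index)."""
    return int(np.argmax(rf_votes(forest, x)))


# ---------------------------------------------------------------------------
# Gradient boosting
# ---------------------------------------------------------------------------


def xgb_margins(forest: ForestModel, x: np.ndarray) -> np.ndarray:
    """Per-class margin sums Z[i] = sum_e leaf(tree[e * n_classes + i], x)."""
    if forest.mode != "xgb":
        raise ValueError(f"xgb_margins requires an xgb forest, got mode={forest.mode!r}")
    Z = np.zeros(forest.n_classes)
    for e in range(forest.n_estimators):
        for i in range(forest.n_classes):
            Z[i] += traverse_tree(forest.trees[e * forest.n_classes + i], x)[0]
    return Z


def softmax(Z: np.ndarray) -> np.ndarray:
    """P[i] = exp(Z[i]) / sum_j exp(Z[j]), computed max-shifted.

    The shift leaves the result mathematically unchanged (the common
    factor cancels) while preventing overflow for large margins.
    """
    Z = np.asarray(Z, dtype=np.float64)
    ZE = np.exp(Z - Z.max(axis=-1, keepdims=True))
    return ZE / ZE.sum(axis=-1, keepdims=True)


def xgb_score(forest: ForestModel, x: np.ndarray) -> XgbScore:
    Z = xgb_margins(forest, x)
    ZE = np.exp(Z - Z.max())
    return XgbScore(Z=Z, ZE=ZE, P=ZE / ZE.sum())


def xgb_predict(forest: ForestModel, x: np.ndarray) -> int:
    """Argmax of the soft-max probabilities (equals argmax of the margins)."""
    return int(np.argmax(xgb_score(forest, x).P))


# ---------------------------------------------------------------------------
# Cube paths
# ---------------------------------------------------------------------------


def _check_cube(forest: ForestModel, cube: HSICube, chunk_size: int, mode: str) -> None:
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    if forest.mode != mode:
        raise ValueError(
            f"forest mode is {forest.mode!r}, this path requires {mode!r}"
        )
    max_feat = max(int(t.feature_idx.max(initial=-1)) for t in forest.trees)
    if max_feat >= cube.n_bands:
        raise ValueError(
            f"forest references band {max_feat} but cube has {cube.n_bands} bands"
        )


def classify_cube_rf(
    forest: ForestModel, cube: HSICube, chunk_size: int = DEFAULT_CHUNK_SIZE
) -> LabelMap:
    """Majority-vote classification of every pixel; chunk-invariant."""
    _check_cube(forest, cube, chunk_size, "rf")
    spectra = cube.pixels()
    labels = np.empty(cube.n_pixels, dtype=np.int64)
    for start in range(0, cube.n_pixels, chunk_size):
        block = spectra[start : start + chunk_size]
        votes = np.zeros((block.shape[0], forest.n_classes), dtype=np.int64)
        for tree in forest.trees:
            winners = np.argmax(traverse_tree_batch(tree, block), axis=1)
            np.add.at(votes, (np.arange(block.shape[0]), winners), 1)
        labels[start : start + chunk_size] = np.argmax(votes, axis=1)
    return LabelMap(
        labels=labels.reshape(cube.height, cube.width), n_classes=forest.n_classes
    )


def classify_cube_xgb(
    forest: ForestModel, cube: HSICube, chunk_size: int = DEFAULT_CHUNK_SIZE
) -> LabelMap:
    """Boosted soft-max classification of every pixel; chunk-invariant.

    Margins are accumulated per class in estimator order, matching the
    scalar double loop exactly (identical addition order per pixel).
    """
    _check_cube(forest, cube, chunk_size, "xgb")
    spectra = cube.pixels()
    labels = np.empty(cube.n_pixels, dtype=np.int64)
    for start in range(0, cube.n_pixels, chunk_size):
        block = spectra[start : start + chunk_size]
        Z = np.zeros((block.shape[0], forest.n_classes))
        for e in range(forest.n_estimators):
            for i in range(forest.n_classes):
                tree = forest.trees[e * forest.n_classes + i]
                Z[:, i] += traverse_tree_batch(tree, block)[:, 0]
        labels[start : start + chunk_size] = np.argmax(softmax(Z), axis=1)
    return LabelMap(
        labels=labels.reshape(cube.height, cube.width), n_classes=forest.n_classes
    )
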