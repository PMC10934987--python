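"""Model containers for the three inference engines, with JSON persistence.

Two model families are supported:

* :class:`SVMModel` -- a trained one-vs-one RBF support-vector machine:
  support vectors ``w_i`` grouped by class, an ``(n_classes - 1) x n_sv``
  dual-coefficient matrix, per-pair intercepts ``b`` and the kernel
  parameter ``gamma``.
* :class:`TreeModel` / :class:`ForestModel` -- decision trees encoded as
  parallel node arrays (feature, threshold, children, leaf payload),
  assembled into either a random forest (``mode="rf"``, each leaf holds
  a class-probability vector) or a gradient-boosted ensemble
  (``mode="xgb"``, each leaf holds one additive margin value, with
  ``n_estimators`` trees per class interleaved class-fastest).

Models are serialized to a single JSON document with a ``model_type``
discriminator; all structural invariants are validated on load.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SVMModel",
    "TreeModel",
    "ForestModel",
    "ModelValidationError",
    "class_pairs",
    "n_class_pairs",
    "validate_tree",
    "save_model",
    "load_model",
]


class ModelValidationError(ValueError):
    """A model violates a structural invariant; the message names the field."""


def n_class_pairs(n_classes: int) -> int:
    """Number of one-vs-one class pairs, n(n-1)/2."""
    return n_classes * (n_classes - 1) // 2


def class_pairs(n_classes: int) -> list[tuple[int, int]]:
    """Ordered class pairs (i, j), i < j, in lexicographic order.

    This is the order produced by the nested voting loops
    ``for i: for j = i+1: ...`` and the order of the pairwise decision
    vector and intercepts everywhere in this package.
    """
    return [(i, j) for i in range(n_classes) for j in range(i + 1, n_classes)]


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------


@dataclass
class SVMModel:
    """One-vs-one RBF SVM parameters.

    ``support_vectors`` rows are grouped by class in class-ascending
    order; ``sv_class_counts[c]`` gives the number of rows belonging to
    class ``c``.  ``dual_coefs`` follows the standard grouped one-vs-one
    layout: for the pair (i, j) with i < j, the decision value sums
    ``dual_coefs[j - 1, s]`` over support vectors ``s`` of class i and
    ``dual_coefs[i, s]`` over support vectors of class j; support
    vectors of other classes contribute nothing to that pair.
    """

    gamma: float
    n_classes: int
    support_vectors: np.ndarray  # (n_sv, n_bands)
    sv_class_counts: np.ndarray  # (n_classes,)
    dual_coefs: np.ndarray  # (n_classes - 1, n_sv)
    intercepts: np.ndarray  # (n_pairs,)

    def __post_init__(self) -> None:
        self.support_vectors = np.asarray(self.support_vectors, dtype=np.float64)
        self.sv_class_counts = np.asarray(self.sv_class_counts, dtype=np.int64)
        self.dual_coefs = np.asarray(self.dual_coefs, dtype=np.float64)
        self.intercepts = np.asarray(self.intercepts, dtype=np.float64)
        self.validate()

    @property
    def n_sv(self) -> int:
        return self.support_vectors.shape[0]

    @property
    def n_bands(self) -> int:
        return self.support_vectors.shape[1]

    @property
    def n_pairs(self) -> int:
        return n_class_pairs(self.n_classes)

    def sv_class_slices(self) -> list[slice]:
        """Row slice of ``support_vectors`` for each class."""
        bounds = np.concatenate(([0], np.cumsum(self.sv_class_counts)))
        return [slice(int(bounds[c]), int(bounds[c + 1])) for c in range(self.n_classes)]

    def validate(self) -> None:
        if not self.gamma > 0:
            raise ModelValidationError(f"gamma must be > 0, got {self.gamma}")
        if self.n_classes < 2:
            raise ModelValidationError("n_classes must be >= 2")
        if self.support_vectors.ndim != 2:
            raise ModelValidationError("support_vectors must be 2-D (n_sv, n_bands)")
        if self.sv_class_counts.shape != (self.n_classes,):
            raise ModelValidationError(
                f"sv_class_counts must have length n_classes={self.n_classes}"
            )
        if np.any(self.sv_class_counts < 1):
            raise ModelValidationError("sv_class_counts entries must all be >= 1")
        if int(self.sv_class_counts.sum()) != self.n_sv:
            raise ModelValidationError(
                f"sv_class_counts sums to {int(self.sv_class_counts.sum())} "
                f"but support_vectors has {self.n_sv} rows"
            )
        if self.dual_coefs.shape != (self.n_classes - 1, self.n_sv):
            raise ModelValidationError(
                f"dual_coefs must be (n_classes - 1, n_sv) = "
                f"({self.n_classes - 1}, {self.n_sv}), got {self.dual_coefs.shape}"
            )
        if self.intercepts.shape != (self.n_pairs,):
            raise ModelValidationError(
                f"intercepts must have length n_pairs={self.n_pairs}, "
                f"got {self.intercepts.shape}"
            )
        if not np.all(np.isfinite(self.support_vectors)):
            raise ModelValidationError("support_vectors contains non-finite values")
        if not np.all(np.isfinite(self.dual_coefs)):
            raise ModelValidationError("dual_coefs contains non-finite values")
        if not np.all(np.isfinite(self.intercepts)):
            raise ModelValidationError("intercepts contains non-finite values")


# ---------------------------------------------------------------------------
# Trees and forests
# ---------------------------------------------------------------------------


@dataclass
class TreeModel:
    """A decision tree as parallel node arrays.

    Node 0 is the root.  A node is a leaf iff ``feature_idx`` and both
    child indices are the sentinel -1; internal nodes route left iff
    ``x[feature] <= threshold``.  Child indices always exceed the parent
    index, so any walk from the root strictly advances and terminates.
    ``leaf_payload[node]`` holds the leaf output vector (class
    probabilities for rf trees, a single margin value for xgb trees);
    it is ignored at internal nodes.
    """

    feature_idx: np.ndarray  # (n_nodes,) int, -1 at leaves
    threshold: np.ndarray  # (n_nodes,) float, ignored at leaves
    left_child: np.ndarray  # (n_nodes,) int, -1 at leaves
    right_child: np.ndarray  # (n_nodes,) int, -1 at leaves
    leaf_payload: np.ndarray  # (n_nodes, payload_dim) float

    def __post_init__(self) -> None:
        self.feature_idx = np.asarray(self.feature_idx, dtype=np.int64)
        self.threshold = np.asarray(self.threshold, dtype=np.float64)
        self.left_child = np.asarray(self.left_child, dtype=np.int64)
        self.right_child = np.asarray(self.right_child, dtype=np.int64)
        self.leaf_payload = np.atleast_2d(np.asarray(self.leaf_payload, dtype=np.float64))

    @property
    def n_nodes(self) -> int:
        return self.feature_idx.shape[0]

    @property
    def payload_dim(self) -> int:
        return self.leaf_payload.shape[1]

    def is_leaf(self, node: int) -> bool:
        return self.left_child[node] == -1 and self.right_child[node] == -1


def validate_tree(tree: TreeModel) -> list[str]:
    """Return a list of invariant violations (empty iff the tree is valid).

    Checks array-length agreement, the leaf sentinel consistency
    (feature and both children are -1 together), forward-pointing
    children (acyclicity) and termination of every root-to-leaf path by
    full traversal.
    """
    findings: list[str] = []
    n = tree.n_nodes
    lengths = {
        "feature_idx": tree.feature_idx.shape[0],
        "threshold": tree.threshold.shape[0],
        "left_child": tree.left_child.shape[0],
        "right_child": tree.right_child.shape[0],
        "leaf_payload": tree.leaf_payload.shape[0],
    }
    if len(set(lengths.values())) != 1:
        findings.append(f"node arrays have unequal lengths: {lengths}")
        return findings
    if n == 0:
        findings.append("tree has no nodes (node 0 must be the root)")
        return findings
    for node in range(n):
        left = int(tree.left_child[node])
        right = int(tree.right_child[node])
        feat = int(tree.feature_idx[node])
        if (left == -1) != (right == -1):
            findings.append(
                f"node {node}: children must be both -1 (leaf) or both set, "
                f"got left={left} right={right}"
            )
            continue
        if left == -1:
            if feat != -1:
                findings.append(
                    f"node {node}: leaf (children -1) but feature_idx={feat} != -1"
                )
        else:
            if feat < 0:
                findings.append(
                    f"node {node}: internal node has leaf sentinel feature_idx={feat}"
                )
            for name, child in (("left", left), ("right", right)):
                if not (0 <= child < n):
                    findings.append(
                        f"node {node}: {name}_child={child} out of range [0, {n})"
                    )
                elif child <= node:
                    findings.append(
                        f"node {node}: {name}_child={child} not forward-pointing "
                        f"(cycle risk)"
                    )
    if findings:
        return findings
    # full traversal from the root: both branches of every reachable internal
    # node must reach a leaf within n_nodes steps
    stack = [(0, 0)]
    while stack:
        node, depth = stack.pop()
        if depth > n:
            findings.append(f"path through node {node} exceeds n_nodes={n} steps")
            break
        if not tree.is_leaf(node):
            stack.append((int(tree.left_child[node]), depth + 1))
            stack.append((int(tree.right_child[node]), depth + 1))
    return findings


@dataclass
class ForestModel:
    """An ordered tree ensemble.

    ``mode="rf"``: ``len(trees) == n_estimators`` total trees, each leaf
    payload a length-``n_classes`` probability vector; prediction is a
    hard majority vote over per-tree argmax classes.

    ``mode="xgb"``: ``len(trees) == n_estimators * n_classes``, each
    leaf payload a single margin; the tree at position
    ``e * n_classes + i`` is estimator ``e`` of class ``i`` and the
    per-class margins are the sums over estimators.
    """

    mode: str  # "rf" | "xgb"
    n_classes: int
    trees: list[TreeModel]
    n_estimators: int

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mode not in ("rf", "xgb"):
            raise ModelValidationError(f"mode must be 'rf' or 'xgb', got {self.mode!r}")
        if self.n_classes < 2:
            raise ModelValidationError("n_classes must be >= 2")
        expected = (
            self.n_estimators
            if self.mode == "rf"
            else self.n_estimators * self.n_classes
        )
        if len(self.trees) != expected:
            raise ModelValidationError(
                f"trees: {self.mode} forest with n_estimators={self.n_estimators} "
                f"and n_classes={self.n_classes} must hold {expected} trees, "
                f"got {len(self.trees)}"
            )
        want_dim = self.n_classes if self.mode == "rf" else 1
        for t, tree in enumerate(self.trees):
            if tree.payload_dim != want_dim:
                raise ModelValidationError(
                    f"trees[{t}]: payload_dim must be {want_dim} for "
                    f"{self.mode} mode, got {tree.payload_dim}"
                )
            findings = validate_tree(tree)
            if findings:
                raise ModelValidationError(f"trees[{t}]: {findings[0]}")
            if self.mode == "rf" and np.any(tree.leaf_payload < 0):
                raise ModelValidationError(
                    f"trees[{t}]: leaf_payload must be nonnegative in rf mode"
                )

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def class_tree(self, estimator: int, cls: int) -> TreeModel:
        """Estimator ``e`` of class ``i`` in an xgb forest (index e*n_classes + i)."""
        if self.mode != "xgb":
            raise ModelValidationError("class_tree is defined for xgb mode only")
        return self.trees[estimator * self.n_classes + cls]


# ---------------------------------------------------------------------------
# JSON persistence
# ---------------------------------------------------------------------------


def _tree_to_json(tree: TreeModel) -> dict:
    return {
        "feature_idx": tree.feature_idx.tolist(),
        "threshold": tree.threshold.tolist(),
        "left_child": tree.left_child.tolist(),
        "right_child": tree.right_child.tolist(),
        "leaf_payload": tree.leaf_payload.tolist(),
    }


def _tree_from_json(obj: dict) -> TreeModel:
    return TreeModel(
        feature_idx=np.array(obj["feature_idx"], dtype=np.int64),
        threshold=np.array(obj["threshold"], dtype=np.float64),
        left_child=np.array(obj["left_child"], dtype=np.int64),
        right_child=np.array(obj["right_child"], dtype=np.int64),
        leaf_payload=np.array(obj["leaf_payload"], dtype=np.float64),
    )


def save_model(model: SVMModel | ForestModel, path: str | os.PathLike) -> None:
    """Serialize a model to JSON.  Floats round-trip bit-exactly
    (Python's repr-based JSON float encoding is lossless for binary64)."""
    if isinstance(model, SVMModel):
        doc = {
            "model_type": "svm",
            "gamma": model.gamma,
            "n_classes": model.n_classes,
            "support_vectors": model.support_vectors.tolist(),
            "sv_class_counts": model.sv_class_counts.tolist(),
            "dual_coefs": model.dual_coefs.tolist(),
            "intercepts": model.intercepts.tolist(),
        }
    elif isinstance(model, ForestModel):
        doc = {
            "model_type": "forest",
            "mode": model.mode,
            "n_classes": model.n_classes,
            "n_estimators": model.n_estimators,
            "trees": [_tree_to_json(t) for t in model.trees],
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    with open(os.fspath(path), "w") as fh:
        json.dump(doc, fh)


def load_model(path: str | os.PathLike) -> SVMModel | ForestModel:
    """Load a model JSON file, validating every structural invariant.

    A forest document may omit ``n_estimators``; it is then inferred
    from the tree count (divided by ``n_classes`` in xgb mode, which
    must divide evenly).
    """
    with open(os.fspath(path)) as fh:
        doc = json.load(fh)
    mtype = doc.get("model_type")
    if mtype == "svm":
        return SVMModel(
            gamma=float(doc["gamma"]),
            n_classes=int(doc["n_classes"]),
            support_vectors=np.array(doc["support_vectors"], dtype=np.float64),
            sv_class_counts=np.array(doc["sv_class_counts"], dtype=np.int64),
            dual_coefs=np.array(doc["dual_coefs"], dtype=np.float64),
            intercepts=np.array(doc["intercepts"], dtype=np.float64),
        )
    if mtype == "forest":
        trees = [_tree_from_json(t) for t in doc["trees"]]
        mode = doc["mode"]
        n_classes = int(doc["n_classes"])
        if "n_estimators" in doc:
            n_estimators = int(doc["n_estimators"])
        elif mode == "xgb":
            if len(trees) % n_classes:
                raise ModelValidationError(
                    f"trees: xgb tree count {len(trees)} not divisible by "
                    f"n_classes={n_classes}"
                )
            n_estimators = len(trees) // n_classes
        else:
            n_estimators = len(trees)
        return ForestModel(
            mode=mode, n_classes=n_classes, trees=trees, n_estimators=n_estimators
        )
    raise ModelValidationError(
        f"model_type must be 'svm' or 'forest', got {mtype!r}"
    )
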