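"""Synthetic hyperspectral scenes and analytically solvable models.

The clinical skin-lesion dataset behind this package (snapshot-camera
cubes, 116 preprocessed bands in [0, 1], five lesion/tissue classes) is
private, so every engine is validated against synthetic scenes with a
known ground truth instead:

* class spectral signatures are clipped, smoothed random walks around
  well-separated base reflectance levels — smooth curves in [0, 1]
  shaped like real tissue spectra, with a configurable band-to-band
  smoothness bound and a guaranteed minimum pairwise separation;
* cubes are painted from a per-pixel class layout, each pixel being its
  class mean plus i.i.d. Gaussian noise, clipped back to [0, 1];
* models are constructed (never trained) so the correct label is
  provable: a nearest-centroid SVM (one support vector per class,
  antisymmetric pairwise coefficients, zero intercepts) and forests of
  axis-aligned midpoint splits that classify every noiseless class mean
  correctly by construction.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hsi_io import HSICube, LabelMap
from .models import ForestModel, SVMModel, TreeModel, class_pairs, n_class_pairs

__all__ = [
    "SignatureSet",
    "generate_signatures",
    "quadrant_layout",
    "random_layout",
    "generate_cube",
    "make_centroid_svm",
    "make_separating_forest",
]

DEFAULT_N_CLASSES = 5
DEFAULT_N_BANDS = 116
DEFAULT_CUBE_SIDE = 50
DEFAULT_SMOOTHNESS = 0.05
DEFAULT_MIN_SEPARATION = 0.5
DEFAULT_NOISE_SD = 0.02


@dataclass
class SignatureSet:
    """Per-class mean spectra with separation and smoothness guarantees."""

    n_classes: int
    n_bands: int
    means: np.ndarray  # (n_classes, n_bands) in [0, 1]
    min_separation: float  # smallest pairwise Euclidean distance
    smoothness: float  # max |band-to-band increment| bound


def _pairwise_min_distance(means: np.ndarray) -> float:
    n = means.shape[0]
    if n < 2:
        return float("inf")
    dists = [
        float(np.linalg.norm(means[i] - means[j]))
        for i, j in class_pairs(n)
    ]
    return min(dists)


def generate_signatures(
    n_classes: int = DEFAULT_N_CLASSES,
    n_bands: int = DEFAULT_N_BANDS,
    smoothness: float = DEFAULT_SMOOTHNESS,
    seed: int = 0,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    max_tries: int = 100,
) -> SignatureSet:
    """Draw smooth, well-separated class spectra in [0, 1].

    Each class curve is a mean-centred smoothed random walk (moving
    average over uniform steps, rescaled so every band-to-band increment
    is below ``smoothness``) around a distinct base reflectance level;
    clipping to [0, 1] is 1-Lipschitz and so preserves the smoothness
    bound.  Draws are repeated (bounded) until the smallest pairwise
    Euclidean distance reaches ``min_separation``.
    """
    if n_classes < 1 or n_bands < 1:
        raise ValueError("n_classes and n_bands must be >= 1")
    if smoothness <= 0:
        raise ValueError("smoothness bound must be > 0")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        base = np.full(n_classes, 0.5)
        if n_classes > 1:
            base = rng.permutation(np.linspace(0.15, 0.85, n_classes))
        means = np.empty((n_classes, n_bands))
        for c in range(n_classes):
            if n_bands == 1:
                walk = np.zeros(1)
            else:
                steps = rng.uniform(-1.0, 1.0, n_bands - 1)
                window = min(9, n_bands - 1)
                steps = np.convolve(steps, np.ones(window) / window, mode="same")
                peak = np.abs(steps).max()
                if peak > 0:
                    steps *= 0.8 * smoothness / peak
                walk = np.concatenate(([0.0], np.cumsum(steps)))
                walk -= walk.mean()
            means[c] = np.clip(base[c] + walk, 0.0, 1.0)
        sep = _pairwise_min_distance(means)
        if n_classes == 1 or sep >= min_separation:
            return SignatureSet(
                n_classes=n_classes,
                n_bands=n_bands,
                means=means,
                min_separation=sep,
                smoothness=smoothness,
            )
    raise RuntimeError(
        f"could not reach min_separation={min_separation} in {max_tries} draws "
        f"(n_classes={n_classes}, n_bands={n_bands})"
    )


# ---------------------------------------------------------------------------
# Scene layouts and cubes
# ---------------------------------------------------------------------------


def quadrant_layout(
    height: int = DEFAULT_CUBE_SIDE,
    width: int = DEFAULT_CUBE_SIDE,
    n_classes: int = DEFAULT_N_CLASSES,
) -> np.ndarray:
    """Four quadrants for classes 0-3 plus a central disc for the last class."""
    rows, cols = np.indices((height, width))
    layout = (
        2 * (rows >= height // 2).astype(np.int64) + (cols >= width // 2)
    ) % n_classes
    if n_classes >= 2:
        radius = min(height, width) / 4.0
        center = ((rows - (height - 1) / 2) ** 2 + (cols - (width - 1) / 2) ** 2) <= radius**2
        layout[center] = n_classes - 1
    return layout


def random_layout(height: int, width: int, n_classes: int, seed: int = 0) -> np.ndarray:
    """Uniform i.i.d. class assignment per pixel."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, n_classes, size=(height, width), dtype=np.int64)


def generate_cube(
    signatures: SignatureSet,
    layout: np.ndarray,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> tuple[HSICube, LabelMap]:
    """Paint a labelled cube: class mean + Gaussian noise, clipped to [0, 1]."""
    layout = np.asarray(layout, dtype=np.int64)
    if layout.ndim != 2:
        raise ValueError("layout must be a 2-D per-pixel class array")
    if layout.size and (layout.min() < 0 or layout.max() >= signatures.n_classes):
        raise ValueError(
            f"layout classes must lie in [0, {signatures.n_classes})"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    clean = signatures.means[layout]  # (H, W, n_bands)
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd else clean
    cube = HSICube(reflectance=np.clip(noisy, 0.0, 1.0))
    truth = LabelMap(labels=layout, n_classes=signatures.n_classes)
    return cube, truth


# ---------------------------------------------------------------------------
# Constructed models with provable ground truth
# ---------------------------------------------------------------------------


def make_centroid_svm(signatures: SignatureSet, gamma: float = 10.0) -> SVMModel:
    """A one-vs-one RBF SVM that is exactly a nearest-centroid classifier.

    One support vector per class (the class mean), coefficients +1/-1
    arranged so the pair (i, j) decision value is
    ``K(c_i, x) - K(c_j, x)``, and zero intercepts.  Because the RBF
    kernel is strictly decreasing in Euclidean distance, every pairwise
    contest is won by the nearer centroid, so the vote winner is the
    nearest centroid overall.
    """
    n = signatures.n_classes
    if n < 2:
        raise ValueError("a multiclass SVM needs n_classes >= 2")
    dual_coefs = np.zeros((n - 1, n))
    for i, j in class_pairs(n):
        dual_coefs[j - 1, i] = 1.0  # class-i SV contributes +K(c_i, x) to pair (i, j)
        dual_coefs[i, j] = -1.0  # class-j SV contributes -K(c_j, x)
    return SVMModel(
        gamma=gamma,
        n_classes=n,
        support_vectors=signatures.means.copy(),
        sv_class_counts=np.ones(n, dtype=np.int64),
        dual_coefs=dual_coefs,
        intercepts=np.zeros(n_class_pairs(n)),
    )


def _pair_tests(
    signatures: SignatureSet, min_gap: float = 1e-9
) -> dict[tuple[int, int], list[tuple[int, float, bool]]]:
    """Candidate single-band separating tests for every class pair.

    For the pair (i, j) each candidate is ``(band, threshold,
    i_is_left)`` with the threshold at the midpoint of the class means
    on that band; candidates are the bands whose mean gap is at least
    half the best gap, ordered by gap descending.  Raises if some pair
    has no separating band at all.
    """
    tests: dict[tuple[int, int], list[tuple[int, float, bool]]] = {}
    for i, j in class_pairs(signatures.n_classes):
        gaps = np.abs(signatures.means[i] - signatures.means[j])
        best = float(gaps.max())
        if best <= min_gap:
            raise ValueError(
                f"classes {i} and {j} are inseparable: no band with a mean gap"
            )
        bands = np.where(gaps >= 0.5 * best)[0]
        bands = bands[np.argsort(-gaps[bands], kind="stable")]
        tests[(i, j)] = [
            (
                int(b),
                float((signatures.means[i, b] + signatures.means[j, b]) / 2.0),
                bool(signatures.means[i, b] <= signatures.means[j, b]),
            )
            for b in bands
        ]
    return tests


def _membership_chain(
    cls: int,
    n_classes: int,
    tests: dict[tuple[int, int], list[tuple[int, float, bool]]],
    pick: int,
) -> list[tuple[int, float, bool]]:
    """The (band, threshold, pass_is_left) checks deciding 'is it class cls?'."""
    chain = []
    for other in range(n_classes):
        if other == cls:
            continue
        i, j = (cls, other) if cls < other else (other, cls)
        cand = tests[(i, j)]
        band, thr, i_left = cand[pick % len(cand)]
        pass_left = i_left if cls == i else not i_left
        chain.append((band, thr, pass_left))
    return chain


def _rf_tree(
    signatures: SignatureSet,
    tests: dict[tuple[int, int], list[tuple[int, float, bool]]],
    pick: int,
) -> TreeModel:
    """One decision-list tree: for each class in turn, a chain of pairwise
    midpoint checks; passing the whole chain lands in that class's
    one-hot leaf, any failure falls through to the next class's chain."""
    n = signatures.n_classes
    m = n - 1  # checks per chain; each chain occupies m test nodes + 1 leaf
    n_nodes = (n - 1) * n + 1
    feature = np.full(n_nodes, -1, dtype=np.int64)
    threshold = np.zeros(n_nodes)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    payload = np.zeros((n_nodes, n))
    final_leaf = (n - 1) * n
    payload[final_leaf, n - 1] = 1.0
    for cls in range(n - 1):
        start = cls * n
        leaf = start + m
        payload[leaf, cls] = 1.0
        fail = (cls + 1) * n if cls < n - 2 else final_leaf
        chain = _membership_chain(cls, n, tests, pick)
        for t, (band, thr, pass_left) in enumerate(chain):
            node = start + t
            feature[node] = band
            threshold[node] = thr
            nxt = node + 1 if t < m - 1 else leaf
            left[node], right[node] = (nxt, fail) if pass_left else (fail, nxt)
    return TreeModel(
        feature_idx=feature,
        threshold=threshold,
        left_child=left,
        right_child=right,
        leaf_payload=payload,
    )


def _xgb_tree(
    signatures: SignatureSet,
    tests: dict[tuple[int, int], list[tuple[int, float, bool]]],
    cls: int,
    pick: int,
) -> TreeModel:
    """A one-class indicator tree: leaf margin +1 iff every pairwise
    midpoint check places the pixel on this class's side, else 0."""
    n = signatures.n_classes
    m = n - 1
    n_nodes = m + 2  # m tests, pass leaf, fail leaf
    feature = np.full(n_nodes, -1, dtype=np.int64)
    threshold = np.zeros(n_nodes)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    payload = np.zeros((n_nodes, 1))
    pass_leaf, fail_leaf = m, m + 1
    payload[pass_leaf, 0] = 1.0
    chain = _membership_chain(cls, n, tests, pick)
    for t, (band, thr, pass_left) in enumerate(chain):
        nxt = t + 1 if t < m - 1 else pass_leaf
        feature[t] = band
        threshold[t] = thr
        left[t], right[t] = (nxt, fail_leaf) if pass_left else (fail_leaf, nxt)
    return TreeModel(
        feature_idx=feature,
        threshold=threshold,
        left_child=left,
        right_child=right,
        leaf_payload=payload,
    )


def make_separating_forest(
    signatures: SignatureSet,
    mode: str,
    n_estimators: int | None = None,
    seed: int = 0,
) -> ForestModel:
    """Construct a forest that provably classifies every class mean correctly.

    Trees use axis-aligned midpoint splits on maximally separating
    bands; successive estimators rotate through the candidate bands of
    each class pair (shuffled by ``seed``) so that, under noise, the
    ensemble averages over several independent band checks rather than
    repeating one.  Defaults: 425 trees for rf, 400 estimators per
    class for xgb.
    """
    if signatures.n_classes < 2:
        raise ValueError("a separating forest needs n_classes >= 2")
    if mode not in ("rf", "xgb"):
        raise ValueError(f"mode must be 'rf' or 'xgb', got {mode!r}")
    if n_estimators is None:
        n_estimators = 425 if mode == "rf" else 400
    if n_estimators < 1:
        raise ValueError("n_estimators must be >= 1")
    tests = _pair_tests(signatures)
    rng = np.random.default_rng(seed)
    for pair in tests:
        cand = tests[pair]
        order = rng.permutation(len(cand))
        tests[pair] = [cand[k] for k in order]
    if mode == "rf":
        trees = [_rf_tree(signatures, tests, e) for e in range(n_estimators)]
    else:
        trees = [
            _xgb_tree(signatures, tests, cls, e)
            for e in range(n_estimators)
            for cls in range(signatures.n_classes)
        ]
    forest = ForestModel(
        mode=mode,
        n_classes=signatures.n_classes,
        trees=trees,
        n_estimators=n_estimators,
    )
    # construction guarantee: every noiseless class mean maps to its class
    from .forest_infer import rf_predict, xgb_predict

    predict = rf_predict if mode == "rf" else xgb_predict
    for c in range(signatures.n_classes):
        got = predict(forest, signatures.means[c])
        if got != c:
            raise ValueError(
                f"signatures are not separable by midpoint splits: "
                f"class {c} mean classified as {got}"
            )
    return forest
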