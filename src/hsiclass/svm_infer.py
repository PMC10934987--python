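"""One-vs-one RBF SVM inference.

Per-pixel classification runs in three steps:

1. kernel evaluation against every support vector,
   ``K(w_s, x) = exp(-gamma * ||w_s - x||^2)``;
2. one pairwise decision value per class pair,
   ``d_ij = sum_s coef(i,j,s) * K(w_s, x) + b_ij``;
3. one-vs-one voting: ``d_ij > 0`` is a vote for class i, otherwise
   (including exactly zero) for class j; the predicted class is the
   smallest index attaining the maximum vote count.

Two execution paths are provided: a literal scalar per-pixel path
(:func:`classify_pixel_svm`) and a chunked batched path over whole
cubes (:func:`classify_cube_svm`).  The two are exactly equivalent for
every chunk size; the chunk size is purely a batching granularity
(default 32, one data-parallel warp's worth of pixels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hsi_io import HSICube, LabelMap
from .models import SVMModel, class_pairs

__all__ = [
    "KernelVector",
    "OvoDecision",
    "rbf_kernel",
    "decision_values",
    "ovo_vote",
    "classify_pixel_svm",
    "classify_cube_svm",
    "pair_coefficients",
]

DEFAULT_CHUNK_SIZE = 32


@dataclass
class KernelVector:
    """RBF kernel values K(w_s, x) for one pixel; always in (0, 1]."""

    values: np.ndarray  # (n_sv,)


@dataclass
class OvoDecision:
    """Pairwise decision values, vote tallies, and the winning class."""

    d: np.ndarray  # (n_pairs,)
    votes: np.ndarray  # (n_classes,) nonnegative ints summing to n_pairs
    winner: int


def rbf_kernel(model: SVMModel, x: np.ndarray) -> KernelVector:
    """Evaluate exp(-gamma * ||w_s - x||^2) against every support vector."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (model.n_bands,):
        raise ValueError(
            f"pixel has {x.shape} bands, model expects ({model.n_bands},)"
        )
    diff = model.support_vectors - x
    sq_dist = np.einsum("sb,sb->s", diff, diff)
    return KernelVector(values=np.exp(-model.gamma * sq_dist))


def pair_coefficients(model: SVMModel) -> np.ndarray:
    """Expand the grouped dual-coefficient matrix into per-pair rows.

    Returns an (n_pairs, n_sv) matrix C such that
    ``d = C @ k + intercepts``: row (i, j) carries ``dual_coefs[j-1, s]``
    for support vectors s of class i, ``dual_coefs[i, s]`` for those of
    class j, and zero elsewhere.
    """
    slices = model.sv_class_slices()
    coefs = np.zeros((model.n_pairs, model.n_sv))
    for p, (i, j) in enumerate(class_pairs(model.n_classes)):
        coefs[p, slices[i]] = model.dual_coefs[j - 1, slices[i]]
        coefs[p, slices[j]] = model.dual_coefs[i, slices[j]]
    return coefs


def decision_values(model: SVMModel, k: KernelVector) -> np.ndarray:
    """Pairwise decision values d_ij, length n_pairs, lexicographic pair order."""
    values = np.asarray(k.values, dtype=np.float64)
    if values.shape != (model.n_sv,):
        raise ValueError(
            f"kernel vector has shape {values.shape}, expected ({model.n_sv},)"
        )
    return pair_coefficients(model) @ values + model.intercepts


def ovo_vote(d: np.ndarray, n_classes: int) -> OvoDecision:
    """Tally one-vs-one votes over the pairwise decision vector.

    ``d_ij > 0`` credits class i; ``d_ij <= 0`` (the else branch,
    including exact zero) credits class j.  Votes always sum to
    n_pairs.  Ties on the maximum go to the smallest class index.
    """
    d = np.asarray(d, dtype=np.float64)
    pairs = class_pairs(n_classes)
    if d.shape != (len(pairs),):
        raise ValueError(
            f"decision vector has shape {d.shape}, expected ({len(pairs)},) "
            f"for n_classes={n_classes}"
        )
    votes = np.zeros(n_classes, dtype=np.int64)
    for value, (i, j) in zip(d, pairs):
        if value > 0:
            votes[i] += 1
        else:
            votes[j] += 1
    winner = int(np.argmax(votes))  # argmax returns the first (smallest) index
    return OvoDecision(d=d, votes=votes, winner=winner)


def classify_pixel_svm(model: SVMModel, x: np.ndarray) -> int:
    """Scalar path: kernel, pairwise decisions, one-vs-one vote for one pixel."""
    k = rbf_kernel(model, x)
    d = decision_values(model, k)
    return ovo_vote(d, model.n_classes).winner


def _votes_from_decisions(d: np.ndarray, n_classes: int) -> np.ndarray:
    """Vectorized vote tally for a (n_pixels, n_pairs) decision block."""
    pairs = class_pairs(n_classes)
    votes = np.zeros((d.shape[0], n_classes), dtype=np.int64)
    for p, (i, j) in enumerate(pairs):
        positive = d[:, p] > 0
        votes[positive, i] += 1
        votes[~positive, j] += 1
    return votes


def classify_cube_svm(
    model: SVMModel, cube: HSICube, chunk_size: int = DEFAULT_CHUNK_SIZE
) -> LabelMap:
    """Classify every pixel of a cube; identical to the scalar path.

    Pixels are processed in chunks of ``chunk_size``; within a chunk the
    kernel matrix (chunk x n_sv), the decision block (chunk x n_pairs)
    and the vote tallies are computed with dense linear algebra.  The
    result is invariant to the chunk size by construction.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    if cube.n_bands != model.n_bands:
        raise ValueError(
            f"cube has {cube.n_bands} bands, model expects {model.n_bands}"
        )
    spectra = cube.pixels()
    coefs_t = pair_coefficients(model).T  # (n_sv, n_pairs)
    sv = model.support_vectors
    sv_sq = np.einsum("sb,sb->s", sv, sv)
    labels = np.empty(cube.n_pixels, dtype=np.int64)
    for start in range(0, cube.n_pixels, chunk_size):
        block = spectra[start : start + chunk_size]
        sq_dist = (
            np.einsum("pb,pb->p", block, block)[:, None]
            + sv_sq[None, :]
            - 2.0 * block @ sv.T
        )
        np.maximum(sq_dist, 0.0, out=sq_dist)  # clamp negative rounding residue
        kernel = np.exp(-model.gamma * sq_dist)
        d = kernel @ coefs_t + model.intercepts
        votes = _votes_from_decisions(d, model.n_classes)
        labels[start : start + chunk_size] = np.argmax(votes, axis=1)
    return LabelMap(
        labels=labels.reshape(cube.height, cube.width), n_classes=model.n_classes
    )
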