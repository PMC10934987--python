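"""Data-parallel execution planning as pure, testable computations.

The inference engines were designed for block/thread execution on an
accelerator: per-support-vector work is split into blocks of
``nthreads`` work items with ``ceil(N / nthreads)`` blocks, and the
per-class boosted margins are summed with a sequential-addressing
reduction over a power-of-two padded buffer, halving the active stride
each step.  Here those schedules are expressed as pure functions —
launch geometry, padding and the reduction order are computed and
verifiable, while actual execution stays on the CPU through the
chunked-execution contracts of the classifiers (results invariant to
chunking).  An accelerator backend could consume these plans unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LaunchPlan",
    "ReductionSchedule",
    "launch_blocks",
    "pad_to_pow2",
    "make_reduction_schedule",
    "sequential_reduce",
    "plan_xgb_reduction",
]

DEFAULT_THREADS_PER_BLOCK = 32  # one warp of work items


@dataclass
class LaunchPlan:
    """Block/thread geometry for N work items.

    Invariants: ``n_blocks * threads_per_block >= n_items`` and
    ``(n_blocks - 1) * threads_per_block < n_items`` (no empty trailing
    block).  ``grid_y`` is the optional second grid axis (one block per
    class in the boosted-reduction plan).
    """

    n_items: int
    threads_per_block: int = DEFAULT_THREADS_PER_BLOCK
    grid_y: int = 1
    n_blocks: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_blocks = launch_blocks(self.n_items, self.threads_per_block)
        if self.grid_y < 1:
            raise ValueError("grid_y must be >= 1")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_items": self.n_items,
                "threads_per_block": self.threads_per_block,
                "n_blocks": self.n_blocks,
                "grid_y": self.grid_y,
            }
        )


@dataclass
class ReductionSchedule:
    """Stride schedule of a sequential-addressing tree reduction.

    ``width`` is the smallest power of two >= the input length; the
    strides halve from ``width / 2`` down to 1.  ``buffer`` is the
    zero-padded working vector.
    """

    width: int
    strides: list[int]
    buffer: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "width": self.width,
                "strides": self.strides,
                "buffer_len": int(self.buffer.shape[0]),
            }
        )


def launch_blocks(n_items: int, threads_per_block: int) -> int:
    """Ceiling-division block count, (N + nthreads - 1) // nthreads."""
    if n_items < 1 or threads_per_block < 1:
        raise ValueError(
            f"n_items and threads_per_block must be >= 1, got "
            f"({n_items}, {threads_per_block})"
        )
    return (n_items + threads_per_block - 1) // threads_per_block


def pad_to_pow2(n: int) -> int:
    """Smallest power of two >= n."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return 1 << (n - 1).bit_length()


def make_reduction_schedule(values: np.ndarray) -> ReductionSchedule:
    """Zero-pad to a power of two and list the halving strides."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("reduction input must be a nonempty 1-D vector")
    width = pad_to_pow2(values.size)
    buffer = np.zeros(width)
    buffer[: values.size] = values
    strides = []
    s = width // 2
    while s > 0:
        strides.append(s)
        s //= 2
    return ReductionSchedule(width=width, strides=strides, buffer=buffer)


def sequential_reduce(values: np.ndarray) -> float:
    """Tree-structured pairwise sum in sequential-addressing order.

    For each stride s halving from width/2 to 1, performs
    ``S[t] += S[t + s]`` for all t < s, then returns ``S[0]``.  Zero is
    the padding element, so the result equals the direct sum exactly on
    integer inputs and to ~1e-9 relative on well-conditioned reals.
    """
    schedule = make_reduction_schedule(values)
    S = schedule.buffer
    for s in schedule.strides:
        S[:s] += S[s : 2 * s]
    return float(S[0])


def plan_xgb_reduction(n_estimators: int, n_classes: int) -> LaunchPlan:
    """2-D grid for the per-class boosted-margin reduction.

    One block of ``pad_to_pow2(n_estimators)`` work items on the x-axis
    (the estimators of one class, padded with zeros) and ``n_classes``
    blocks on the y-axis (one per class).
    """
    if n_estimators < 1 or n_classes < 1:
        raise ValueError("n_estimators and n_classes must be >= 1")
    width = pad_to_pow2(n_estimators)
    return LaunchPlan(n_items=width, threads_per_block=width, grid_y=n_classes)
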