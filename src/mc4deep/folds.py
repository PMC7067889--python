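"""Stratified, seeded cross-validation fold assignment.

All out-of-fold machinery in the package (CNN+BLSTM advanced features,
KNN encoding references, stacking probability columns) keys off one
:class:`FoldAssignment`, so a single seed pins the entire protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .samples import DnaSample


@dataclass(frozen=True)
class FoldAssignment:
    """Assignment of every sample (by row) to one of ``k`` folds.

    Stratified: within each class, a seeded shuffle followed by
    round-robin assignment, with the round-robin phase carried across
    classes so overall fold sizes differ by at most one.
    """

    ids: tuple[str, ...]
    assignments: np.ndarray  # shape (n,), values in 0..k-1
    k: int
    seed: int
    _by_id: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "_by_id", {i: int(f) for i, f in zip(self.ids, self.assignments)}
        )

    def fold_of(self, sample_id: str) -> int:
        return self._by_id[sample_id]

    def rows_in_fold(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def rows_not_in_fold(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)


def stratified_folds(
    samples: Sequence[DnaSample] | np.ndarray,
    k: int = 3,
    seed: int = 0,
    ids: Sequence[str] | None = None,
) -> FoldAssignment:
    """Assign samples to ``k`` stratified folds, deterministically per seed.

    ``samples`` may be a list of :class:`DnaSample` or a plain 0/1 label
    array (then ``ids`` may name the rows).  Each class must have at
    least ``k`` members.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if len(samples) and isinstance(samples[0], DnaSample):
        labels = np.asarray([s.label for s in samples], dtype=int)
        ids = tuple(s.id for s in samples)
    else:
        labels = np.asarray(samples, dtype=int)
        ids = tuple(ids) if ids is not None else tuple(str(i) for i in range(len(labels)))
    n = len(labels)
    if len(ids) != n:
        raise ValueError("ids length does not match samples")

    rng = np.random.default_rng(seed)
    assignments = np.full(n, -1, dtype=int)
    offset = 0  # carry the round-robin phase across classes for global balance
    for cls in sorted(np.unique(labels), reverse=True):
        rows = np.flatnonzero(labels == cls)
        if len(rows) < k:
            raise ValueError(
                f"class {cls} has {len(rows)} samples, fewer than k={k}"
            )
        rows = rng.permutation(rows)
        assignments[rows] = (offset + np.arange(len(rows))) % k
        offset += len(rows)
    return FoldAssignment(ids=ids, assignments=assignments, k=k, seed=seed)
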