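"""Shared helpers: stratified fold assignment."""

from __future__ import annotations

import numpy as np


def stratified_fold_indices(
    labels: np.ndarray, k: int, seed: int
) -> list[np.ndarray]:
    """Partition sample indices into k class-stratified folds.

    Within each class the indices are shuffled with a seeded generator and
    dealt round-robin, so per-class fold sizes differ by at most one and
    the assignment is bit-reproducible for a given seed.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise ValueError(f"need k >= 2 folds, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n} samples")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    counter = 0  # continues across classes so overall sizes stay balanced
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        for i in rng.permutation(idx):
            folds[counter % k].append(int(i))
            counter += 1
    return [np.sort(np.array(f, dtype=int)) for f in folds]
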