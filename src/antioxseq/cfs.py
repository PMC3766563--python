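"""Correlation-based Feature Subset selection (CFS) with best-first search.

Features are first discretized by recursive entropy minimization with the
Fayyad-Irani MDL stopping rule; correlations are then measured as the
symmetrical uncertainty SU(x, y) = 2 I(x;y) / (H(x) + H(y)) between
discretized features and between each feature and the class. A candidate
subset S of k features is scored by the CFS merit

    merit(S) = k * r_cf / sqrt(k + k (k-1) * r_ff)

where r_cf is the mean feature-class SU and r_ff the mean pairwise
feature-feature SU within S: relevance is rewarded, redundancy penalized.
Subsets are explored by best-first search with backtracking, terminated
after a fixed number of consecutive non-improving expansions.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._utils import stratified_fold_indices
from .features import FeatureMatrix

_MERIT_EPS = 1e-12


def _entropy_bits(counts: np.ndarray) -> float:
    counts = counts[counts > 0].astype(float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts / total
    return float(-(p * np.log2(p)).sum())


def _class_counts(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(labels, minlength=n_classes)


def _best_split(values: np.ndarray, labels: np.ndarray, n_classes: int):
    """Best binary entropy split of a sorted block; None if unsplittable."""
    n = len(values)
    # candidate cuts sit between adjacent distinct values
    boundaries = np.flatnonzero(values[1:] > values[:-1]) + 1
    if boundaries.size == 0:
        return None
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), labels] = 1.0
    cum = np.cumsum(onehot, axis=0)
    left = cum[boundaries - 1]
    total = cum[-1]
    right = total - left
    n_left = boundaries.astype(float)
    n_right = n - n_left

    def _ent_rows(mat: np.ndarray, sizes: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = mat / sizes[:, None]
            terms = np.where(p > 0, p * np.log2(p), 0.0)
        return -terms.sum(axis=1)

    ent_left = _ent_rows(left, n_left)
    ent_right = _ent_rows(right, n_right)
    weighted = (n_left * ent_left + n_right * ent_right) / n
    j = int(np.argmin(weighted))
    b = boundaries[j]
    return {
        "pos": int(b),
        "cut": (values[b - 1] + values[b]) / 2.0,
        "weighted_entropy": float(weighted[j]),
        "left_counts": left[j],
        "right_counts": right[j],
    }


def _mdl_accepts(
    ent_s: float,
    split: dict,
    n: int,
    k: int,
    k1: int,
    k2: int,
    e1: float,
    e2: float,
) -> bool:
    gain = ent_s - split["weighted_entropy"]
    delta = math.log2(3**k - 2) - (k * ent_s - k1 * e1 - k2 * e2)
    threshold = (math.log2(n - 1) + delta) / n
    return gain > threshold


def _recurse_cuts(
    values: np.ndarray,
    labels: np.ndarray,
    n_classes: int,
    cuts: list[float],
) -> None:
    n = len(values)
    if n < 2:
        return
    counts = _class_counts(labels, n_classes)
    ent_s = _entropy_bits(counts)
    if ent_s == 0.0:
        return
    split = _best_split(values, labels, n_classes)
    if split is None:
        return
    k = int((counts > 0).sum())
    k1 = int((split["left_counts"] > 0).sum())
    k2 = int((split["right_counts"] > 0).sum())
    e1 = _entropy_bits(split["left_counts"])
    e2 = _entropy_bits(split["right_counts"])
    if not _mdl_accepts(ent_s, split, n, k, k1, k2, e1, e2):
        return
    pos = split["pos"]
    cuts.append(split["cut"])
    _recurse_cuts(values[:pos], labels[:pos], n_classes, cuts)
    _recurse_cuts(values[pos:], labels[pos:], n_classes, cuts)


def mdl_discretize(values: np.ndarray, labels: np.ndarray) -> list[float]:
    """Fayyad-Irani supervised discretization: accepted cut points.

    Recursively picks the binary split minimizing the class-entropy of the
    partition and keeps it only when the information gain clears the MDL
    coding cost. Returns the sorted cut values (possibly empty: the feature
    then collapses to a single bin, i.e. carries no class information at
    this sample size). Single-class input yields no cuts.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(values) != len(labels):
        raise ValueError("values and labels must have equal length")
    if len(values) < 2 or len(np.unique(labels)) < 2:
        return []
    order = np.argsort(values, kind="stable")
    cuts: list[float] = []
    _recurse_cuts(values[order], labels[order], int(labels.max()) + 1, cuts)
    return sorted(cuts)


def apply_cuts(values: np.ndarray, cuts: Sequence[float]) -> np.ndarray:
    """Map continuous values to integer bin codes given cut points."""
    return np.searchsorted(np.asarray(cuts, dtype=float), values, side="left")


def symmetrical_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """SU(x, y) = 2 I(x;y) / (H(x) + H(y)), in [0, 1].

    Defined as 0 when either variable has zero entropy (a constant carries
    no information to share).
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny)
    hx = _entropy_bits(np.bincount(xi))
    hy = _entropy_bits(np.bincount(yi))
    if hx == 0.0 or hy == 0.0:
        return 0.0
    hxy = _entropy_bits(joint)
    su = 2.0 * (hx + hy - hxy) / (hx + hy)
    return float(min(1.0, max(0.0, su)))


class CorrelationCache:
    """Discretized features plus lazily computed pairwise correlations."""

    def __init__(self, fm: FeatureMatrix, labels: np.ndarray) -> None:
        self.feature_names = fm.feature_names
        self._index = {n: i for i, n in enumerate(fm.feature_names)}
        labels = np.asarray(labels, dtype=int)
        self._labels = labels
        self._codes = np.empty(
            (fm.n_features, fm.n_samples), dtype=np.int64
        )
        for i in range(fm.n_features):
            col = fm.values[:, i]
            self._codes[i] = apply_cuts(col, mdl_discretize(col, labels))
        self.feature_class_corr = np.array(
            [
                symmetrical_uncertainty(self._codes[i], labels)
                for i in range(fm.n_features)
            ]
        )
        self._pair: dict[tuple[int, int], float] = {}

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def index_of(self, name: str) -> int:
        return self._index[name]

    def class_correlation(self, feature: int | str) -> float:
        i = feature if isinstance(feature, int) else self._index[feature]
        return float(self.feature_class_corr[i])

    def feature_correlation(self, a: int | str, b: int | str) -> float:
        i = a if isinstance(a, int) else self._index[a]
        j = b if isinstance(b, int) else self._index[b]
        if i == j:
            return 1.0
        key = (i, j) if i < j else (j, i)
        if key not in self._pair:
            self._pair[key] = symmetrical_uncertainty(
                self._codes[key[0]], self._codes[key[1]]
            )
        return self._pair[key]


@dataclass(frozen=True)
class FeatureSubset:
    """An ordered set of feature names with its CFS merit."""

    names: tuple[str, ...]
    merit: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if len(set(self.names)) != len(self.names):
            raise ValueError("subset names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names


def cfs_merit(
    subset: Sequence[str] | Sequence[int], cache: CorrelationCache
) -> float:
    """CFS merit k*r_cf / sqrt(k + k(k-1)*r_ff); 0 for the empty subset."""
    idx = [
        f if isinstance(f, (int, np.integer)) else cache.index_of(f)
        for f in subset
    ]
    k = len(idx)
    if k == 0:
        return 0.0
    r_cf = float(np.mean([cache.feature_class_corr[i] for i in idx]))
    if k == 1:
        return r_cf
    pair_sum = 0.0
    for a in range(k):
        for b in range(a + 1, k):
            pair_sum += cache.feature_correlation(idx[a], idx[b])
    r_ff = pair_sum / (k * (k - 1) / 2)
    return k * r_cf / math.sqrt(k + k * (k - 1) * r_ff)


def _merit_incremental(
    members: tuple[int, ...],
    new: int,
    cf_sum: float,
    ff_sum: float,
    cache: CorrelationCache,
) -> tuple[float, float, float]:
    """Merit of members+{new} given running sums for members."""
    cf_sum = cf_sum + cache.feature_class_corr[new]
    for m in members:
        ff_sum = ff_sum + cache.feature_correlation(m, new)
    k = len(members) + 1
    r_cf = cf_sum / k
    if k == 1:
        return r_cf, cf_sum, ff_sum
    r_ff = ff_sum / (k * (k - 1) / 2)
    return k * r_cf / math.sqrt(k + k * (k - 1) * r_ff), cf_sum, ff_sum


def best_first_select(
    fm: FeatureMatrix,
    labels: np.ndarray,
    max_stale: int = 5,
    cache: CorrelationCache | None = None,
) -> FeatureSubset:
    """Best-first search over feature subsets scored by CFS merit.

    Starts from the empty set, expands the best unexpanded subset by every
    single-feature addition, and backtracks to the next best open subset
    when an expansion fails to improve. Terminates after ``max_stale``
    consecutive non-improving expansions (or when the open list empties)
    and returns the best-merit subset seen. Ties in merit prefer the
    smaller subset, then the lexicographically earlier name tuple, so the
    result is deterministic.
    """
    if fm.n_features < 1:
        raise ValueError("need at least one feature")
    if cache is None:
        cache = CorrelationCache(fm, labels)
    n_feat = cache.n_features
    names = cache.feature_names

    def _names_of(members: tuple[int, ...]) -> tuple[str, ...]:
        return tuple(names[i] for i in members)

    best_members: tuple[int, ...] = ()
    best_merit = 0.0
    # heap entries: (-merit, size, name-tuple, members, cf_sum, ff_sum)
    heap: list[tuple] = [(0.0, 0, (), (), 0.0, 0.0)]
    seen: set[tuple[int, ...]] = {()}
    stale = 0
    while heap and stale < max_stale:
        _, _, _, members, cf_sum, ff_sum = heapq.heappop(heap)
        improved = False
        member_set = set(members)
        for f in range(n_feat):
            if f in member_set:
                continue
            child = tuple(sorted(members + (f,)))
            if child in seen:
                continue
            seen.add(child)
            merit, c_cf, c_ff = _merit_incremental(
                members, f, cf_sum, ff_sum, cache
            )
            heapq.heappush(
                heap, (-merit, len(child), _names_of(child), child, c_cf, c_ff)
            )
            if merit > best_merit + _MERIT_EPS:
                best_members, best_merit = child, merit
                improved = True
            elif (
                abs(merit - best_merit) <= _MERIT_EPS
                and best_members
                and (len(child), _names_of(child))
                < (len(best_members), _names_of(best_members))
            ):
                best_members = child
        stale = 0 if improved else stale + 1
    return FeatureSubset(_names_of(best_members), best_merit)


@dataclass(frozen=True)
class CrossvalSelection:
    """Per-fold CFS selections with their frequency-ranked consensus."""

    per_fold: tuple[FeatureSubset, ...]
    frequencies: dict[str, int] = field(compare=False)
    consensus: FeatureSubset = None  # type: ignore[assignment]
    full_data: FeatureSubset = None  # type: ignore[assignment]
    k: int = 0
    seed: int = 0


def crossval_select(
    fm: FeatureMatrix,
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
    max_stale: int = 5,
) -> CrossvalSelection:
    """Run best-first CFS inside each training fold of a stratified k-fold.

    Returns the per-fold subsets, the union frequency of every selected
    name, a consensus subset (names picked in at least half the folds,
    ranked by frequency then canonical column order, merit re-scored on
    the full data) and the subset selected on the full data.
    """
    labels = np.asarray(labels, dtype=int)
    folds = stratified_fold_indices(labels, k, seed)
    all_idx = np.arange(fm.n_samples)
    per_fold: list[FeatureSubset] = []
    for fold in folds:
        train = np.setdiff1d(all_idx, fold)
        if len(np.unique(labels[train])) < 2:
            raise ValueError("a training fold lost one class entirely")
        per_fold.append(
            best_first_select(fm.rows(train), labels[train], max_stale)
        )
    freq: dict[str, int] = {}
    for sub in per_fold:
        for name in sub.names:
            freq[name] = freq.get(name, 0) + 1
    order = {n: i for i, n in enumerate(fm.feature_names)}
    consensus_names = sorted(
        (n for n, c in freq.items() if 2 * c >= k),
        key=lambda n: (-freq[n], order[n]),
    )
    full_cache = CorrelationCache(fm, labels)
    consensus = FeatureSubset(
        tuple(consensus_names), cfs_merit(consensus_names, full_cache)
    )
    full = best_first_select(fm, labels, max_stale, cache=full_cache)
    return CrossvalSelection(
        per_fold=tuple(per_fold),
        frequencies=freq,
        consensus=consensus,
        full_data=full,
        k=k,
        seed=seed,
    )
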