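"""Structural-overlap auditing via ordered tree edit distance.

A secondary structure maps to a rooted ordered tree: a virtual root, one
internal node per base pair (nesting = ancestry), and one leaf per unpaired
nucleotide attached to its innermost enclosing pair.  The distance between two
structures is the ordered tree edit distance (insert / delete / relabel, unit
costs) computed with the Zhang–Shasha dynamic program; the inner loops are
numba-compiled.

The audit statistic for a train/test split is the mean, over test records, of
the minimum distance to any training record.  Splits that leak near-identical
structures between the sides score low; leave-one-family-out splits score
high.  Crossing (pseudoknotted) pairs are removed before tree building by
keeping a maximum-cardinality non-crossing subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .structure_io import RnaRecord

#: Node labels.
LABEL_UNPAIRED, LABEL_PAIR, LABEL_ROOT = 0, 1, 2


@dataclass(frozen=True)
class StructureTree:
    """Postorder encoding of a structure tree.

    ``labels[k]`` is the label of postorder node k; ``lml[k]`` is the postorder
    index of its leftmost leaf descendant.  Child order follows 5'→3' sequence
    order; node count = |pairs| + #unpaired + 1 (the root).
    """

    labels: np.ndarray
    lml: np.ndarray
    record_id: str = ""

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def keyroots(self) -> np.ndarray:
        seen: dict[int, int] = {}
        for k in range(len(self.lml)):
            seen[int(self.lml[k])] = k  # last (highest) node per leftmost leaf
        return np.array(sorted(seen.values()), dtype=np.int64)


def max_noncrossing_pairs(
    pairs: Sequence[tuple[int, int]], length: int
) -> frozenset[tuple[int, int]]:
    """Maximum-cardinality non-crossing subset of a (possibly pseudoknotted)
    pair set, by interval DP.  Deterministic: ties resolved toward pairing the
    leftmost base."""
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if i >= j:
            return 0
        k = partner.get(i)
        skip = best(i + 1, j)
        if k is not None and i < k <= j:
            take = 1 + best(i + 1, k - 1) + best(k + 1, j)
            if take >= skip:
                return take
        return skip

    kept: set[tuple[int, int]] = set()

    def trace(i: int, j: int) -> None:
        while i < j:
            k = partner.get(i)
            if (k is not None and i < k <= j
                    and 1 + best(i + 1, k - 1) + best(k + 1, j) >= best(i + 1, j)):
                kept.add((i, k))
                trace(i + 1, k - 1)
                i = k + 1
            else:
                i += 1

    best(1, length)
    trace(1, length)
    return frozenset(kept)


def structure_to_tree(record: RnaRecord) -> StructureTree:
    """Encode a record's structure as an ordered tree (crossing pairs removed)."""
    pairs = record.pairs
    if _has_crossing(pairs):
        pairs = max_noncrossing_pairs(pairs, len(record))
    open_at = {i: j for i, j in pairs}
    labels: list[int] = []
    lml: list[int] = []

    def emit(i: int, j: int, label: int) -> int:
        """Postorder-emit the node covering interval (i..j); returns its index."""
        first_leaf = None
        pos = i
        while pos <= j:
            if pos in open_at:
                child = emit(pos + 1, open_at[pos] - 1, LABEL_PAIR)
                pos = open_at[pos] + 1
            else:
                labels.append(LABEL_UNPAIRED)
                lml.append(len(labels) - 1)
                child = len(labels) - 1
                pos += 1
            if first_leaf is None:
                first_leaf = lml[child]
        labels.append(label)
        me = len(labels) - 1
        lml.append(me if first_leaf is None else first_leaf)
        return me

    emit(1, len(record), LABEL_ROOT)
    return StructureTree(
        labels=np.array(labels, dtype=np.int64),
        lml=np.array(lml, dtype=np.int64),
        record_id=record.id,
    )


def _has_crossing(pairs) -> bool:
    ps = sorted(pairs)
    for a in range(len(ps)):
        i, j = ps[a]
        for b in range(a + 1, len(ps)):
            k, l = ps[b]
            if k > j:
                break
            if i < k < j < l:
                return True
    return False


@njit(cache=True)
def _zhang_shasha(l1, lab1, kr1, l2, lab2, kr2):  # pragma: no cover - numba
    n1, n2 = l1.shape[0], l2.shape[0]
    td = np.zeros((n1, n2))
    for x in range(kr1.shape[0]):
        i1 = kr1[x]
        li = l1[i1]
        m = i1 - li + 2
        for y in range(kr2.shape[0]):
            j1 = kr2[y]
            lj = l2[j1]
            n = j1 - lj + 2
            fd = np.zeros((m, n))
            for di in range(1, m):
                fd[di, 0] = fd[di - 1, 0] + 1.0
            for dj in range(1, n):
                fd[0, dj] = fd[0, dj - 1] + 1.0
            for di in range(1, m):
                i = li + di - 1
                for dj in range(1, n):
                    j = lj + dj - 1
                    if l1[i] == li and l2[j] == lj:
                        cost = 0.0 if lab1[i] == lab2[j] else 1.0
                        v = fd[di - 1, dj - 1] + cost
                        if fd[di - 1, dj] + 1.0 < v:
                            v = fd[di - 1, dj] + 1.0
                        if fd[di, dj - 1] + 1.0 < v:
                            v = fd[di, dj - 1] + 1.0
                        fd[di, dj] = v
                        td[i, j] = v
                    else:
                        v = fd[l1[i] - li, l2[j] - lj] + td[i, j]
                        if fd[di - 1, dj] + 1.0 < v:
                            v = fd[di - 1, dj] + 1.0
                        if fd[di, dj - 1] + 1.0 < v:
                            v = fd[di, dj - 1] + 1.0
                        fd[di, dj] = v
    return td[n1 - 1, n2 - 1]


def tree_edit_distance(a: StructureTree, b: StructureTree) -> float:
    """Unit-cost ordered tree edit distance (Zhang–Shasha DP); symmetric."""
    if len(a) == 0 or len(b) == 0:
        return float(max(len(a), len(b)))
    return float(
        _zhang_shasha(a.lml, a.labels, a.keyroots, b.lml, b.labels, b.keyroots)
    )


def mean_min_ted(
    test: Sequence[RnaRecord],
    train: Sequence[RnaRecord],
    max_test: int | None = None,
    max_train: int | None = None,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Mean over test records of the minimum tree edit distance to training.

    All-vs-all TED is quadratic in corpus size with sizeable trees, so both
    sides can be subsampled (seeded) via ``max_test`` / ``max_train``; the
    detail table records which records were compared.  Returns
    ``(mean_min_distance, detail)`` with one detail row per audited test
    record: its nearest training record and the distance.
    """
    if not test or not train:
        raise ValueError("both test and train must be nonempty")
    rng = np.random.default_rng(seed)
    test = _subsample(list(test), max_test, rng)
    train = _subsample(list(train), max_train, rng)
    train_trees = [structure_to_tree(r) for r in train]
    rows = []
    for rec in test:
        t = structure_to_tree(rec)
        dists = np.array([tree_edit_distance(t, tt) for tt in train_trees])
        k = int(dists.argmin())
        rows.append({"test_id": rec.id, "nearest_train_id": train[k].id,
                     "distance": float(dists[k])})
    detail = pd.DataFrame(rows)
    return float(detail["distance"].mean()), detail


def _subsample(records: list, cap: int | None, rng) -> list:
    if cap is None or len(records) <= cap:
        return records
    idx = rng.choice(len(records), size=cap, replace=False)
    return [records[i] for i in sorted(idx)]
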