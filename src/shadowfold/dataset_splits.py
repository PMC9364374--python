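"""Cross-validation split construction.

Two benchmarking regimes are supported: plain k-fold cross-validation (the
intra-family regime — test RNAs share families with training RNAs) and
family-fold cross-validation, where one whole RNA family is held out for
testing per fold so no family ever crosses the train/test boundary.  In both
regimes a 10% seeded-random subset of the training records is carved out as a
validation set for early stopping and parameter search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure_io import RnaRecord


@dataclass(frozen=True)
class SplitPlan:
    """Train/validation/test membership for one cross-validation fold."""

    fold_id: int | str
    train_ids: frozenset[str]
    val_ids: frozenset[str]
    test_ids: frozenset[str]
    seed: int = 0
    k: int | None = None

    def __post_init__(self) -> None:
        if (
            self.train_ids & self.val_ids
            or self.train_ids & self.test_ids
            or self.val_ids & self.test_ids
        ):
            raise ValueError(f"fold {self.fold_id}: overlapping membership sets")

    @property
    def all_ids(self) -> frozenset[str]:
        return self.train_ids | self.val_ids | self.test_ids


def kfold_split(
    records: Sequence[RnaRecord], k: int = 5, seed: int = 0
) -> list[SplitPlan]:
    """Unstratified k-fold split by seeded uniform shuffle.

    Every record lands in exactly one fold's test set; test-set sizes differ by
    at most one.  Validation sets are left empty — apply
    :func:`carve_validation` per fold.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if len(records) < k:
        raise ValueError(f"need at least k={k} records, got {len(records)}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    chunks = np.array_split(order, k)
    plans = []
    for fold, chunk in enumerate(chunks):
        test = frozenset(ids[i] for i in chunk)
        train = frozenset(ids) - test
        plans.append(
            SplitPlan(fold_id=fold, train_ids=train, val_ids=frozenset(),
                      test_ids=test, seed=seed, k=k)
        )
    return plans


def familyfold_split(records: Sequence[RnaRecord]) -> list[SplitPlan]:
    """Leave-one-family-out split: one plan per family, that family as test."""
    families: dict[str, set[str]] = {}
    for r in records:
        families.setdefault(r.family, set()).add(r.id)
    if len(families) < 2:
        raise ValueError("family-fold split needs at least two distinct families")
    all_ids = frozenset(r.id for r in records)
    plans = []
    for fam in sorted(families):
        test = frozenset(families[fam])
        plans.append(
            SplitPlan(fold_id=fam, train_ids=all_ids - test,
                      val_ids=frozenset(), test_ids=test)
        )
    return plans


def carve_validation(
    plan: SplitPlan, fraction: float = 0.10, seed: int = 0
) -> SplitPlan:
    """Move a seeded-random fraction of the training set into validation.

    The carve-out size rounds to the nearest integer with a floor of one
    record.  Test membership is untouched.  Note that for family-fold plans
    the validation set deliberately still shares families with training — this
    mirrors the benchmarking protocol whose consequences the pipeline is built
    to expose (early stopping on such a validation set cannot catch
    inter-family overfitting).
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    if plan.val_ids:
        raise ValueError(f"fold {plan.fold_id}: validation set already carved")
    train = sorted(plan.train_ids)
    n_val = max(1, round(fraction * len(train)))
    rng = np.random.default_rng(seed)
    val_idx = rng.choice(len(train), size=n_val, replace=False)
    val = frozenset(train[i] for i in val_idx)
    return SplitPlan(
        fold_id=plan.fold_id,
        train_ids=plan.train_ids - val,
        val_ids=val,
        test_ids=plan.test_ids,
        seed=seed,
        k=plan.k,
    )


# ---------------------------------------------------------------------------
# JSON interchange, so external predictors can consume identical splits
# ---------------------------------------------------------------------------

def save_plans(plans: Sequence[SplitPlan], path: str | Path) -> None:
    payload = [
        {
            "fold": p.fold_id,
            "train": sorted(p.train_ids),
            "val": sorted(p.val_ids),
            "test": sorted(p.test_ids),
            "seed": p.seed,
            "k": p.k,
        }
        for p in plans
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_plans(path: str | Path) -> list[SplitPlan]:
    payload = json.loads(Path(path).read_text())
    return [
        SplitPlan(
            fold_id=d["fold"],
            train_ids=frozenset(d["train"]),
            val_ids=frozenset(d["val"]),
            test_ids=frozenset(d["test"]),
            seed=d.get("seed", 0),
            k=d.get("k"),
        )
        for d in payload
    ]
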