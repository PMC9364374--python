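"""Benchmarking metrics and statistics.

Structure prediction accuracy is scored as PPV / sensitivity / F1 over base
pairs with one-nucleotide slippage tolerance: a pair (i)-(j) also counts as
correct if the other side contains (i±1)-(j) or (i)-(j±1).  Shadow predictions
are scored by ROC AUC over unpadded positions.  Family-level reporting uses
per-family means with an *unweighted* grand mean across families, and paired
two-tailed t-tests compare conditions sequence by sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PairSet = frozenset


@dataclass(frozen=True)
class PairScore:
    """Slippage-tolerant comparison of a predicted and a reference pair set."""

    matched_pred: int
    matched_ref: int
    n_pred: int
    n_ref: int
    ppv: float
    sensitivity: float
    f1: float


@dataclass(frozen=True)
class RocResult:
    """Shadow ROC summary; ``auc`` is NaN when either class is empty."""

    auc: float
    n_paired: int
    n_unpaired: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.auc)


def _has_slippage_match(pair: tuple[int, int], other: frozenset, slip: int) -> bool:
    i, j = pair
    if (i, j) in other:
        return True
    if slip == 0:
        return False
    return any(
        p in other
        for p in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1))
    )


def score_pairs_slippage(
    predicted: Iterable[tuple[int, int]],
    reference: Iterable[tuple[int, int]],
    slippage: int = 1,
    length: int | None = None,
) -> PairScore:
    """Score a predicted pair set against a reference with ±1 slippage.

    Matching is two-sided and independent (no one-to-one assignment): each
    predicted pair checks for any reference pair within displacement, and vice
    versa.  Pseudoknotted reference pairs participate fully.  When both sets
    are empty all three metrics are 1 (a correctly predicted unpaired
    molecule); a one-sided empty set gives 0.
    """
    pred = frozenset(tuple(p) for p in predicted)
    ref = frozenset(tuple(p) for p in reference)
    if length is not None:
        for i, j in pred | ref:
            if not (1 <= i <= length and 1 <= j <= length):
                raise ValueError(f"pair ({i},{j}) out of range for length {length}")
    if not pred and not ref:
        return PairScore(0, 0, 0, 0, 1.0, 1.0, 1.0)
    matched_pred = sum(_has_slippage_match(p, ref, slippage) for p in pred)
    matched_ref = sum(_has_slippage_match(p, pred, slippage) for p in ref)
    ppv = matched_pred / len(pred) if pred else 0.0
    sens = matched_ref / len(ref) if ref else 0.0
    return PairScore(
        matched_pred=matched_pred,
        matched_ref=matched_ref,
        n_pred=len(pred),
        n_ref=len(ref),
        ppv=ppv,
        sensitivity=sens,
        f1=f1_score(ppv, sens),
    )


def f1_score(ppv: float, sensitivity: float) -> float:
    """Harmonic mean of PPV and sensitivity; 0 when both are 0."""
    if ppv + sensitivity == 0:
        return 0.0
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)


def auc_shadow(
    y_hat: Sequence[float], shadow: Sequence[int], true_length: int | None = None
) -> RocResult:
    """Rank-based ROC AUC for distinguishing paired from unpaired positions.

    Equivalent to the normalized pairwise-comparison statistic: the
    probability that a random paired position gets a higher score than a
    random unpaired one, with ties counting one half.  Inputs must already
    exclude padding (or pass ``true_length`` to truncate).  When the shadow is
    all-ones or all-zeros the AUC is undefined and returned as NaN, to be
    excluded from aggregates.
    """
    y_hat = np.asarray(y_hat, dtype=float)
    shadow = np.asarray(shadow)
    if true_length is not None:
        y_hat, shadow = y_hat[:true_length], shadow[:true_length]
    pos = shadow == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        return RocResult(float("nan"), n1, n0)
    ranks = stats.rankdata(y_hat)
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return RocResult(float(auc), n1, n0)


def paired_ttest(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Two-tailed paired t-test on per-sequence score differences.

    Returns ``(t, p)``.  Degenerate cases: all-zero differences give
    ``(0.0, 1.0)`` (no effect, no evidence); zero-variance nonzero differences
    have no finite t and give ``(±inf, 0.0)``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length score vectors of length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return math.copysign(math.inf, d.mean()), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def minmax_normalize(values: Sequence[float]) -> np.ndarray:
    """Scale to [0,1] via (v - min) / (max - min); constant input is an error."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("constant vector cannot be min-max normalized")
    return (v - lo) / (hi - lo)


def aggregate_report(
    per_sequence: pd.DataFrame, metrics: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-family mean metrics plus an unweighted grand "Mean" row.

    ``per_sequence`` needs a ``family`` column plus numeric metric columns
    (e.g. ``f1``, ``auc``).  NaN metric values (undefined AUCs) are excluded
    from the means; the ``n_<metric>`` columns report how many sequences
    contributed to each family mean.  The grand Mean row averages the family
    means without weighting by family size — a large family counts no more
    than a small one.
    """
    if "family" not in per_sequence.columns:
        raise ValueError("per-sequence table needs a 'family' column")
    if metrics is None:
        metrics = [
            c for c in per_sequence.columns
            if c != "family" and pd.api.types.is_numeric_dtype(per_sequence[c])
        ]
    grouped = per_sequence.groupby("family", sort=True)
    rows = grouped[list(metrics)].mean()
    rows.insert(0, "N", grouped.size())
    for m in metrics:
        rows[f"n_{m}"] = grouped[m].count()
    mean_row = rows[list(metrics)].mean()
    mean_row["N"] = rows["N"].sum()
    for m in metrics:
        mean_row[f"n_{m}"] = rows[f"n_{m}"].sum()
    rows.loc["Mean"] = mean_row
    rows["N"] = rows["N"].astype(int)
    return rows
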