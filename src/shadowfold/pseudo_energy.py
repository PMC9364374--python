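"""SHAPE-like profiles and pseudo-free-energy terms.

The shadow predictor outputs per-nucleotide pairing probabilities ŷ(i); SHAPE
chemistry runs the other way (high reactivity ⇒ likely unpaired), so predicted
shadows are converted to SHAPE-like reactivities α̂(i) = 1 − ŷ(i) with no
further normalization.  Reactivities map to pseudo-free-energy change terms

    ΔG′(i) = m · ln(α(i) + 1) + b        [kcal/mol]

which a folding engine adds for each nucleotide participating in a pair.  With
m = 0 the term collapses to the uniform "nudge" ΔΔG′ = b, a family-agnostic
perturbation used to probe how uniformly the thermodynamic model treats
different RNA families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EnergyParams:
    """Slope and intercept of the pseudo-free-energy transform, in kcal/mol.

    Defaults are the conservative published SHAPE values (m = 1.8,
    b = −0.6 kcal/mol) rather than values refit to any training family.
    """

    m: float = 1.8
    b: float = -0.6

    def __post_init__(self) -> None:
        if not (math.isfinite(self.m) and math.isfinite(self.b)):
            raise ValueError("m and b must be finite")


@dataclass(frozen=True)
class ShapeLikeProfile:
    """Per-nucleotide SHAPE-like reactivities (unitless, 1-based)."""

    alpha: np.ndarray
    record_id: str = ""

    def __len__(self) -> int:
        return len(self.alpha)


@dataclass(frozen=True)
class PseudoEnergyProfile:
    """Per-nucleotide ΔG′ terms (kcal/mol, 1-based)."""

    dG: np.ndarray
    record_id: str = ""
    provenance: str = "shadow-derived"  # or "uniform-nudge"

    def __len__(self) -> int:
        return len(self.dG)


def shadow_to_shape(y_hat: Sequence[float], record_id: str = "") -> ShapeLikeProfile:
    """α̂(i) = 1 − ŷ(i): invert pairing probabilities into reactivities."""
    y = np.asarray(y_hat, dtype=float)
    if y.size and (y.min() < 0 or y.max() > 1):
        raise ValueError("shadow probabilities must lie in [0,1]")
    return ShapeLikeProfile(alpha=1.0 - y, record_id=record_id)


def pseudo_energy(
    alpha: ShapeLikeProfile | Sequence[float],
    params: EnergyParams = EnergyParams(),
    record_id: str = "",
) -> PseudoEnergyProfile:
    """ΔG′(i) = m·ln(α(i)+1) + b, elementwise (natural logarithm)."""
    if isinstance(alpha, ShapeLikeProfile):
        record_id = record_id or alpha.record_id
        a = np.asarray(alpha.alpha, dtype=float)
    else:
        a = np.asarray(alpha, dtype=float)
    if a.size and a.min() <= -1:
        raise ValueError("reactivities must exceed -1 for the log transform")
    return PseudoEnergyProfile(
        dG=params.m * np.log1p(a) + params.b, record_id=record_id
    )


def uniform_nudge(length: int, b: float, record_id: str = "") -> PseudoEnergyProfile:
    """The m = 0 special case: a constant ΔΔG′ = b at every nucleotide."""
    return PseudoEnergyProfile(
        dG=np.full(length, float(b)), record_id=record_id,
        provenance="uniform-nudge",
    )


def make_nudge_grid(
    b_min: float = -1.00, b_max: float = 1.00, step: float = 0.02
) -> list[EnergyParams]:
    """Inclusive arithmetic grid of uniform nudges (m = 0).

    Defaults give b ∈ {−1.00, −0.98, …, 0.98, 1.00}: 101 parameter sets, i.e.
    101 folds per sequence.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if b_min > b_max:
        raise ValueError("b_min must not exceed b_max")
    n_steps = (b_max - b_min) / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"step {step} does not divide [{b_min}, {b_max}]")
    n = int(round(n_steps)) + 1
    bs = np.round(np.linspace(b_min, b_max, n), 10)
    return [EnergyParams(m=0.0, b=float(b)) for b in bs]


def default_search_grid() -> tuple[list[float], list[float]]:
    """Default 11×11 (m, b) search grid.

    m ∈ {0.0, 0.3, …, 3.0} and b ∈ {−1.5, −1.3, …, 0.5}: brackets both
    published SHAPE optima (m=1.8, b=−0.6 and m=2.6, b=−0.8).
    """
    grid_m = [round(0.3 * i, 10) for i in range(11)]
    grid_b = [round(-1.5 + 0.2 * i, 10) for i in range(11)]
    return grid_m, grid_b


def grid_search_params(
    val_records,
    model,
    engine,
    grid_m: Sequence[float] | None = None,
    grid_b: Sequence[float] | None = None,
) -> tuple[EnergyParams, pd.DataFrame]:
    """Exhaustive (m, b) search maximizing mean F1 on the validation set.

    ``engine`` is a callable/backend exposing ``fold(record, profile)`` (see
    :mod:`shadowfold.fold_engine`); ``model`` must provide shadow predictions
    via :func:`shadowfold.shadow_cnn.predict_shadow`, or be ``None`` to use
    the true shadows (useful for calibration).  Returns the best parameters
    and the full score surface, one row per grid cell.  Mean F1 is the
    unweighted per-sequence mean.  Ties prefer the weakest intervention:
    smallest |m|, then smallest |b|.
    """
    from .scoring_stats import score_pairs_slippage
    from .shadow_cnn import predict_shadow
    from .structure_io import shadow_of

    if grid_m is None or grid_b is None:
        grid_m, grid_b = default_search_grid()
    if not val_records:
        raise ValueError("empty validation set")

    if model is not None:
        y_hats = predict_shadow(model, val_records)
    else:
        y_hats = [shadow_of(r).astype(float) for r in val_records]
    alphas = [shadow_to_shape(y, record_id=r.id)
              for y, r in zip(y_hats, val_records)]

    rows = []
    for m in grid_m:
        for b in grid_b:
            params = EnergyParams(m=m, b=b)
            f1s = []
            for rec, alpha in zip(val_records, alphas):
                profile = pseudo_energy(alpha, params)
                try:
                    result = engine.fold(rec, profile)
                except Exception as exc:
                    raise RuntimeError(
                        f"folding failed at grid cell (m={m}, b={b}), "
                        f"record {rec.id}"
                    ) from exc
                f1s.append(
                    score_pairs_slippage(result.pairs, rec.pairs).f1)
            rows.append({"m": m, "b": b, "mean_f1": float(np.mean(f1s)),
                         "n": len(f1s)})
    surface = pd.DataFrame(rows)
    best = surface.loc[
        surface.sort_values(
            ["mean_f1", "m", "b"],
            key=lambda s: -s if s.name == "mean_f1" else s.abs(),
            ascending=True,
        ).index[0]
    ]
    return EnergyParams(m=float(best["m"]), b=float(best["b"])), surface


def write_shape_file(
    profile: ShapeLikeProfile | PseudoEnergyProfile, path: str | Path
) -> None:
    """Two-column SHAPE data file: 1-based position, value; −999 = missing."""
    values = profile.alpha if isinstance(profile, ShapeLikeProfile) else profile.dG
    with open(path, "w") as fh:
        for i, v in enumerate(values, start=1):
            if v is None or (isinstance(v, float) and math.isnan(v)):
                fh.write(f"{i} -999\n")
            else:
                fh.write(f"{i} {v:.6f}\n")
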