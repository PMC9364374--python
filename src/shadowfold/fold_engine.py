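"""Minimum-free-energy folding backends.

Two interchangeable backends produce a non-crossing MFE structure from a
sequence plus optional per-nucleotide pseudo-free-energy terms:

* ``external`` — a wrapper around the RNAstructure ``Fold`` executable (the
  full nearest-neighbour thermodynamic model), discovered on PATH or via the
  ``RNASTRUCTURE_FOLD`` environment variable.  Pseudo-energies are passed as a
  SHAPE data file with slope/intercept options.
* ``reference`` — a built-in O(n³) dynamic-programming folder over a
  simplified energy model: each canonical pair (i, j) contributes a base
  stability term (GC/CG −3, AU/UA −2, GU/UG −1, model units) plus, when a
  pseudo-energy profile is given, ΔG′(i) + ΔG′(j) once per formed pair.  It
  keeps the whole pipeline runnable and exactly reproducible with no external
  binary, and carries pseudo-energies at full precision.

The per-pair application of ΔG′ in the reference backend is a documented
simplification: the nearest-neighbour scheme adds ΔG′ per base-pair *stack*,
which has no analogue in a stack-free energy model.  Both backends enforce the
minimum hairpin constraint j − i > 3 and never emit crossing pairs.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .pseudo_energy import EnergyParams, PseudoEnergyProfile, ShapeLikeProfile, write_shape_file
from .structure_io import RnaRecord, read_ct, write_ct

#: Base stability of each canonical pair, model units (negative = stabilizing).
DEFAULT_PAIR_ENERGIES: dict[tuple[str, str], float] = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}

#: Minimum hairpin loop: a pair (i, j) requires j - i > 3.
MIN_HAIRPIN_SPAN = 3

_BASES = "ACGU"
_FORBIDDEN = 1e9


class BackendNotFoundError(RuntimeError):
    """The external folding executable could not be located."""


class ExternalFoldError(RuntimeError):
    """The external folding executable failed."""


@dataclass(frozen=True)
class FoldResult:
    """A predicted non-crossing structure and its total energy."""

    pairs: frozenset[tuple[int, int]]
    score: float
    backend: str


def _energy_matrix(pair_energies: dict[tuple[str, str], float]) -> np.ndarray:
    mat = np.full((4, 4), _FORBIDDEN)
    for (a, b), e in pair_energies.items():
        mat[_BASES.index(a), _BASES.index(b)] = e
    return mat


@njit(cache=True)
def _fill_dp(seq: np.ndarray, pair_e: np.ndarray, dg: np.ndarray) -> np.ndarray:
    """Interval DP: E[i, j] = minimum energy of any non-crossing structure on
    i..j (1-based, inclusive); unpaired bases contribute zero."""
    n = seq.shape[0] - 1  # seq is 1-based with a dummy at 0
    E = np.zeros((n + 2, n + 2))
    for span in range(MIN_HAIRPIN_SPAN + 1, n):
        for i in range(1, n - span + 1):
            j = i + span
            best = E[i + 1, j]  # i unpaired
            for k in range(i + MIN_HAIRPIN_SPAN + 1, j + 1):
                pe = pair_e[seq[i], seq[k]]
                if pe < 1e8:
                    v = pe + dg[i] + dg[k] + E[i + 1, k - 1] + E[k + 1, j]
                    if v < best:
                        best = v
            E[i, j] = best
    return E


def _traceback(
    E: np.ndarray, seq: np.ndarray, pair_e: np.ndarray, dg: np.ndarray, n: int
) -> set[tuple[int, int]]:
    """Deterministic traceback: at ties prefer the pairing branch, and among
    pairing branches the smallest partner index."""
    pairs: set[tuple[int, int]] = set()
    stack = [(1, n)]
    tol = 1e-9
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_HAIRPIN_SPAN:
            continue
        target = E[i, j]
        chosen = False
        for k in range(i + MIN_HAIRPIN_SPAN + 1, j + 1):
            pe = pair_e[seq[i], seq[k]]
            if pe < 1e8:
                v = pe + dg[i] + dg[k] + E[i + 1, k - 1] + E[k + 1, j]
                if abs(v - target) <= tol:
                    pairs.add((i, k))
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    chosen = True
                    break
        if not chosen:
            stack.append((i + 1, j))
    return pairs


def fold_reference(
    record: RnaRecord,
    profile: PseudoEnergyProfile | None = None,
    pair_energies: dict[tuple[str, str], float] | None = None,
) -> FoldResult:
    """Fold with the built-in DP folder; see the module docstring for the model."""
    seq_str = record.sequence.upper().replace("T", "U")
    if any(b not in _BASES for b in seq_str):
        raise ValueError(
            f"{record.id}: reference folder requires an A/C/G/U sequence")
    n = len(seq_str)
    seq = np.zeros(n + 1, dtype=np.int8)
    for i, b in enumerate(seq_str, start=1):
        seq[i] = _BASES.index(b)
    dg = np.zeros(n + 1)
    if profile is not None:
        if len(profile) != n:
            raise ValueError(
                f"{record.id}: profile length {len(profile)} != sequence {n}")
        dg[1:] = np.asarray(profile.dG, dtype=float)
    pair_e = _energy_matrix(pair_energies or DEFAULT_PAIR_ENERGIES)
    E = _fill_dp(seq, pair_e, dg)
    pairs = _traceback(E, seq, pair_e, dg, n)
    return FoldResult(pairs=frozenset(pairs), score=float(E[1, n]),
                      backend="reference")


# ---------------------------------------------------------------------------
# External backend (RNAstructure Fold)
# ---------------------------------------------------------------------------

def find_fold_executable(executable: str | None = None) -> str:
    """Locate RNAstructure's ``Fold`` binary or raise an actionable error."""
    candidates = [executable, os.environ.get("RNASTRUCTURE_FOLD"), "Fold"]
    for cand in candidates:
        if cand:
            path = shutil.which(cand) or (cand if Path(cand).is_file() else None)
            if path:
                return path
    raise BackendNotFoundError(
        "RNAstructure 'Fold' executable not found. Install RNAstructure and "
        "either put Fold on PATH, set the RNASTRUCTURE_FOLD environment "
        "variable, or pass executable=... / --fold-exe. Alternatively use the "
        "built-in backend (backend='reference')."
    )


def fold_external(
    record: RnaRecord,
    shape: ShapeLikeProfile | str | Path | None = None,
    params: EnergyParams = EnergyParams(),
    executable: str | None = None,
) -> FoldResult:
    """Fold with RNAstructure's ``Fold``, optionally SHAPE-directed.

    ``shape`` may be a reactivity profile (written to a SHAPE data file) or a
    path to an existing one; ``params`` supplies the slope and intercept
    passed to Fold.  Only the first (MFE) structure of the output CT is kept.
    The baseline — plain free-energy minimization — is a call with
    ``shape=None``.
    """
    exe = find_fold_executable(executable)
    with tempfile.TemporaryDirectory(prefix="shadowfold_") as tmp:
        tmp = Path(tmp)
        seq_fa = tmp / "input.fasta"
        seq_fa.write_text(f">{record.id or 'seq'}\n{record.sequence}\n")
        out_ct = tmp / "output.ct"
        cmd = [exe, str(seq_fa), str(out_ct), "--MFE"]
        if shape is not None:
            if isinstance(shape, (str, Path)):
                shape_path = Path(shape)
            else:
                shape_path = tmp / "input.shape"
                write_shape_file(shape, shape_path)
            cmd += ["--SHAPE", str(shape_path),
                    "--SHAPEslope", str(params.m),
                    "--SHAPEintercept", str(params.b)]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ExternalFoldError(
                f"Fold exited with {proc.returncode} for {record.id}: "
                f"{proc.stderr.strip()}"
            )
        folded = read_ct(out_ct)
    score = _parse_ct_energy(out_ct_header=folded.id)
    return FoldResult(pairs=folded.pairs, score=score, backend="external")


def _parse_ct_energy(out_ct_header: str) -> float:
    # CT headers look like "ENERGY = -12.3  name"; absent for unstructured output
    tokens = out_ct_header.replace("=", " ").split()
    for i, tok in enumerate(tokens):
        if tok.upper() in ("ENERGY", "DG") and i + 1 < len(tokens):
            try:
                return float(tokens[i + 1])
            except ValueError:
                pass
    return float("nan")


@dataclass
class FoldBackend:
    """Uniform fold interface over the two backends.

    ``fold(record, profile)`` takes an optional :class:`PseudoEnergyProfile`.
    For the external backend the profile is converted back to SHAPE-like
    reactivities only when it was shadow-derived with known (m, b); otherwise
    pass reactivities and params explicitly via ``fold_external``.
    """

    name: str = "reference"
    pair_energies: dict | None = None
    params: EnergyParams = EnergyParams()
    executable: str | None = None

    def fold(
        self, record: RnaRecord, profile: PseudoEnergyProfile | None = None
    ) -> FoldResult:
        if self.name == "reference":
            return fold_reference(record, profile, self.pair_energies)
        if self.name == "external":
            if profile is None:
                return fold_external(record, None, self.params, self.executable)
            # Fold applies dG' = m*ln(a+1)+b itself; recover a from the profile.
            if self.params.m == 0:
                raise ValueError(
                    "external backend cannot carry uniform nudges at full "
                    "precision; use the reference backend for nudge runs")
            alpha = np.expm1((np.asarray(profile.dG) - self.params.b) /
                             self.params.m)
            shape = ShapeLikeProfile(alpha=alpha, record_id=record.id)
            return fold_external(record, shape, self.params, self.executable)
        raise ValueError(f"unknown backend {self.name!r}")
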