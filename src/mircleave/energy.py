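"""Stack-face free-energy profiles along a hairpin stem.

The stem path is cut into structural elements (stacks, bulges, internal
loops). Every element is mapped onto "stack faces" — one face per
nucleotide step of the 5' arm:

* a stack contributes one face carrying its nearest-neighbor stacking dG;
* a bulge or internal loop with ``u5`` unpaired 5'-arm nucleotides
  contributes ``u5 + 1`` faces, each carrying an equal share of the loop's
  total dG (a 3'-arm-only bulge, ``u5 = 0``, yields a single face with the
  full loop dG) — the only split that conserves energy;
* the terminal loop contributes no face.

Faces are indexed by 5'-arm *boundary* indices: the face between 5'-arm
nucleotides ``b-1`` and ``b`` has boundary ``b``. Relative to a cut site at
boundary ``d``, the face at ``d`` is index 0, positive indices run
downstream (away from the loop, ``b = d - k``) and negative upstream —
the axis convention of the species energy-pattern analysis.

Energies are Turner-2004 nearest-neighbor values evaluated by ViennaRNA
with dangling-end contributions disabled (see :mod:`mircleave.structure`),
in kcal/mol at 37 C.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import RNA
from scipy import stats

from .structure import (
    PairTable,
    StemElement,
    StemPath,
    StructureError,
    _model_details,
    decompose_stem,
    render_dotbracket,
)


class EnergyModel:
    """Per-sequence handle to the reference nearest-neighbor evaluator.

    Wraps a ViennaRNA fold compound (dangles disabled). Loop energies are in
    kcal/mol; the evaluator's integer centi-kcal values are divided by 100.
    """

    def __init__(self, sequence: str):
        self.sequence = sequence
        self._fc = RNA.fold_compound(sequence, _model_details())

    def two_way_loop(self, outer: tuple[int, int], inner: tuple[int, int]) -> float:
        """dG of the stack/bulge/internal loop between two closing pairs."""
        (oi, oj), (ii, ij) = outer, inner
        e = self._fc.eval_int_loop(oi + 1, oj + 1, ii + 1, ij + 1)
        return e / 100.0

    def hairpin_loop(self, closing: tuple[int, int]) -> float:
        i, j = closing
        return self._fc.eval_hp_loop(i + 1, j + 1) / 100.0

    def structure_energy(self, dotbracket: str) -> float:
        return float(self._fc.eval_structure(dotbracket))


def element_energy(
    element: StemElement, sequence: str, model: Optional[EnergyModel] = None
) -> float:
    """Free energy (kcal/mol) of one stem element under the Turner model.

    Stacks get the nearest-neighbor stack dG; bulges and internal loops get
    the loop's total dG including initiation, asymmetry and closure terms.
    """
    model = model or EnergyModel(sequence)
    if element.kind == "terminal_loop":
        return model.hairpin_loop(element.outer)
    if element.inner is None:
        raise StructureError("two-way element without an inner pair")
    return model.two_way_loop(element.outer, element.inner)


@dataclass(frozen=True)
class StackFace:
    """One stack face: a 5'-arm boundary with its energy share."""

    boundary: int  # 5'-arm boundary index b (face between b-1 and b)
    energy: float
    source: str  # stack | bulge | internal_loop | padding


@dataclass
class FaceProfile:
    """Ordered faces along the 5' arm, loop-closing pair outward to the base."""

    faces: list[StackFace]
    path: StemPath

    def __post_init__(self) -> None:
        self._by_boundary = {}
        for f in self.faces:
            self._by_boundary.setdefault(f.boundary, f)

    def __len__(self) -> int:
        return len(self.faces)

    def face_at(self, boundary: int) -> Optional[StackFace]:
        return self._by_boundary.get(boundary)


def face_profile(
    path: StemPath,
    sequence: str,
    model: Optional[EnergyModel] = None,
    loop_split: str = "arm5",
) -> FaceProfile:
    """Compute the stack-face profile of a stem path.

    ``loop_split`` chooses the number of faces a bulge/internal loop is split
    into: ``"arm5"`` (default) uses ``u5 + 1`` — faces then map one-to-one
    onto 5'-arm boundaries — while ``"maxarm"`` uses ``max(u5, u3) + 1``
    (pattern-analysis variant; surplus faces share their last boundary).
    """
    if loop_split not in ("arm5", "maxarm"):
        raise ValueError(f"unknown loop_split {loop_split!r}")
    model = model or EnergyModel(sequence)
    elements = decompose_stem(path.pair_table, path)
    faces: list[StackFace] = []
    for elem in elements:
        if elem.kind == "terminal_loop":
            continue
        dg = element_energy(elem, sequence, model)
        n_boundaries = elem.unpaired5 + 1  # boundaries outer[0]+1 .. inner[0]
        if elem.kind == "stack":
            n_faces = 1
        elif loop_split == "arm5":
            n_faces = n_boundaries
        else:
            n_faces = max(elem.unpaired5, elem.unpaired3) + 1
        share = dg / n_faces
        assert elem.inner is not None
        # loop -> base order: boundaries inner[0], inner[0]-1, ..., outer[0]+1
        boundaries = list(range(elem.inner[0], elem.outer[0], -1))
        for k in range(n_faces):
            b = boundaries[k] if k < len(boundaries) else boundaries[-1]
            faces.append(StackFace(boundary=b, energy=share, source=elem.kind))
    return FaceProfile(faces=faces, path=path)


def profile_window(
    profile: FaceProfile,
    origin: int,
    lo: int,
    hi: int,
    pad: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Energies at relative face indices ``lo..hi`` around a cut boundary.

    Index ``k`` maps to 5'-arm boundary ``origin - k`` (positive =
    downstream). Boundaries outside the structured path are filled with
    ``pad`` and flagged in the returned boolean mask.
    """
    if lo > hi:
        raise ValueError(f"window lo {lo} > hi {hi}")
    values = np.empty(hi - lo + 1)
    padded = np.zeros(hi - lo + 1, dtype=bool)
    for idx, k in enumerate(range(lo, hi + 1)):
        face = profile.face_at(origin - k)
        if face is None:
            values[idx] = pad
            padded[idx] = True
        else:
            values[idx] = face.energy
    return values, padded


def profile_to_rows(profile: FaceProfile, origin: int) -> list[tuple[int, float, str]]:
    """(relative_index, energy, source) rows for TSV export/plotting."""
    return [
        (origin - f.boundary, f.energy, f.source)
        for f in sorted(profile.faces, key=lambda f: -f.boundary)
    ]


def average_pattern(
    windows: Iterable[tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Position-wise mean energy over hairpins; padded positions excluded.

    Each item is a ``(values, padded)`` pair from :func:`profile_window` with
    a common window. Positions padded in every hairpin yield NaN.
    """
    windows = list(windows)
    if len(windows) < 2:
        raise ValueError("need at least 2 hairpins to average a pattern")
    vals = np.stack([v for v, _ in windows])
    mask = np.stack([~p for _, p in windows])
    counts = mask.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, (vals * mask).sum(axis=0) / counts, np.nan)
    return means


def pattern_correlation(
    v1: Sequence[float], v2: Sequence[float], lo: int = 0, hi: int = 19
) -> float:
    """Pearson r between two energy patterns over relative indices lo..hi.

    The vectors are indexed so that entry 0 is relative index ``lo`` (as
    produced by :func:`profile_window` / :func:`average_pattern`).
    """
    a = np.asarray(v1, dtype=float)[: hi - lo + 1]
    b = np.asarray(v2, dtype=float)[: hi - lo + 1]
    if len(a) != len(b):
        raise ValueError("patterns have different lengths over the index range")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance pattern: correlation undefined")
    return float(stats.pearsonr(a, b)[0])


def stem_energy_oracle(sequence: str, pt: PairTable, path: StemPath) -> float:
    """Reference total for the conservation check, via eval_structure only.

    Energy attributable to the stem path's two-way loops = E(full structure)
    - E(structure with the path's pairs stripped down to the loop-closing
    pair). An independent route from the per-element evaluation (which goes
    through eval_int_loop), used by tests.
    """
    model = EnergyModel(sequence)
    full = render_dotbracket(pt)
    keep = set(path.chain[:1])
    drop = set(path.chain[1:])
    reduced_pairs = [p for p in pt.pairs() if p not in drop or p in keep]
    reduced = ["."] * len(pt)
    for i, j in reduced_pairs:
        reduced[i], reduced[j] = "(", ")"
    return model.structure_energy(full) - model.structure_energy("".join(reduced))
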