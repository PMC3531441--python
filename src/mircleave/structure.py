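"""Secondary-structure core: folding, pair tables, stem paths, overhang algebra.

The stem-loop of a folded hairpin is walked from the terminal loop outward,
through stacks, bulges and internal loops, down to the first multiloop
junction or the exterior loop (the stem–ssRNA junction). All processing
sites live on the 5' arm of that path; the matching 3'-arm boundaries are
obtained by projecting across the duplex with the 2-nt 3' overhang rule
characteristic of RNase III cleavage:

* Drosha mode — the pre-miRNA starts at the 5'-arm cut ``d``; its 3' end is
  ``partner(d) + 2`` (inclusive), i.e. the 3' strand overhangs by 2 nt.
  :func:`project_cut_3p` returns the *exclusive* end boundary
  ``partner(d) + 3`` so that ``sequence[d:end]`` is the pre-miRNA.
* Dicer mode — the cut ``c`` falls after the 5p mature's 3' end; the 3p
  product starts at ``partner(c - 3)`` (the 5p 3' end overhangs the 3p
  5' end by 2 nt). :func:`project_cut_3p` returns that inclusive start.

Unpaired endpoints are resolved by scanning toward the terminal loop for the
nearest paired position and extrapolating its partner by the scan distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import RNA

from .rna_io import CutSite, normalize_rna

CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

#: ViennaRNA model details: dangling-end / terminal-mismatch exterior
#: contributions are disabled so that the stack-face decomposition of a stem
#: sums exactly to the evaluator's loop-energy total (conservation invariant).
DANGLES = 0


class StructureError(ValueError):
    """Invalid structure string or an operation outside its preconditions."""


def engine_version() -> str:
    return f"ViennaRNA {RNA.__version__}"


def _model_details() -> "RNA.md":
    md = RNA.md()
    md.dangles = DANGLES
    return md


def fold(sequence: str) -> tuple[str, float]:
    """MFE-fold ``sequence`` (Turner nearest-neighbor rules, no dangles).

    Returns ``(dotbracket, mfe_kcal_mol)``; deterministic for a fixed input.
    """
    seq = normalize_rna(sequence)
    if not seq:
        raise StructureError("cannot fold an empty sequence")
    fc = RNA.fold_compound(seq, _model_details())
    db, mfe = fc.mfe()
    return db, round(float(mfe), 2)


class PairTable:
    """Pairing map of one structure: ``partner[i] = j`` if (i, j) paired, else -1."""

    def __init__(self, partner: Sequence[int], sequence: str):
        self.partner = list(partner)
        self.sequence = sequence
        n = len(self.partner)
        if len(sequence) != n:
            raise StructureError("pair table and sequence lengths differ")
        for i, j in enumerate(self.partner):
            if j >= 0 and self.partner[j] != i:
                raise StructureError(f"pair table not an involution at {i}")

    def __len__(self) -> int:
        return len(self.partner)

    def __getitem__(self, i: int) -> int:
        return self.partner[i]

    def is_paired(self, i: int) -> bool:
        return self.partner[i] >= 0

    def pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j in enumerate(self.partner) if j > i]


def parse_dotbracket(sequence: str, dotbracket: str) -> PairTable:
    """Parse a dot-bracket string into a :class:`PairTable`.

    Rejects unbalanced strings, length mismatches and non-canonical pairs
    (only AU, UA, GC, CG, GU, UG are allowed).
    """
    seq = normalize_rna(sequence)
    if len(seq) != len(dotbracket):
        raise StructureError(
            f"sequence length {len(seq)} != structure length {len(dotbracket)}"
        )
    partner = [-1] * len(seq)
    stack: list[int] = []
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            if (seq[j], seq[i]) not in CANONICAL_PAIRS:
                raise StructureError(
                    f"non-canonical pair {seq[j]}{seq[i]} at positions ({j}, {i})"
                )
            partner[j], partner[i] = i, j
        elif ch != ".":
            raise StructureError(f"illegal structure character {ch!r} at {i}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return PairTable(partner, seq)


def render_dotbracket(pt: PairTable) -> str:
    out = ["."] * len(pt)
    for i, j in pt.pairs():
        out[i], out[j] = "(", ")"
    return "".join(out)


@dataclass(frozen=True)
class StemElement:
    """One structural element of a stem path.

    ``outer``/``inner`` are the closing pairs as ``(i5, i3)`` index tuples,
    outer being the base-proximal one (``outer[0] < inner[0]``); the terminal
    loop has ``inner=None``. ``span5`` is the half-open 5'-arm interval owned
    by the element, from its outer pair's 5' nucleotide (inclusive) to its
    inner pair's 5' nucleotide (exclusive) — elements tile the 5' arm.
    """

    kind: str  # stack | bulge | internal_loop | terminal_loop
    outer: tuple[int, int]
    inner: Optional[tuple[int, int]]
    unpaired5: int
    unpaired3: int
    span5: tuple[int, int]

    def __post_init__(self) -> None:
        if self.kind == "stack" and (self.unpaired5 or self.unpaired3):
            raise StructureError("stack element with unpaired nucleotides")
        if self.kind == "bulge" and not (
            (self.unpaired5 == 0) != (self.unpaired3 == 0)
        ):
            raise StructureError("bulge must be unpaired on exactly one arm")
        if self.kind == "internal_loop" and not (
            self.unpaired5 >= 1 and self.unpaired3 >= 1
        ):
            raise StructureError("internal loop must be unpaired on both arms")


@dataclass
class StemPath:
    """The ordered walk of one hairpin's stem, terminal loop outward.

    ``chain`` lists closing pairs from the loop-closing pair to the outermost
    pair of the path (stopping at a multiloop junction or the exterior loop).
    """

    chain: list[tuple[int, int]]
    pair_table: PairTable

    @property
    def loop_junction(self) -> tuple[int, int]:
        return self.chain[0]

    @property
    def base_junction(self) -> tuple[int, int]:
        return self.chain[-1]

    @property
    def arm5_positions(self) -> range:
        """All 5'-arm indices from the outermost pair to the loop-closing pair."""
        return range(self.base_junction[0], self.loop_junction[0] + 1)

    @property
    def n_pairs(self) -> int:
        return len(self.chain)

    def on_arm5(self, pos: int) -> bool:
        return self.base_junction[0] <= pos <= self.loop_junction[0]

    def on_arm3(self, pos: int) -> bool:
        return self.loop_junction[1] <= pos <= self.base_junction[1]


def _hairpin_loops(pt: PairTable) -> list[tuple[int, int]]:
    """Closing pairs (i, j) with every position in (i, j) unpaired."""
    loops = []
    for i, j in pt.pairs():
        if all(pt[k] == -1 for k in range(i + 1, j)):
            loops.append((i, j))
    return loops


def _walk_outward(pt: PairTable, closing: tuple[int, int]) -> list[tuple[int, int]]:
    """Extend from a hairpin-closing pair toward the base through 2-way loops."""
    chain = [closing]
    i, j = closing
    n = len(pt)
    while True:
        k = i - 1
        while k >= 0 and pt[k] == -1:
            k -= 1
        if k < 0:
            break  # exterior loop reached
        l = pt[k]
        if l < k or l <= j:
            break  # sibling helix: multiloop junction
        if any(pt[x] != -1 for x in range(j + 1, l)):
            break  # paired position between the arms: multiloop junction
        chain.append((k, l))
        i, j = k, l
    return chain


def select_stemloop(
    pt: PairTable, anchor: Optional[int | tuple[int, int]] = None
) -> StemPath:
    """Select one hairpin's stem path from a (possibly multi-loop) structure.

    With an ``anchor`` (a position or half-open interval, e.g. an annotated
    mature span or the window midpoint), the hairpin whose stem covers the
    anchor is chosen; otherwise the hairpin with the most base pairs on its
    path wins (ties: the 5'-most).
    """
    loops = _hairpin_loops(pt)
    if not loops:
        raise StructureError("no stem-loop in structure")
    paths = [StemPath(_walk_outward(pt, lp), pt) for lp in loops]
    if anchor is not None:
        if isinstance(anchor, int):
            a, b = anchor, anchor + 1
        else:
            a, b = anchor
        covering = [
            p
            for p in paths
            if p.base_junction[0] <= a and b <= p.base_junction[1] + 1
        ]
        if covering:
            return max(covering, key=lambda p: p.n_pairs)
        # anchor in unstructured context: fall through to the most-paired rule
    return max(paths, key=lambda p: (p.n_pairs, -p.loop_junction[0]))


def decompose_stem(pt: PairTable, path: StemPath) -> list[StemElement]:
    """Decompose a stem path into its elements, terminal loop first.

    The elements tile the 5' arm contiguously (see :class:`StemElement`);
    unpaired counts per element are exact.
    """
    li, lj = path.loop_junction
    elements = [
        StemElement(
            kind="terminal_loop",
            outer=(li, lj),
            inner=None,
            unpaired5=lj - li - 1,
            unpaired3=0,
            span5=(li, li),
        )
    ]
    for (oi, oj), (ii, ij) in zip(path.chain[1:], path.chain[:-1]):
        u5 = ii - oi - 1
        u3 = oj - ij - 1
        if u5 == 0 and u3 == 0:
            kind = "stack"
        elif u5 == 0 or u3 == 0:
            kind = "bulge"
        else:
            kind = "internal_loop"
        elements.append(
            StemElement(
                kind=kind,
                outer=(oi, oj),
                inner=(ii, ij),
                unpaired5=u5,
                unpaired3=u3,
                span5=(oi, ii),
            )
        )
    return elements


def partner_extrapolated(pt: PairTable, path: StemPath, pos: int) -> int:
    """Pairing partner of ``pos``, extrapolated if ``pos`` is unpaired.

    Scans toward the terminal loop for the nearest paired position on the
    same side and corrects its partner by the scan distance, i.e. treats the
    local region as if it were perfectly stacked.
    """
    li, lj = path.loop_junction
    if 0 <= pos < len(pt) and pt[pos] >= 0:
        return pt[pos]
    if pos <= li:  # 5' side: toward the loop is rightward
        scan = range(max(pos + 1, 0), li + 1)
    elif pos >= lj:  # 3' side: toward the loop is leftward
        scan = range(min(pos - 1, len(pt) - 1), lj - 1, -1)
    else:
        raise StructureError(f"position {pos} lies inside the terminal loop")
    for k in scan:
        if pt[k] >= 0:
            return pt[k] + (k - pos)
    raise StructureError(f"no paired position toward the loop from {pos}")


def project_cut_3p(
    pt: PairTable, path: StemPath, cut: CutSite | int, mode: str
) -> int:
    """Project a 5'-arm cut across the duplex with the 2-nt 3' overhang rule.

    ``mode="drosha"``: ``cut`` starts the pre-miRNA; returns the *exclusive*
    3' end boundary ``partner(cut) + 3`` (the last pre-miRNA nucleotide is
    ``partner(cut) + 2``, a 2-nt 3' overhang past the cut's partner).

    ``mode="dicer"``: ``cut`` ends the 5p mature; returns the *inclusive*
    start of the 3p product, ``partner(cut - 3)`` (the 5p 3' end overhangs
    the 3p 5' end by 2 nt).
    """
    d = cut.position if isinstance(cut, CutSite) else cut
    if mode == "drosha":
        if not path.on_arm5(d):
            raise StructureError(f"drosha cut {d} not on the 5' arm of the stem")
        return partner_extrapolated(pt, path, d) + 3
    if mode == "dicer":
        if not path.on_arm5(d - 1):
            raise StructureError(f"dicer cut {d} not on the 5' arm of the stem")
        return partner_extrapolated(pt, path, d - 3)
    raise ValueError(f"unknown projection mode {mode!r}")


@lru_cache(maxsize=4096)
def _folded(sequence: str) -> tuple[str, float]:
    return fold(sequence)


def structure_of(record) -> PairTable:
    """Pair table of a record, from its stored structure or by MFE folding."""
    if record.structure is not None:
        return parse_dotbracket(record.sequence, record.structure)
    db, _ = _folded(record.sequence)
    return parse_dotbracket(record.sequence, db)
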