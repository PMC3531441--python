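"""Dicer stage: pre-miRNA excision/refold, 42 structural features, ranking.

The pre-miRNA defined by the Drosha cut is excised and refolded on its own
(after nuclear export the molecule folds as a single chain, so base pairing
may differ from the pri-miRNA context; ``refold=False`` inherits the
pri-miRNA pairing instead). Candidate Dicer cuts give a 16-25 nt 5p mature
on the stem. Each candidate's "mature region" — the duplex from the
pre-miRNA's non-loop end up to the cut — is summarized as 42 features:

* 36: a 6x6 grid counting internal loops with exactly i unpaired 5'-arm and
  j unpaired 3'-arm nucleotides (i, j in 1..6; larger loops mark the
  pre-miRNA irregular);
* 4: bulge count and total bulged nucleotides, per arm;
* 1: 1-based position of the first paired nucleotide from the 5' end;
* 1: the candidate mature length (nucleotides 5' end to the cut).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import rank
from .drosha import FoldedHairpin, IrregularStructure
from .rna_io import CutSite, HairpinRecord
from .structure import (
    PairTable,
    StemPath,
    StructureError,
    decompose_stem,
    fold,
    parse_dotbracket,
    partner_extrapolated,
    project_cut_3p,
    select_stemloop,
)

MATURE_MIN, MATURE_MAX = 16, 25
PREMIR_MIN, PREMIR_MAX = 50, 80
MAX_LOOP_SIDE = 6  # internal loops with a longer side are irregular

FEATURE_NAMES = (
    [f"iloop_{i}x{j}" for i in range(1, 7) for j in range(1, 7)]
    + ["bulge5_count", "bulge5_nt", "bulge3_count", "bulge3_nt"]
    + ["first_paired_pos", "mature_len"]
)

LENGTH_ONLY_MASK = [len(FEATURE_NAMES) - 1]


@dataclass
class PreMiRNA:
    """An excised pre-miRNA in local coordinates (0 = Drosha cut)."""

    sequence: str
    structure: str
    pair_table: PairTable
    path: Optional[StemPath]
    offset: int  # hairpin coordinate of local position 0
    flags: list[str] = field(default_factory=list)

    @property
    def irregular(self) -> bool:
        return bool(self.flags)


@dataclass
class DicerCandidate:
    cut: int  # local boundary after the candidate 5p mature 3' end
    mature_len: int
    features: Optional[np.ndarray] = None
    score: Optional[float] = None


def build_premirna(
    hp: FoldedHairpin, drosha_cut: int, refold: bool = True
) -> PreMiRNA:
    """Excise the pre-miRNA at a Drosha cut and (by default) refold it.

    Irregular outcomes (no hairpin in the refold) are flagged, not raised;
    a pre-miRNA length outside 50-80 nt violates the precondition and does
    raise.
    """
    end = project_cut_3p(hp.pair_table, hp.path, drosha_cut, mode="drosha")
    end = min(end, len(hp.record.sequence))
    seq = hp.record.sequence[drosha_cut:end]
    if not (PREMIR_MIN <= len(seq) <= PREMIR_MAX):
        raise StructureError(
            f"pre-miRNA length {len(seq)} outside [{PREMIR_MIN}, {PREMIR_MAX}]"
        )
    if refold:
        db, _ = fold(seq)
    else:
        db = _inherit_structure(hp, drosha_cut, end)
    pt = parse_dotbracket(seq, db)
    flags: list[str] = []
    path: Optional[StemPath] = None
    try:
        path = select_stemloop(pt)
    except StructureError:
        flags.append("irregular:no_hairpin")
    return PreMiRNA(
        sequence=seq, structure=db, pair_table=pt, path=path,
        offset=drosha_cut, flags=flags,
    )


def _inherit_structure(hp: FoldedHairpin, start: int, end: int) -> str:
    """Slice the pri-miRNA dot-bracket, dropping pairs that cross the cut."""
    chars = ["."] * (end - start)
    for i, j in hp.pair_table.pairs():
        if start <= i and j < end:
            chars[i - start], chars[j - start] = "(", ")"
    return "".join(chars)


def enumerate_dicer(pm: PreMiRNA) -> list[DicerCandidate]:
    """Candidate Dicer cuts: 16-25 nt matures whose cut stays on the stem."""
    if pm.irregular or pm.path is None:
        return []
    loop_i5 = pm.path.loop_junction[0]
    out = []
    for m in range(MATURE_MIN, MATURE_MAX + 1):
        if m > len(pm.sequence):
            break
        if m - 1 > loop_i5:  # cut would fall in the terminal loop
            continue
        out.append(DicerCandidate(cut=m, mature_len=m))
    return out


def dicer_features(cand: DicerCandidate, pm: PreMiRNA) -> np.ndarray:
    """The 42-vector for one candidate (see module docstring).

    An internal loop with either side > 6 nt in the mature region raises
    :class:`IrregularStructure`; callers treat the record as irregular (at
    prediction time a clipped best-effort count is used instead — see
    ``clip`` in :func:`candidate_matrix`).
    """
    return _features(cand, pm, clip=False)


def _features(cand: DicerCandidate, pm: PreMiRNA, clip: bool) -> np.ndarray:
    assert pm.path is not None
    grid = np.zeros((MAX_LOOP_SIDE, MAX_LOOP_SIDE))
    b5_count = b5_nt = b3_count = b3_nt = 0
    last5 = cand.cut - 1  # last mature nucleotide on the 5' arm
    for elem in decompose_stem(pm.pair_table, pm.path):
        if elem.kind in ("terminal_loop", "stack"):
            continue
        assert elem.inner is not None
        if elem.inner[0] > last5:  # element above the cut: outside region R
            continue
        if elem.kind == "bulge":
            if elem.unpaired5:
                b5_count += 1
                b5_nt += elem.unpaired5
            else:
                b3_count += 1
                b3_nt += elem.unpaired3
        else:  # internal loop
            u5, u3 = elem.unpaired5, elem.unpaired3
            if u5 > MAX_LOOP_SIDE or u3 > MAX_LOOP_SIDE:
                if not clip:
                    raise IrregularStructure(
                        f"internal loop {u5}x{u3} exceeds {MAX_LOOP_SIDE} nt"
                    )
                u5, u3 = min(u5, MAX_LOOP_SIDE), min(u3, MAX_LOOP_SIDE)
            grid[u5 - 1, u3 - 1] += 1
    first_paired = next(
        (i for i in range(len(pm.pair_table)) if pm.pair_table.is_paired(i)), None
    )
    if first_paired is None:
        raise IrregularStructure("no paired nucleotide in pre-miRNA")
    return np.concatenate(
        [
            grid.ravel(),  # row-major: L(1,1)..L(1,6), L(2,1)..L(6,6)
            [b5_count, b5_nt, b3_count, b3_nt],
            [float(first_paired + 1)],  # 1-based
            [float(cand.mature_len)],
        ]
    )


def derive_dicer_truth(pm: PreMiRNA, record: HairpinRecord) -> CutSite:
    """True Dicer cut (local boundary) from mature annotations.

    5p (or both arms): the boundary after the 5p mature 3' end. 3p-only:
    the 5'-arm boundary leaving a 2-nt overhang past the 3p mature 5' end.
    A truth cut inside the terminal loop flags the record irregular.
    """
    ann5 = record.annotation("5p")
    if ann5 is not None:
        c = ann5.end - pm.offset
    else:
        ann3 = record.annotation("3p")
        if ann3 is None:
            raise ValueError(f"record {record.id}: no mature annotation")
        s_local = ann3.start - pm.offset
        if not (0 <= s_local < len(pm.sequence)):
            raise ValueError(f"record {record.id}: 3p mature outside the pre-miRNA")
        if pm.path is None:
            raise StructureError(f"record {record.id}: irregular pre-miRNA")
        # 5p 3' end overhangs the 3p 5' start by 2:  c - 3 pairs with s_local
        c = partner_extrapolated(pm.pair_table, pm.path, s_local) + 3
    if not (0 < c <= len(pm.sequence)):
        raise ValueError(f"record {record.id}: mature annotation outside pre-miRNA")
    if pm.path is not None and c - 1 > pm.path.loop_junction[0]:
        pm.flags.append("irregular:mature_in_loop")
    return CutSite(position=c, role="dicer5")


def candidate_matrix(
    pm: PreMiRNA, cands: Sequence[DicerCandidate], clip: bool = False
) -> np.ndarray:
    return np.vstack([_features(c, pm, clip=clip) for c in cands])


def build_training_rows(
    premirnas: Sequence[tuple[PreMiRNA, HairpinRecord]], margin: int = 1
) -> tuple[np.ndarray, np.ndarray, int]:
    """Labelled candidate rows; irregular records are skipped (and counted)."""
    X_rows, y_rows, skipped = [], [], 0
    for pm, rec in premirnas:
        cands = enumerate_dicer(pm)
        try:
            truth = derive_dicer_truth(pm, rec).position
        except (ValueError, StructureError):
            skipped += 1
            continue
        if pm.irregular or not any(c.cut == truth for c in cands):
            skipped += 1
            continue
        try:
            X = candidate_matrix(pm, cands, clip=False)
        except IrregularStructure:
            skipped += 1
            continue
        for c, x in zip(cands, X):
            dist = abs(c.cut - truth)
            if 0 < dist <= margin:
                continue
            X_rows.append(x)
            y_rows.append(1 if dist == 0 else 0)
    if not X_rows:
        raise ValueError("no usable training pre-miRNAs")
    return np.vstack(X_rows), np.asarray(y_rows, dtype=np.int8), skipped


def train_dicer(
    premirnas: Sequence[tuple[PreMiRNA, HairpinRecord]],
    n_trees: int = rank.DEFAULT_N_TREES,
    seed: int = 0,
    margin: int = 1,
    balance: bool = False,
    feature_mask: Optional[Sequence[int]] = None,
) -> rank.RankModel:
    X, y, _ = build_training_rows(premirnas, margin=margin)
    return rank.train(
        X, y, n_trees=n_trees, seed=seed, feature_names=FEATURE_NAMES,
        balance=balance, feature_mask=feature_mask,
    )


def predict_dicer(
    pm: PreMiRNA, model: rank.RankModel
) -> tuple[CutSite, float, list[DicerCandidate]]:
    """Highest-scoring Dicer candidate (ties: smallest cut).

    Irregular pre-miRNAs (oversized internal loops) still get a flagged
    best-effort prediction from clipped loop counts.
    """
    cands = enumerate_dicer(pm)
    if not cands:
        raise IrregularStructure("no Dicer candidates (irregular pre-miRNA)")
    try:
        X = candidate_matrix(pm, cands, clip=False)
    except IrregularStructure:
        pm.flags.append("irregular:long_internal_loop")
        X = candidate_matrix(pm, cands, clip=True)
    scores = rank.score(model, X)
    for c, s in zip(cands, scores):
        c.score = float(s)
    best = max(cands, key=lambda c: (c.score, -c.cut))
    return CutSite(position=best.cut, role="dicer5"), best.score, cands


@dataclass
class MaturePair:
    mature5p: tuple[int, int]  # hairpin coordinates, half-open
    mature3p: tuple[int, int]
    mature5p_seq: str
    mature3p_seq: str


def assemble_mature(
    hp: FoldedHairpin, drosha_cut: int, dicer_cut_local: int, pm: PreMiRNA
) -> MaturePair:
    """Mature 5p/3p intervals and sequences in hairpin coordinates.

    mature5p = [drosha_cut, drosha_cut + dicer_cut); mature3p runs from the
    Dicer cut's 3'-arm projection to the pre-miRNA 3' end (both ends carry
    the 2-nt 3' overhangs).
    """
    d = drosha_cut
    c = dicer_cut_local
    m5 = (d, d + c)
    if pm.path is None:
        raise StructureError("cannot assemble matures on an irregular pre-miRNA")
    s3_local = project_cut_3p(pm.pair_table, pm.path, c, mode="dicer")
    m3 = (d + s3_local, d + len(pm.sequence))
    seq = hp.record.sequence
    return MaturePair(
        mature5p=m5,
        mature3p=m3,
        mature5p_seq=seq[m5[0] : m5[1]],
        mature3p_seq=seq[m3[0] : m3[1]],
    )
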