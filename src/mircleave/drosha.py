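"""Drosha stage: candidate pre-miRNA enumeration, 21-feature vectors, ranking.

A candidate Drosha site is a 5'-arm cut boundary whose projected pre-miRNA
(2-nt 3' overhang rule) is 50-80 nt long and whose implied mature region
stays on the stem. Each candidate is described by the energies of the 20
stack faces downstream of the cut (the cut's own face included) plus the
candidate pre-miRNA length — 21 features ranked by a random forest; the
highest-scoring candidate is the predicted site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import rank
from .energy import EnergyModel, FaceProfile, face_profile, profile_window
from .rna_io import CutSite, HairpinRecord, MatureAnnotation
from .structure import (
    PairTable,
    StemPath,
    StructureError,
    partner_extrapolated,
    project_cut_3p,
    select_stemloop,
    structure_of,
)

PREMIR_MIN, PREMIR_MAX = 50, 80
MATURE_MIN = 16
N_FACES = 20

FEATURE_NAMES = [f"face_dG_{k}" for k in range(N_FACES)] + ["premir_len"]


class IrregularStructure(Exception):
    """Hairpin outside the model's regular-structure domain."""


@dataclass
class DroshaCandidate:
    cut: int  # 5'-arm boundary: pre-miRNA starts at this index
    end: int  # exclusive 3' end boundary of the pre-miRNA
    premir_len: int
    features: Optional[np.ndarray] = None
    score: Optional[float] = None


@dataclass
class FoldedHairpin:
    """A hairpin with its pair table, selected stem path and face profile."""

    record: HairpinRecord
    pair_table: PairTable
    path: StemPath
    profile: FaceProfile


def prepare(record: HairpinRecord, loop_split: str = "arm5") -> FoldedHairpin:
    """Fold (or adopt the stored structure), select the stem, build the profile.

    The stem-loop is anchored at the window midpoint, matching windows
    extracted centered on the hairpin; annotated records anchor on their
    mature span instead.
    """
    pt = structure_of(record)
    if record.annotations:
        ann = record.annotations[0]
        anchor: int | tuple[int, int] = (ann.start, ann.end)
    else:
        anchor = len(record.sequence) // 2
    path = select_stemloop(pt, anchor=anchor)
    model = EnergyModel(record.sequence)
    profile = face_profile(path, record.sequence, model, loop_split=loop_split)
    return FoldedHairpin(record=record, pair_table=pt, path=path, profile=profile)


def enumerate_drosha(hp: FoldedHairpin) -> list[DroshaCandidate]:
    """All candidate Drosha cuts, ordered by position.

    An empty list is a value ("no regular structure"), not an error.
    """
    pt, path = hp.pair_table, hp.path
    n = len(pt)
    out = []
    for d in path.arm5_positions:
        try:
            end = project_cut_3p(pt, path, d, mode="drosha")
        except StructureError:
            continue
        length = end - d
        if not (PREMIR_MIN <= length <= PREMIR_MAX):
            continue
        if end > n:
            continue
        # implied mature region must fit on the stem, not the terminal loop
        if d + MATURE_MIN - 1 > path.loop_junction[0]:
            continue
        out.append(DroshaCandidate(cut=d, end=end, premir_len=length))
    return out


def drosha_features(cand: DroshaCandidate, profile: FaceProfile) -> np.ndarray:
    """[e0..e19, premir_len]: 20 downstream face energies plus the length.

    Face 0 spans the cut itself; faces beyond the structured stem are
    0-padded. Energies are taken from the profile unchanged.
    """
    energies, _ = profile_window(profile, cand.cut, 0, N_FACES - 1, pad=0.0)
    return np.concatenate([energies, [float(cand.premir_len)]])


def derive_drosha_truth(hp: FoldedHairpin) -> CutSite:
    """True Drosha cut from mature annotations.

    A 5p (or both-arm) annotation defines the cut at the 5p mature start;
    with a 3p-only annotation the cut is the 5'-arm boundary leaving the
    annotated 3p 3' end overhanging by 2 nt.
    """
    rec = hp.record
    ann5 = rec.annotation("5p")
    if ann5 is not None:
        return CutSite(position=ann5.start, role="drosha5")
    ann3 = rec.annotation("3p")
    if ann3 is None:
        raise ValueError(f"record {rec.id}: no mature annotation")
    # 3p mature 3' end e-1 sits at partner(d)+2  =>  d = partner(e-3)
    d = partner_extrapolated(hp.pair_table, hp.path, ann3.end - 3)
    if d <= 0:
        raise StructureError(f"record {rec.id}: 3p-only truth has no paired anchor")
    return CutSite(position=d, role="drosha5")


def build_training_rows(
    hairpins: Sequence[FoldedHairpin], margin: int = 1
) -> tuple[np.ndarray, np.ndarray, int]:
    """Stack labelled candidate rows over hairpins.

    Positives are the truth candidates; candidates within ``margin`` nt of
    truth are excluded from both classes (ambiguous near-misses); the rest
    are negatives. Hairpins whose truth is not among the candidates are
    skipped; their count is returned.
    """
    X_rows, y_rows, skipped = [], [], 0
    for hp in hairpins:
        cands = enumerate_drosha(hp)
        try:
            truth = derive_drosha_truth(hp).position
        except (ValueError, StructureError):
            skipped += 1
            continue
        if not any(c.cut == truth for c in cands):
            skipped += 1
            continue
        for c in cands:
            dist = abs(c.cut - truth)
            if 0 < dist <= margin:
                continue
            X_rows.append(drosha_features(c, hp.profile))
            y_rows.append(1 if dist == 0 else 0)
    if not X_rows:
        raise ValueError("no usable training hairpins")
    return np.vstack(X_rows), np.asarray(y_rows, dtype=np.int8), skipped


def train_drosha(
    hairpins: Sequence[FoldedHairpin],
    n_trees: int = rank.DEFAULT_N_TREES,
    seed: int = 0,
    margin: int = 1,
    balance: bool = False,
) -> rank.RankModel:
    X, y, _ = build_training_rows(hairpins, margin=margin)
    return rank.train(
        X, y, n_trees=n_trees, seed=seed, feature_names=FEATURE_NAMES, balance=balance
    )


def predict_drosha(
    hp: FoldedHairpin, model: rank.RankModel
) -> tuple[CutSite, float, list[DroshaCandidate]]:
    """Highest-scoring candidate (ties: smallest cut position).

    Raises :class:`IrregularStructure` when no candidate exists.
    """
    cands = enumerate_drosha(hp)
    if not cands:
        raise IrregularStructure(f"record {hp.record.id}: no regular structure")
    X = np.vstack([drosha_features(c, hp.profile) for c in cands])
    scores = rank.score(model, X)
    for c, s in zip(cands, scores):
        c.features, c.score = None, float(s)
    best = max(cands, key=lambda c: (c.score, -c.cut))
    return CutSite(position=best.cut, role="drosha5"), best.score, cands
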