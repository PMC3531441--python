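"""Deviation metrics, dataset hygiene filters and comparison statistics.

Accuracy is reported as the fraction of sites predicted within d nt of the
annotated site (d = 0..5). Spread uses the *population* standard deviation
(divisor n) of the absolute deviations, the convention of cross-validated
tool comparisons in this problem domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import Align
from scipy import stats

from .rna_io import HairpinRecord

MAX_ACCURACY_D = 5


@dataclass
class DeviationReport:
    deviations: dict[str, int]  # per-record signed deviation, predicted - truth
    accuracy_at: list[float] = field(default_factory=list)  # d = 0..5
    mean_abs: float = 0.0
    sdp: float = 0.0  # population SD (divisor n) of |deviation|
    n_evaluated: int = 0
    n_irregular: int = 0


def deviation_report(
    predictions: Mapping[str, int],
    truths: Mapping[str, int],
    n_irregular: int = 0,
) -> DeviationReport:
    """Signed deviations, accuracy-within-d curve, mean |dev| and SDP.

    ``predictions`` and ``truths`` map record ids to cut boundaries and must
    cover the same ids.
    """
    if set(predictions) != set(truths):
        missing = set(predictions) ^ set(truths)
        raise ValueError(f"prediction/truth id mismatch: {sorted(missing)[:5]}")
    if not predictions:
        raise ValueError("empty prediction set")
    devs = {rid: predictions[rid] - truths[rid] for rid in predictions}
    absdev = np.abs(np.array(list(devs.values()), dtype=float))
    accuracy = [float(np.mean(absdev <= d)) for d in range(MAX_ACCURACY_D + 1)]
    return DeviationReport(
        deviations=devs,
        accuracy_at=accuracy,
        mean_abs=float(absdev.mean()),
        sdp=float(absdev.std(ddof=0)),
        n_evaluated=len(devs),
        n_irregular=n_irregular,
    )


def distance_from_truth(
    record: HairpinRecord,
    drosha_deviation: Optional[int],
    dicer_deviation: Optional[int],
) -> int:
    """Mature-start error: the Drosha deviation for 5p-arm microRNAs, the
    Dicer deviation for 3p-only microRNAs (each arm's mature 5' end is set
    by a different enzyme)."""
    if record.annotation("5p") is not None:
        if drosha_deviation is None:
            raise ValueError(f"record {record.id}: missing Drosha deviation")
        return drosha_deviation
    if record.annotation("3p") is not None:
        if dicer_deviation is None:
            raise ValueError(f"record {record.id}: missing Dicer deviation")
        return dicer_deviation
    raise ValueError(f"record {record.id}: no mature annotation")


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = 0
_aligner.open_gap_score = -1
_aligner.extend_gap_score = -1


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns."""
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    total = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / total if total else 0.0


def redundancy_filter(
    records: Sequence[HairpinRecord], threshold: float = 0.90
) -> list[HairpinRecord]:
    """Greedily drop records over ``threshold`` identity to an earlier record.

    Deterministic in input order and idempotent.
    """
    kept: list[HairpinRecord] = []
    for rec in records:
        if any(pairwise_identity(rec.sequence, k.sequence) > threshold for k in kept):
            continue
        kept.append(rec)
    return kept


def family_exclusion(
    test: Sequence[HairpinRecord],
    train: Sequence[HairpinRecord],
    families: Mapping[str, str],
) -> list[HairpinRecord]:
    """Remove test records whose family also occurs in the training set.

    Records absent from the family table are kept (no family evidence).
    """
    train_fams = {families[r.id] for r in train if r.id in families}
    return [
        r for r in test if r.id not in families or families[r.id] not in train_fams
    ]


def negative_hairpin_ok(
    record: HairpinRecord,
    max_stem_pairs: int = 18,
    mfe_threshold: float = -15.0,
    stem_pairs_at_most: bool = True,
) -> bool:
    """Decoy-hairpin admission test for specificity controls.

    Criterion 1: the selected stem carries no more than ``max_stem_pairs``
    base pairs (set ``stem_pairs_at_most=False`` for the at-least reading —
    see the methods note). Criterion 2: MFE <= ``mfe_threshold`` kcal/mol.
    """
    from .structure import fold, parse_dotbracket, select_stemloop, StructureError

    db, mfe = (record.structure, None) if record.structure else fold(record.sequence)
    if mfe is None:
        from .energy import EnergyModel

        mfe = EnergyModel(record.sequence).structure_energy(db)
    pt = parse_dotbracket(record.sequence, db)
    try:
        path = select_stemloop(pt, anchor=len(record.sequence) // 2)
    except StructureError:
        return False
    pairs_ok = (
        path.n_pairs <= max_stem_pairs
        if stem_pairs_at_most
        else path.n_pairs >= max_stem_pairs
    )
    return pairs_ok and mfe <= mfe_threshold


def mean_score_comparison(
    scores_positive: Sequence[float], scores_negative: Sequence[float]
) -> tuple[float, float, float]:
    """Mean best-candidate score per set and a two-sample t-test p-value."""
    if len(scores_positive) == 0 or len(scores_negative) == 0:
        raise ValueError("empty score set")
    a = np.asarray(scores_positive, dtype=float)
    b = np.asarray(scores_negative, dtype=float)
    if np.allclose(a.std(), 0) and np.allclose(b.std(), 0) and np.allclose(
        a.mean(), b.mean()
    ):
        return float(a.mean()), float(b.mean()), 1.0
    t = stats.ttest_ind(a, b)
    return float(a.mean()), float(b.mean()), float(t.pvalue)


def paired_comparison(
    errors_a: Sequence[float], errors_b: Sequence[float]
) -> tuple[float, float, float]:
    """Paired t-test between two tools' per-record errors."""
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("paired comparison needs two equal-length error lists")
    t = stats.ttest_rel(a, b)
    return float(a.mean()), float(b.mean()), float(t.pvalue)


def kfold_split(
    records: Sequence[HairpinRecord], k: int = 5, seed: int = 0
) -> list[tuple[list[HairpinRecord], list[HairpinRecord]]]:
    """Seeded k-fold (train, test) partition; every record tests exactly once."""
    if k < 2 or k > len(records):
        raise ValueError(f"k={k} invalid for {len(records)} records")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    folds = np.array_split(order, k)
    out = []
    for i in range(k):
        test_idx = set(folds[i].tolist())
        test = [records[j] for j in sorted(test_idx)]
        train = [records[j] for j in range(len(records)) if j not in test_idx]
        out.append((train, test))
    return out
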