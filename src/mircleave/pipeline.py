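"""End-to-end orchestration: fold -> Drosha -> excise/refold -> Dicer -> matures.

Library counterpart of the CLI subcommands. All steps are deterministic for
a fixed config and seed; per-record irregular/padding flags propagate into
the output rows, and logs carry the engine version, seeds and model digests
needed to reproduce a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from . import dicer, drosha, rank
from .config import Config
from .rna_io import HairpinRecord, PredictionRow
from .structure import StructureError, engine_version

log = logging.getLogger("mircleave")


def prepare_all(
    records: Sequence[HairpinRecord], cfg: Config
) -> list[drosha.FoldedHairpin]:
    out = []
    for rec in records:
        out.append(drosha.prepare(rec, loop_split=cfg.loop_split))
    return out


def train_drosha_stage(
    records: Sequence[HairpinRecord], cfg: Config
) -> rank.RankModel:
    hairpins = prepare_all(records, cfg)
    log.info("train-drosha: %d hairpins, %s", len(hairpins), engine_version())
    model = drosha.train_drosha(
        hairpins,
        n_trees=cfg.n_trees,
        seed=cfg.seed,
        margin=cfg.train_margin,
        balance=cfg.train_balance,
    )
    return model


def true_premirnas(
    records: Sequence[HairpinRecord], cfg: Config
) -> list[tuple[dicer.PreMiRNA, HairpinRecord]]:
    """Pre-miRNAs excised at the annotation-derived (true) Drosha cuts."""
    out = []
    for hp in prepare_all(records, cfg):
        try:
            truth = drosha.derive_drosha_truth(hp)
            pm = dicer.build_premirna(hp, truth.position, refold=cfg.dicer_refold)
        except (ValueError, StructureError) as exc:
            log.info("dicer-train skip %s: %s", hp.record.id, exc)
            continue
        out.append((pm, hp.record))
    return out


def train_dicer_stage(
    records: Sequence[HairpinRecord],
    cfg: Config,
    feature_mask: Optional[Sequence[int]] = None,
) -> rank.RankModel:
    pms = true_premirnas(records, cfg)
    log.info("train-dicer: %d pre-miRNAs", len(pms))
    return dicer.train_dicer(
        pms,
        n_trees=cfg.n_trees,
        seed=cfg.seed,
        margin=cfg.train_margin,
        balance=cfg.train_balance,
        feature_mask=feature_mask,
    )


def predict_record(
    rec: HairpinRecord,
    drosha_model: rank.RankModel,
    dicer_model: Optional[rank.RankModel],
    cfg: Config,
    stage: str = "all",
) -> PredictionRow:
    """Run the two-stage prediction on one hairpin; flags, never raises for
    irregular structures."""
    row = PredictionRow(hairpin_id=rec.id)
    try:
        hp = drosha.prepare(rec, loop_split=cfg.loop_split)
    except StructureError as exc:
        row.flags.append(f"irregular:{exc}")
        return row
    try:
        cut, score, cands = drosha.predict_drosha(hp, drosha_model)
    except drosha.IrregularStructure:
        row.flags.append("irregular:no_drosha_candidate")
        return row
    best = next(c for c in cands if c.cut == cut.position)
    row.drosha_cut, row.drosha_score = cut.position, score
    row.premir_start, row.premir_end = best.cut, best.end
    row.premirna_seq = rec.sequence[best.cut : best.end]
    if stage == "drosha" or dicer_model is None:
        return row
    try:
        pm = dicer.build_premirna(hp, cut.position, refold=cfg.dicer_refold)
    except StructureError as exc:
        row.flags.append(f"irregular:{exc}")
        return row
    if pm.irregular:
        row.flags.extend(pm.flags)
        return row
    try:
        dcut, dscore, _ = dicer.predict_dicer(pm, dicer_model)
    except dicer.IrregularStructure:
        row.flags.append("irregular:no_dicer_candidate")
        return row
    row.flags.extend(f for f in pm.flags if f not in row.flags)
    row.dicer_cut = cut.position + dcut.position  # hairpin coordinates
    row.dicer_score = dscore
    try:
        mp = dicer.assemble_mature(hp, cut.position, dcut.position, pm)
    except StructureError as exc:
        row.flags.append(f"irregular:{exc}")
        return row
    row.mature5p_seq, row.mature3p_seq = mp.mature5p_seq, mp.mature3p_seq
    row.mature5p_span, row.mature3p_span = mp.mature5p, mp.mature3p
    return row


def predict_all(
    records: Sequence[HairpinRecord],
    drosha_model: rank.RankModel,
    dicer_model: Optional[rank.RankModel],
    cfg: Config,
    stage: str = "all",
) -> list[PredictionRow]:
    log.info(
        "predict: %d records, stage=%s, seed=%d, %s",
        len(records), stage, cfg.seed, engine_version(),
    )
    return [
        predict_record(rec, drosha_model, dicer_model, cfg, stage=stage)
        for rec in records
    ]
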