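"""Shared fixtures: benchmark datasets, trained models, test-local oracles.

The oracle helpers re-derive quantities from dot-bracket strings with plain
stack-based parsing, independent of the package's structure walk.
"""

from __future__ import annotations

import copy

import pytest
from hypothesis import HealthCheck, settings

from mircleave import dicer, drosha, pipeline
from mircleave.config import Config
from mircleave.synthetic import GenParams, make_dataset

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

TRAIN_SEED, TEST_SEED = 101, 202
NULL_TRAIN_SEED, NULL_TEST_SEED = 303, 404
N_TRAIN, N_TEST = 300, 100


# ---------------------------------------------------------------- oracles
def oracle_pairs(db: str) -> dict[int, int]:
    """Stack-parse a dot-bracket into a symmetric partner map."""
    out, stack = {}, []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            out[i], out[j] = j, i
    return out


def oracle_loop_i5(db: str) -> int:
    """5' index of the loop-closing pair: the rightmost '('."""
    return max(i for i, ch in enumerate(db) if ch == "(")


def oracle_partner(db: str, pos: int) -> int:
    """Partner of a 5'-side position, extrapolating from the nearest paired
    position toward the loop (independent re-implementation)."""
    pairs = oracle_pairs(db)
    loop_i5 = oracle_loop_i5(db)
    for k in range(pos, loop_i5 + 1):
        if k in pairs and pairs[k] > k:
            return pairs[k] + (k - pos)
    raise AssertionError("no paired anchor")


def oracle_drosha_candidates(db: str) -> list[int]:
    """Brute-force boundary walk over the 5' arm of a one-stem structure."""
    pairs = oracle_pairs(db)
    loop_i5 = oracle_loop_i5(db)
    arm_start = min(i for i, ch in enumerate(db) if ch == "(")
    out = []
    for d in range(arm_start, loop_i5 + 1):
        end = oracle_partner(db, d) + 3
        if 50 <= end - d <= 80 and end <= len(db) and d + 15 <= loop_i5:
            out.append(d)
    return out


def oracle_dicer_candidates(premir_db: str) -> list[int]:
    loop_i5 = oracle_loop_i5(premir_db)
    return [
        m
        for m in range(16, 26)
        if m <= len(premir_db) and m - 1 <= loop_i5
    ]


# ---------------------------------------------------------------- fixtures
def _strip(records):
    out = copy.deepcopy(records)
    for r in out:
        r.structure = None
    return out


@pytest.fixture(scope="session")
def cfg():
    return Config(seed=11)


@pytest.fixture(scope="session")
def bench(cfg):
    """Signal-0.8 benchmark: annotated records (designed structures kept),
    fold-from-sequence copies, and both trained stage models."""
    train = make_dataset(GenParams(seed=TRAIN_SEED, n=N_TRAIN, signal_strength=0.8)).records
    test = make_dataset(GenParams(seed=TEST_SEED, n=N_TEST, signal_strength=0.8)).records
    train_f, test_f = _strip(train), _strip(test)
    dmodel = pipeline.train_drosha_stage(train_f, cfg)
    cmodel = pipeline.train_dicer_stage(train_f, cfg)
    return {
        "train": train, "test": test,
        "train_folded": train_f, "test_folded": test_f,
        "drosha_model": dmodel, "dicer_model": cmodel,
    }


@pytest.fixture(scope="session")
def null_bench(cfg):
    """Signal-0 benchmark: truth uniform over valid sites, no planted signal."""
    train = make_dataset(GenParams(seed=NULL_TRAIN_SEED, n=N_TRAIN, signal_strength=0.0)).records
    test = make_dataset(GenParams(seed=NULL_TEST_SEED, n=N_TEST, signal_strength=0.0)).records
    train_f, test_f = _strip(train), _strip(test)
    dmodel = pipeline.train_drosha_stage(train_f, cfg)
    cmodel = pipeline.train_dicer_stage(train_f, cfg)
    return {
        "train": train, "test": test,
        "train_folded": train_f, "test_folded": test_f,
        "drosha_model": dmodel, "dicer_model": cmodel,
    }


def evaluate_stages(test_records, test_folded, dmodel, cmodel):
    """Per-record predictions vs planted truth for both stages.

    Returns rows of (record, candidates, drosha_pred, drosha_truth,
    dicer_candidates, dicer_pred, dicer_truth); Dicer runs on the true
    pre-miRNA (annotation-derived Drosha cut), refolded.
    """
    rows = []
    for rec_true, rec in zip(test_records, test_folded):
        hp = drosha.prepare(rec)
        truth_d = drosha.derive_drosha_truth(hp).position
        cut, _, cands = drosha.predict_drosha(hp, dmodel)
        pm = dicer.build_premirna(hp, truth_d, refold=True)
        dicer_row = None
        if not pm.irregular:
            truth_c = dicer.derive_dicer_truth(pm, rec).position
            if not pm.irregular:
                dcut, _, dcands = dicer.predict_dicer(pm, cmodel)
                dicer_row = (dcands, dcut.position, truth_c)
        rows.append((rec_true, cands, cut.position, truth_d, dicer_row))
    return rows
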