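"""Synthetic miRNA-like hairpins with planted Drosha/Dicer truth sites.

Each generated record is a ~130-160 nt window holding one imperfect
stem-loop: a lower stem below the planted Drosha cut, an upper (pre-miRNA)
stem, a terminal loop, and single-stranded A/C flanks that cannot pair with
each other. Truth sites obey the 2-nt 3' overhang algebra, and both-arm
mature annotations are derived from the designed pairing, so every planted
record round-trips through the truth-derivation rules.

``signal_strength`` in [0, 1] sets how learnable the planted sites are:

* with probability ``s`` the Drosha cut sits at the composition-templated
  position — lower-stem pairs follow (each with probability ``s``) a
  vertebrate-like template with a strong-stack (GC) trough 10-14 faces
  downstream of the cut and weak (AU) stacks at 15-20 — and the Dicer cut
  is marked by small 3'-arm bulges bracketing it, with the mature length
  drawn from a 22-nt-peaked distribution;
* otherwise (always, at ``s = 0``) both truth sites are placed uniformly
  among the record's valid candidate boundaries and composition is random,
  making the truth statistically exchangeable with the other candidates.

Planting acts on sequence composition only — energies are always computed
from the sequence by the evaluator, never edited post hoc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .rna_io import HairpinRecord, MatureAnnotation, write_hairpins
from .structure import (
    PairTable,
    StructureError,
    parse_dotbracket,
    partner_extrapolated,
    select_stemloop,
)

PAIRS = ["GC", "CG", "AU", "UA", "GU", "UG"]
PAIR_WEIGHTS = [0.25, 0.25, 0.175, 0.175, 0.075, 0.075]
STRONG = ["GC", "CG"]
WEAK = ["AU", "UA"]
SS_ALPHABET = ["A", "C"]  # A/C cannot pair with each other
SS_WEIGHTS = [0.7, 0.3]

PREMIR_MIN, PREMIR_MAX = 50, 80
MATURE_MIN, MATURE_MAX = 16, 25

#: mature-length weights at full signal: peaked at 22 nt
MATURE_LEN_PEAKED = {
    16: 1, 17: 2, 18: 4, 19: 7, 20: 11, 21: 16, 22: 18, 23: 14, 24: 8, 25: 3,
}

#: lower-stem template by pair depth below the Drosha cut (1 = adjacent)
def _template_pair(depth: int, rng: np.random.Generator) -> Optional[str]:
    if 10 <= depth <= 14:
        return STRONG[rng.integers(2)]
    if 15 <= depth <= 20:
        return WEAK[rng.integers(2)]
    return None


@dataclass
class GenParams:
    """Generation settings; defaults are the package's standard benchmark
    conditions (regular-structure limits are hard constraints)."""

    seed: int = 0
    n: int = 100
    lower_stem_bp: tuple[int, int] = (14, 20)
    loop_len: tuple[int, int] = (6, 12)
    flank_len: int = 30
    loop_rate: float = 0.06  # per between-pair slot
    loop_size_max: int = 3
    signal_strength: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValueError("signal_strength must be in [0, 1]")
        if self.loop_size_max > 6:
            raise ValueError("loop sizes above 6 nt leave the regular domain")
        if self.loop_len[0] < 3:
            raise ValueError("terminal loop must be at least 3 nt")


class _Builder:
    """Accumulates a stem base-to-loop; arms are kept in base-to-loop order."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.a5: list[str] = []
        self.a3: list[str] = []
        self.pairs: list[tuple[int, int]] = []

    def random_pair(self) -> str:
        return PAIRS[self.rng.choice(len(PAIRS), p=PAIR_WEIGHTS)]

    def ss(self, n: int) -> str:
        return "".join(
            np.asarray(SS_ALPHABET)[self.rng.choice(2, size=n, p=SS_WEIGHTS)]
        )

    def add_pair(self, xy: Optional[str] = None) -> None:
        xy = xy or self.random_pair()
        self.a5.append(xy[0])
        self.a3.append(xy[1])
        self.pairs.append((len(self.a5) - 1, len(self.a3) - 1))

    def add_bulge5(self, n: int) -> None:
        self.a5.extend(self.ss(n))

    def add_bulge3(self, n: int) -> None:
        self.a3.extend(self.ss(n))

    def add_internal_loop(self, n5: int, n3: int) -> None:
        self.add_bulge5(n5)
        self.add_bulge3(n3)

    def add_random_loop(self, size_max: int) -> int:
        """Insert a random bulge/internal loop; returns nucleotides added."""
        kind = self.rng.integers(3)
        s1 = int(self.rng.integers(1, size_max + 1))
        if kind == 0:
            self.add_bulge5(s1)
            return s1
        if kind == 1:
            self.add_bulge3(s1)
            return s1
        s2 = int(self.rng.integers(1, size_max + 1))
        self.add_internal_loop(s1, s2)
        return s1 + s2


def make_perfect_hairpin(
    stem_bp: int, loop_len: int, seed: int = 0, flank_len: int = 0
) -> HairpinRecord:
    """A fully complementary Watson-Crick stem with an A/C loop (and flanks)."""
    if stem_bp <= 0:
        raise ValueError("stem_bp must be positive")
    if loop_len < 3:
        raise ValueError("terminal loop must be at least 3 nt")
    rng = np.random.default_rng(seed)
    b = _Builder(rng)
    wc = ["GC", "CG", "AU", "UA"]
    for _ in range(stem_bp):
        b.add_pair(wc[rng.integers(4)])
    return _assemble(b, loop_seq=b.ss(loop_len), f5=b.ss(flank_len),
                     f3=b.ss(flank_len), record_id=f"perfect_{stem_bp}bp")


def _assemble(
    b: _Builder, loop_seq: str, f5: str, f3: str, record_id: str
) -> HairpinRecord:
    n5, n3, nl = len(b.a5), len(b.a3), len(loop_seq)
    seq = f5 + "".join(b.a5) + loop_seq + "".join(reversed(b.a3)) + f3
    db = ["."] * len(seq)
    for i5, i3 in b.pairs:
        db[len(f5) + i5] = "("
        db[len(f5) + n5 + nl + (n3 - 1 - i3)] = ")"
    return HairpinRecord(id=record_id, sequence=seq, structure="".join(db))


def plant_hairpin(params: GenParams, seed: int) -> HairpinRecord:
    """One hairpin with planted truth and both-arm mature annotations."""
    for attempt in range(30):
        rec = _try_plant(params, np.random.default_rng([seed, attempt]))
        if rec is not None:
            return rec
    raise RuntimeError("could not generate a valid hairpin (parameters too tight?)")


def _try_plant(params: GenParams, rng: np.random.Generator) -> Optional[HairpinRecord]:
    s = params.signal_strength
    informative = rng.random() < s
    b = _Builder(rng)

    # --- lower stem (below the Drosha cut), template-biased when informative
    ds = int(rng.integers(params.lower_stem_bp[0], params.lower_stem_bp[1] + 1))
    for t in range(ds):
        depth = ds - t  # 1 = adjacent to the cut
        if t > 0 and rng.random() < params.loop_rate:
            b.add_random_loop(params.loop_size_max)
        tpl = _template_pair(depth, rng) if informative and rng.random() < s else None
        b.add_pair(tpl)
    cut5_rel = len(b.a5)  # pre-miRNA starts here (relative to the 5' arm)

    # --- upper (pre-miRNA) stem with Dicer markers at mature length m
    loop_l = int(rng.integers(params.loop_len[0], params.loop_len[1] + 1))
    if informative:
        m = int(rng.choice(list(MATURE_LEN_PEAKED), p=_mature_probs()))
    else:
        m = int(rng.integers(MATURE_MIN, MATURE_MAX + 1))
    for q in range(m + 3):  # pairs at local 5'-arm positions 0..m+2
        if informative and q == m - 1:
            b.add_bulge3(1)  # marker: enters region R once the cut >= m
        if informative and q == m + 2:
            b.add_bulge3(2)  # marker: enters region R once the cut >= m+3
        b.add_pair()
    base_len = (len(b.a5) - cut5_rel) + (len(b.a3) - cut5_rel)
    # extra pairs to put the pre-miRNA length inside [50, 80]
    lo = max(2, -(-(PREMIR_MIN - loop_l - 2 - base_len) // 2))
    hi = (PREMIR_MAX - 4 - loop_l - 2 - base_len) // 2  # slack for random loops
    if hi < lo:
        return None
    extra = int(rng.integers(lo, hi + 1))
    for t in range(extra):
        cur = (len(b.a5) - cut5_rel) + (len(b.a3) - cut5_rel)
        if (
            t > 0
            and rng.random() < params.loop_rate
            and cur + 2 * params.loop_size_max + 2 * (extra - t) + loop_l + 2
            <= PREMIR_MAX
        ):
            b.add_random_loop(params.loop_size_max)
        b.add_pair()

    rec = _assemble(
        b,
        loop_seq=b.ss(loop_l),
        f5=b.ss(params.flank_len),
        f3=b.ss(params.flank_len),
        record_id="syn",
    )
    pt = parse_dotbracket(rec.sequence, rec.structure)
    try:
        path = select_stemloop(pt, anchor=len(rec.sequence) // 2)
    except StructureError:
        return None

    d0 = params.flank_len + cut5_rel
    if informative:
        d, c = d0, m
        if not _valid_site(pt, path, d, c):
            return None
    else:
        choices = _valid_choices(pt, path)
        if not choices:
            return None
        d, c = choices[rng.integers(len(choices))]

    e3 = pt[d] + 3  # 3p mature 3' end (exclusive): 2-nt overhang past partner(d)
    s3 = pt[d + c - 3]  # 3p mature 5' start: pairs the 5p 3' end minus the overhang
    if not (MATURE_MIN <= e3 - s3 <= MATURE_MAX) or e3 > len(rec.sequence):
        return None
    rec.annotations = [
        MatureAnnotation(start=d, end=d + c, arm="5p"),
        MatureAnnotation(start=s3, end=e3, arm="3p"),
    ]
    rec.truth = (d, d + c)
    return rec


def _mature_probs() -> np.ndarray:
    w = np.array([MATURE_LEN_PEAKED[k] for k in sorted(MATURE_LEN_PEAKED)], float)
    return w / w.sum()


def _valid_choices(pt: PairTable, path) -> list[tuple[int, int]]:
    return [
        (d, c)
        for d in path.arm5_positions
        for c in range(MATURE_MIN, MATURE_MAX + 1)
        if _valid_site(pt, path, d, c)
    ]


def valid_truth_choices(record: HairpinRecord) -> list[tuple[int, int]]:
    """All (drosha_cut, local dicer_cut) sites the generator could plant in a
    record, from its designed structure — the support of the uniform truth
    placement at signal_strength 0 (useful as an exact chance-level null)."""
    if record.structure is None:
        raise ValueError("valid_truth_choices needs the designed structure")
    pt = parse_dotbracket(record.sequence, record.structure)
    path = select_stemloop(pt, anchor=len(record.sequence) // 2)
    return _valid_choices(pt, path)


def _valid_site(pt: PairTable, path, d: int, c: int) -> bool:
    """Drosha cut d / Dicer cut d+c is a regular, cleanly-paired truth site."""
    loop_i5 = path.loop_junction[0]
    if not (path.on_arm5(d) and pt[d] >= 0 and pt[d + c - 3] >= 0):
        return False
    if d + c - 1 > loop_i5:  # mature must end on the stem
        return False
    premir_len = pt[d] + 3 - d
    if not (PREMIR_MIN <= premir_len <= PREMIR_MAX):
        return False
    if d + MATURE_MIN - 1 > loop_i5:
        return False
    return True


@dataclass
class Dataset:
    records: list[HairpinRecord]
    params: GenParams
    fasta_path: Optional[Path] = None
    annotation_path: Optional[Path] = None
    truth_path: Optional[Path] = None


def make_dataset(params: GenParams, out_dir: Optional[str | Path] = None) -> Dataset:
    """Generate ``params.n`` records (reproducible per seed); optionally write
    FASTA + annotation TSV + truth TSV consumable by the CLI."""
    records = []
    for i in range(params.n):
        rec = plant_hairpin(params, seed=_record_seed(params.seed, i))
        rec.id = f"syn{i:04d}"
        records.append(rec)
    ds = Dataset(records=records, params=params)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ds.fasta_path = out / "hairpins.fa"
        ds.annotation_path = out / "matures.tsv"
        ds.truth_path = out / "truth.tsv"
        write_hairpins(records, ds.fasta_path)
        with ds.annotation_path.open("w") as fh:
            for rec in records:
                for ann in rec.annotations:
                    fh.write(f"{rec.id}\t{ann.start}\t{ann.end}\t{ann.arm}\n")
        with ds.truth_path.open("w") as fh:
            fh.write("hairpin_id\tdrosha_cut\tdicer_cut\n")
            for rec in records:
                assert rec.truth is not None
                fh.write(f"{rec.id}\t{rec.truth[0]}\t{rec.truth[1]}\n")
    return ds


def _record_seed(seed: int, index: int) -> int:
    # stable per-record seed, independent of n
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))
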