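"""Input/output and the coordinate conventions used throughout the package.

Conventions
-----------
* All coordinates are 0-based; intervals are half-open ``[start, end)``.
* A *cut site* is an integer boundary index ``p``: the backbone is cleaved
  between nucleotides ``p-1`` and ``p``.
* RNA is canonical internally (``U`` not ``T``); DNA input is transcribed.
* GFF3 output is 1-based inclusive, as the format requires.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

TSV_COLUMNS = [
    "hairpin_id",
    "drosha_cut",
    "drosha_score",
    "dicer_cut",
    "dicer_score",
    "mature5p_seq",
    "mature3p_seq",
    "premirna_seq",
    "flags",
]


class FormatError(ValueError):
    """Malformed input file or record."""


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA interval on its hairpin, 0-based half-open."""

    start: int
    end: int
    arm: str  # "5p" or "3p"

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise FormatError(f"unknown arm token {self.arm!r} (expected 5p/3p)")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"empty or negative mature interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CutSite:
    """A cleavage boundary: the cut falls *before* 0-based index ``position``.

    ``role`` is ``"drosha5"`` or ``"dicer5"`` — both sites are represented on
    the 5' arm; the matching 3'-arm boundary follows from the 2-nt 3' overhang
    left by RNase III enzymes (see :mod:`mircleave.structure`).
    """

    position: int
    role: str = "drosha5"

    def __post_init__(self) -> None:
        if self.role not in ("drosha5", "dicer5"):
            raise ValueError(f"unknown cut role {self.role!r}")
        if self.position <= 0:
            raise ValueError("cut boundary must be a positive interior index")


@dataclass
class HairpinRecord:
    """One hairpin (pri-miRNA window) with optional structure and truth.

    ``truth`` holds planted/annotated cut boundaries in hairpin coordinates:
    ``(drosha_cut, dicer_cut)`` where ``dicer_cut`` is the boundary after the
    last 5p-mature nucleotide.
    """

    id: str
    sequence: str
    structure: Optional[str] = None
    annotations: list[MatureAnnotation] = field(default_factory=list)
    truth: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence, record_id=self.id)
        if not self.sequence:
            raise FormatError(f"record {self.id}: empty sequence")
        if self.structure is not None and len(self.structure) != len(self.sequence):
            raise FormatError(
                f"record {self.id}: structure length {len(self.structure)} != "
                f"sequence length {len(self.sequence)}"
            )
        for ann in self.annotations:
            self._check_annotation(ann)

    def _check_annotation(self, ann: MatureAnnotation) -> None:
        if ann.end > len(self.sequence):
            raise FormatError(
                f"record {self.id}: annotation [{ann.start}, {ann.end}) exceeds "
                f"sequence length {len(self.sequence)}"
            )

    def with_annotations(self, anns: Sequence[MatureAnnotation]) -> "HairpinRecord":
        rec = replace(self, annotations=list(anns))
        return rec

    def annotation(self, arm: str) -> Optional[MatureAnnotation]:
        for ann in self.annotations:
            if ann.arm == arm:
                return ann
        return None

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_rna(seq: str, record_id: str = "?") -> str:
    """Uppercase, transcribe T->U, and validate the alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise FormatError(
            f"record {record_id}: illegal character(s) {sorted(bad)} in sequence"
        )
    return s


def read_hairpins(fasta_path: str | Path) -> list[HairpinRecord]:
    """Read hairpins from FASTA; ids are the first whitespace token of headers."""
    path = Path(fasta_path)
    records = []
    with path.open() as fh:
        first = fh.read(1)
        if first and first != ">":
            raise FormatError(f"{path}: not FASTA (first line must start with '>')")
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(HairpinRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_hairpins(records: Iterable[HairpinRecord], fasta_path: str | Path) -> None:
    with Path(fasta_path).open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


def read_structures(dbn_path: str | Path, records: list[HairpinRecord]) -> None:
    """Attach dot-bracket structures to ``records`` in place.

    The file carries one structure line per record, same order as the FASTA
    (optionally interleaved with ``>id`` headers and sequence lines, i.e.
    plain ``.dbn`` output is accepted).
    """
    lines = [
        ln.strip()
        for ln in Path(dbn_path).read_text().splitlines()
        if ln.strip() and not ln.startswith(">") and set(ln.strip()) <= set(".()")
    ]
    if len(lines) != len(records):
        raise FormatError(
            f"{dbn_path}: {len(lines)} structure lines for {len(records)} records"
        )
    for rec, db in zip(records, lines):
        if len(db) != len(rec.sequence):
            raise FormatError(
                f"{dbn_path}: structure length mismatch for record {rec.id}"
            )
        rec.structure = db


def read_annotations(
    tsv_path: str | Path,
    hairpins: Optional[dict[str, HairpinRecord]] = None,
) -> dict[str, list[MatureAnnotation]]:
    """Read a mature-annotation TSV: hairpin_id, start, end, arm (0-based, half-open).

    When ``hairpins`` is given, coordinates are validated against the loaded
    sequences. A hairpin may carry entries for both arms.
    """
    table: dict[str, list[MatureAnnotation]] = {}
    with Path(tsv_path).open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{tsv_path}:{lineno}: expected >=4 tab-separated columns"
                )
            hid, start_s, end_s, arm = fields[0], fields[1], fields[2], fields[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{tsv_path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise FormatError(
                    f"{tsv_path}:{lineno}: empty interval [{start}, {end}) for {hid}"
                )
            ann = MatureAnnotation(start=start, end=end, arm=arm)
            if hairpins is not None:
                if hid not in hairpins:
                    raise FormatError(f"{tsv_path}:{lineno}: unknown hairpin id {hid}")
                hairpins[hid]._check_annotation(ann)
            table.setdefault(hid, []).append(ann)
    if hairpins is not None:
        for hid, anns in table.items():
            hairpins[hid].annotations = anns
    return table


def read_families(tsv_path: str | Path) -> dict[str, str]:
    """Read a family table (family_id<TAB>member_id) -> {member_id: family_id}."""
    members: dict[str, str] = {}
    with Path(tsv_path).open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{tsv_path}:{lineno}: expected family_id<TAB>member_id")
            members[fields[1]] = fields[0]
    return members


@dataclass
class PredictionRow:
    """One hairpin's pipeline output (see TSV_COLUMNS for serialization order)."""

    hairpin_id: str
    drosha_cut: Optional[int] = None
    drosha_score: Optional[float] = None
    dicer_cut: Optional[int] = None  # hairpin coordinates (boundary)
    dicer_score: Optional[float] = None
    mature5p_seq: str = ""
    mature3p_seq: str = ""
    premirna_seq: str = ""
    flags: list[str] = field(default_factory=list)
    # not serialized to TSV; used by GFF3 output
    premir_start: Optional[int] = None
    premir_end: Optional[int] = None
    mature5p_span: Optional[tuple[int, int]] = None
    mature3p_span: Optional[tuple[int, int]] = None


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{value:.4f}"
    return str(value)


def write_predictions(
    rows: Iterable[PredictionRow], path: str | Path, format: str = "tsv"
) -> None:
    """Write predictions as TSV or GFF3.

    GFF3 emits ``pre_miRNA`` and ``miRNA`` features in 1-based inclusive
    coordinates on the hairpin sequence.
    """
    fmt = format.lower()
    if fmt == "tsv":
        _write_tsv(rows, path)
    elif fmt == "gff3":
        _write_gff3(rows, path)
    else:
        raise FormatError(f"unknown prediction format {format!r} (use tsv or gff3)")


def _write_tsv(rows: Iterable[PredictionRow], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for row in rows:
            writer.writerow(
                [
                    row.hairpin_id,
                    _fmt(row.drosha_cut),
                    _fmt(row.drosha_score),
                    _fmt(row.dicer_cut),
                    _fmt(row.dicer_score),
                    row.mature5p_seq,
                    row.mature3p_seq,
                    row.premirna_seq,
                    ";".join(row.flags) if row.flags else ".",
                ]
            )


def _write_gff3(rows: Iterable[PredictionRow], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for row in rows:
            if row.premir_start is None or row.premir_end is None:
                continue
            # half-open [start, end) -> 1-based inclusive [start+1, end]
            fh.write(
                "\t".join(
                    [
                        row.hairpin_id,
                        "mircleave",
                        "pre_miRNA",
                        str(row.premir_start + 1),
                        str(row.premir_end),
                        _fmt(row.drosha_score),
                        "+",
                        ".",
                        f"ID={row.hairpin_id}_premir",
                    ]
                )
                + "\n"
            )
            for arm, span in (("5p", row.mature5p_span), ("3p", row.mature3p_span)):
                if span is None:
                    continue
                fh.write(
                    "\t".join(
                        [
                            row.hairpin_id,
                            "mircleave",
                            "miRNA",
                            str(span[0] + 1),
                            str(span[1]),
                            _fmt(row.dicer_score),
                            "+",
                            ".",
                            f"ID={row.hairpin_id}_{arm};Parent={row.hairpin_id}_premir",
                        ]
                    )
                    + "\n"
                )


def read_predictions(path: str | Path) -> list[PredictionRow]:
    """Reparse a prediction TSV (round-trip counterpart of write_predictions)."""
    rows: list[PredictionRow] = []
    with Path(path).open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != TSV_COLUMNS:
            raise FormatError(f"{path}: unexpected prediction TSV header")
        for fields in reader:
            if not fields:
                continue

            def opt_int(s: str) -> Optional[int]:
                return None if s == "NA" else int(s)

            def opt_float(s: str) -> Optional[float]:
                return None if s == "NA" else float(s)

            rows.append(
                PredictionRow(
                    hairpin_id=fields[0],
                    drosha_cut=opt_int(fields[1]),
                    drosha_score=opt_float(fields[2]),
                    dicer_cut=opt_int(fields[3]),
                    dicer_score=opt_float(fields[4]),
                    mature5p_seq=fields[5],
                    mature3p_seq=fields[6],
                    premirna_seq=fields[7],
                    flags=[] if fields[8] == "." else fields[8].split(";"),
                )
            )
    return rows
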