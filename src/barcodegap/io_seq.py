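"""Sequence and metadata I/O for barcode surveys.

Reads FASTA barcode sequences and a per-sample metadata table (morphological
species label, sampling location, hybrid-suspect flag), and trims sequences to
a shared analysis region so that every downstream pairwise comparison runs over
the same aligned window.

Coordinates are 0-based half-open internally; reports print 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes -> set of compatible unambiguous bases.
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: Characters allowed in a stored sequence (gap included).
ALPHABET = frozenset(IUPAC) | {"-"}

_TRUE = {"yes", "true", "1"}
_FALSE = {"no", "false", "0"}


class FastaParseError(ValueError):
    """Malformed FASTA input (empty sequence, duplicate id, illegal character)."""


@dataclass
class SeqRecord:
    """One sequenced sample.

    Metadata fields stay ``None`` until joined from the sample table.
    """

    id: str
    sequence: str
    species_label: str | None = None
    location: str | None = None
    hybrid_suspect: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        seq = self.sequence.upper().replace("U", "T")
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - ALPHABET
        if bad:
            raise FastaParseError(
                f"record {self.id!r}: illegal character(s) {sorted(bad)}"
            )
        self.sequence = seq


@dataclass
class AlignedSet:
    """Records sharing one analysis region of identical length."""

    records: list[SeqRecord]
    length: int = field(default=0)

    def __post_init__(self) -> None:
        if self.records and not self.length:
            self.length = len(self.records[0].sequence)
        for r in self.records:
            if len(r.sequence) != self.length:
                raise ValueError(
                    f"record {r.id!r} has length {len(r.sequence)}, "
                    f"expected {self.length}"
                )
        if self.records and self.length <= 0:
            raise ValueError("alignment length must be positive")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into bare :class:`SeqRecord` objects.

    The sample id is the first whitespace-delimited token of the header.
    Sequences are uppercased; duplicate ids, empty sequences and characters
    outside the IUPAC DNA alphabet raise :class:`FastaParseError` naming the
    offending header.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq)
        if not seq:
            raise FastaParseError(f"FASTA entry {entry.id!r}: empty sequence")
        if entry.id in seen:
            raise FastaParseError(f"FASTA entry {entry.id!r}: duplicate id")
        seen.add(entry.id)
        try:
            records.append(SeqRecord(id=entry.id, sequence=seq))
        except FastaParseError:
            raise
        except ValueError as exc:
            raise FastaParseError(f"FASTA entry {entry.id!r}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write records to FASTA (id + sequence only)."""
    bio = [BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def _parse_bool(value: object, row_id: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValueError(
        f"metadata row {row_id!r}: hybrid_suspect {value!r} not in "
        "{yes,no,true,false,1,0}"
    )


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (columns id, species, location, hybrid_suspect)."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "species", "location", "hybrid_suspect"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metadata missing column(s): {sorted(missing)}")
    return table


def join_metadata(
    records: Sequence[SeqRecord], table: pd.DataFrame
) -> list[SeqRecord]:
    """Attach species label, location and hybrid flag to each record.

    Every record must appear exactly once in the table; records missing from
    the table raise an error listing their ids.
    """
    ids = table["id"].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate metadata id(s): {dupes}")
    rows = {row["id"]: row for _, row in table.iterrows()}
    absent = [r.id for r in records if r.id not in rows]
    if absent:
        raise ValueError(f"record(s) missing from metadata: {absent}")
    out = []
    for r in records:
        row = rows[r.id]
        out.append(
            replace(
                r,
                species_label=str(row["species"]),
                location=str(row["location"]),
                hybrid_suspect=_parse_bool(row["hybrid_suspect"], r.id),
            )
        )
    return out


def _valid_site(ch: str) -> bool:
    # auto-trim treats gaps and fully missing bases as absent coverage
    return ch in IUPAC and ch != "N"


def trim_to_region(
    records: Sequence[SeqRecord],
    mode: str = "auto",
    start: int | None = None,
    end: int | None = None,
) -> tuple[AlignedSet, list[SeqRecord]]:
    """Cut all sequences to one shared window.

    ``explicit`` mode uses the 0-based half-open window ``[start, end)``;
    records too short to cover it are dropped with a warning and returned in
    the second element. ``auto`` mode takes the longest contiguous run of
    columns covered by a non-gap, non-missing base in every sequence.
    """
    if not records:
        raise ValueError("no records to trim")
    if mode == "explicit":
        if start is None or end is None or not (0 <= start < end):
            raise ValueError("explicit mode requires 0 <= start < end")
        kept, dropped = [], []
        for r in records:
            if len(r.sequence) < end:
                logger.warning(
                    "dropping %s: length %d cannot cover window [%d, %d)",
                    r.id, len(r.sequence), start, end,
                )
                dropped.append(r)
            else:
                kept.append(replace(r, sequence=r.sequence[start:end]))
        if not kept:
            raise ValueError("no record covers the requested window")
        return AlignedSet(kept), dropped
    if mode == "auto":
        width = min(len(r.sequence) for r in records)
        covered = [
            all(_valid_site(r.sequence[i]) for r in records) for i in range(width)
        ]
        best_start = best_len = run_start = 0
        run_len = 0
        for i, ok in enumerate(covered):
            if ok:
                if run_len == 0:
                    run_start = i
                run_len += 1
                if run_len > best_len:
                    best_start, best_len = run_start, run_len
            else:
                run_len = 0
        if best_len == 0:
            raise ValueError("sequences share no gap-free overlap")
        window = (best_start, best_start + best_len)
        trimmed = [
            replace(r, sequence=r.sequence[window[0]:window[1]]) for r in records
        ]
        return AlignedSet(trimmed), []
    raise ValueError(f"unknown trim mode {mode!r}")
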