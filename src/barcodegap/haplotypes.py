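"""Collapse identical barcode sequences into named haplotypes per species group.

A haplotype is a distinct sequence variant within a species (or
species+location) group. Collapsing uses exact string equality over
unambiguous bases; a sequence carrying IUPAC ambiguity codes joins an existing
haplotype only when it is compatible with exactly one of them, otherwise it
forms its own haplotype flagged ``ambiguous_only``. Samples flagged as
suspected hybrids are collapsed in a parallel group (label suffixed ``*``) and
never merged with non-suspect fish of the same species, so that hybrid
sequences can be excluded from within-species distance averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_seq import IUPAC, AlignedSet, SeqRecord


@dataclass
class Haplotype:
    """A distinct sequence variant with its member samples."""

    sequence: str
    member_ids: list[str]
    name: str | None = None
    ambiguous_only: bool = False
    known: bool | None = None  # set by new_vs_reference

    @property
    def count(self) -> int:
        return len(self.member_ids)


@dataclass
class HaplotypeTable:
    """Haplotypes of one group, ordered by descending count (ties: input order)."""

    group_label: str
    haplotypes: list[Haplotype]
    n_samples: int
    hybrid_group: bool = False

    def frequencies(self) -> list[float]:
        return [h.count / self.n_samples for h in self.haplotypes]


def _unambiguous(seq: str) -> bool:
    return set(seq) <= set("ACGT")

def _compatible(seq: str, ref: str) -> bool:
    """True when every position's IUPAC sets intersect ('-' matches nothing)."""
    for a, b in zip(seq, ref):
        sa, sb = IUPAC.get(a), IUPAC.get(b)
        if sa is None or sb is None or not (sa & sb):
            return False
    return True


def collapse(aligned: AlignedSet, group_key: str = "species") -> list[HaplotypeTable]:
    """Collapse an aligned sample set into per-group haplotype tables.

    ``group_key`` is ``"species"`` or ``"species+location"``. Suspected
    hybrids form their own parallel group with the label suffixed ``*``.
    Groups appear in order of first occurrence in the input; empty groups are
    simply absent.
    """
    if not aligned.records:
        raise ValueError("empty alignment")
    if group_key not in ("species", "species+location"):
        raise ValueError(f"unknown group key {group_key!r}")

    groups: dict[str, list[SeqRecord]] = {}
    hybrid_flags: dict[str, bool] = {}
    for rec in aligned:
        if rec.species_label is None:
            raise ValueError(f"record {rec.id!r} lacks a species label")
        label = rec.species_label
        if group_key == "species+location":
            label = f"{label} @ {rec.location}"
        if rec.hybrid_suspect:
            label += "*"
        groups.setdefault(label, []).append(rec)
        hybrid_flags[label] = rec.hybrid_suspect

    tables = []
    for label, recs in groups.items():
        plain = [r for r in recs if _unambiguous(r.sequence)]
        fuzzy = [r for r in recs if not _unambiguous(r.sequence)]
        haps: list[Haplotype] = []
        by_seq: dict[str, Haplotype] = {}
        for r in plain:
            hap = by_seq.get(r.sequence)
            if hap is None:
                hap = Haplotype(sequence=r.sequence, member_ids=[])
                by_seq[r.sequence] = hap
                haps.append(hap)
            hap.member_ids.append(r.id)
        for r in fuzzy:
            matches = [h for h in haps if _compatible(r.sequence, h.sequence)]
            if len(matches) == 1:
                matches[0].member_ids.append(r.id)
            else:
                haps.append(
                    Haplotype(sequence=r.sequence, member_ids=[r.id],
                              ambiguous_only=True)
                )
        # stable sort keeps first-occurrence order among equal counts
        haps.sort(key=lambda h: -h.count)
        tables.append(
            HaplotypeTable(
                group_label=label,
                haplotypes=haps,
                n_samples=len(recs),
                hybrid_group=hybrid_flags[label],
            )
        )
    return tables


def _letters(i: int) -> str:
    """0 -> 'A', 25 -> 'Z', 26 -> 'AA' (spreadsheet-column style)."""
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("A") + rem) + out
    return out


def name_haplotypes(
    tables: Sequence[HaplotypeTable], acronym_map: Mapping[str, str]
) -> list[HaplotypeTable]:
    """Name haplotypes acronym + 'A','B',... in table order (in place).

    ``acronym_map`` maps the species name to a short code (e.g. "Gr" for
    *Garra rufa* -> "GrA".."GrD"). Hybrid groups use the same acronym with a
    trailing '*' on each name so labels stay unique across groups. Beyond 26
    haplotypes names continue 'AA', 'AB', ... When several tables share one
    acronym (species+location grouping), lettering continues across them in
    table order so every name stays unique.
    """
    seen = {}
    for code in acronym_map.values():
        if code in seen:
            raise ValueError(f"acronym {code!r} assigned to more than one species")
        seen[code] = True
    counters: dict[tuple[str, str], int] = {}
    out = []
    for table in tables:
        species = table.group_label.rstrip("*").split(" @ ")[0]
        try:
            code = acronym_map[species]
        except KeyError:
            raise KeyError(f"no acronym for species {species!r}") from None
        suffix = "*" if table.hybrid_group else ""
        offset = counters.get((code, suffix), 0)
        for i, hap in enumerate(table.haplotypes):
            hap.name = f"{code}{_letters(offset + i)}{suffix}"
        counters[(code, suffix)] = offset + len(table.haplotypes)
        out.append(table)
    return out


def default_acronyms(species: Iterable[str]) -> dict[str, str]:
    """Derive unique 2+-letter acronyms from species names (genus+species initials)."""
    acronyms: dict[str, str] = {}
    used: set[str] = set()
    for sp in species:
        parts = [p for p in sp.replace("_", " ").split() if p]
        base = (parts[0][0].upper() + (parts[1][0].lower() if len(parts) > 1 else "x"))
        code, k = base, 1
        while code in used:
            k += 1
            code = f"{base}{k}"
        used.add(code)
        acronyms[sp] = code
    return acronyms


def new_vs_reference(
    tables: Sequence[HaplotypeTable], reference: "ReferenceLibrary"
) -> pd.DataFrame:
    """Mark each haplotype known (exact sequence in the reference) or new.

    Returns a table with one row per haplotype (species, haplotype, count,
    frequency, new) — the per-species number of new barcodes is
    ``df.groupby("species")["new"].sum()``.
    """
    ref_seqs = {e.sequence for e in reference.entries}
    rows = []
    for table in tables:
        for hap in table.haplotypes:
            hap.known = hap.sequence in ref_seqs
            rows.append(
                {
                    "species": table.group_label,
                    "haplotype": hap.name,
                    "count": hap.count,
                    "frequency": round(hap.count / table.n_samples, 4),
                    "new": not hap.known,
                }
            )
    return pd.DataFrame(rows)


def table_to_frame(tables: Sequence[HaplotypeTable]) -> pd.DataFrame:
    """Flatten haplotype tables to the report layout (Table-2 style columns)."""
    rows = []
    for t in tables:
        for h in t.haplotypes:
            rows.append(
                {
                    "species": t.group_label,
                    "n_samples": t.n_samples,
                    "haplotype": h.name,
                    "count": h.count,
                    "frequency": round(h.count / t.n_samples, 4),
                    "ambiguous_only": h.ambiguous_only,
                }
            )
    return pd.DataFrame(rows)
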