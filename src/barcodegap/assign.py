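"""Reference-based molecular species identification and discrepancy flagging.

A local reference library (FASTA + taxonomy TSV) stands in for an online
barcode database. Each query haplotype is compared against every reference
entry over the pairwise-deleted sites of their shared region; the hit list
ranks species by percent identity, and the called species is the top hit —
or AMBIGUOUS when two or more species tie at 4-decimal identity, mirroring
how co-equal database hits are reported in practice.

Discrepancy flags compare the molecular call against the morphological label
(a correct genus with a different species still counts as a discrepancy);
hybrid evidence requires both a prior morphological hybrid suspicion and a
mismatching molecular call, since a hybrid carries the mitochondrial barcode
of only one parent species.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import io_seq
from .distance import DistanceMatrix, GroupSummary, _summary, k2p

AMBIGUOUS = "AMBIGUOUS"

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class RefEntry:
    id: str
    sequence: str
    species: str
    source_tag: str = ""
    location: str = ""


@dataclass
class ReferenceLibrary:
    """Reference barcode entries indexed by species."""

    entries: list[RefEntry]

    def __post_init__(self) -> None:
        for e in self.entries:
            if not e.species:
                raise ValueError(f"reference entry {e.id!r} has empty species")

    @classmethod
    def from_files(cls, fasta: str | Path, taxonomy: str | Path) -> "ReferenceLibrary":
        """Load FASTA + TSV (sequence_id, species, source_tag, location)."""
        records = io_seq.read_fasta(fasta)
        table = pd.read_csv(taxonomy, sep="\t", dtype=str).fillna("")
        if "sequence_id" not in table.columns or "species" not in table.columns:
            raise ValueError("taxonomy TSV needs sequence_id and species columns")
        rows = table.set_index("sequence_id")
        entries = []
        for rec in records:
            if rec.id not in rows.index:
                raise ValueError(f"reference sequence {rec.id!r} missing taxonomy")
            row = rows.loc[rec.id]
            entries.append(
                RefEntry(
                    id=rec.id,
                    sequence=rec.sequence,
                    species=str(row["species"]),
                    source_tag=str(row.get("source_tag", "")),
                    location=str(row.get("location", "")),
                )
            )
        return cls(entries)

    def species(self) -> list[str]:
        return sorted({e.species for e in self.entries})


@dataclass
class Hit:
    species: str
    percent_identity: float
    k2p_d: float


@dataclass
class AssignmentResult:
    query: str
    hits: list[Hit]
    called_species: str | None
    discrepancy: bool | None = None
    hybrid_evidence: bool | None = None
    tied_species: list[str] = field(default_factory=list)


def _identity(query: str, ref: str) -> tuple[float, int]:
    """Percent identity over pairwise-deleted sites of the shared prefix region."""
    n = matches = 0
    for a, b in zip(query, ref):
        if a in _VALID and b in _VALID:
            n += 1
            if a == b:
                matches += 1
    if n == 0:
        return 0.0, 0
    return 100.0 * matches / n, n


def identify(
    query,
    ref: ReferenceLibrary,
    min_identity: float = 97.0,
    min_overlap: int = 200,
) -> AssignmentResult:
    """Identify one query haplotype against the reference library.

    ``query`` is a Haplotype-like object (.name, .sequence) or a
    (name, sequence) tuple. Hits are the best identity per species, ranked
    descending; hits below ``min_identity`` are omitted. ``called_species``
    is the top species, AMBIGUOUS on a 4-decimal tie, or None when no hit
    passes the threshold.
    """
    name, seq = query if isinstance(query, tuple) else (query.name, query.sequence)
    if not ref.entries:
        raise ValueError("empty reference library")

    best: dict[str, tuple[float, str]] = {}
    any_overlap = False
    for entry in ref.entries:
        ident, n = _identity(seq, entry.sequence)
        if n < min_overlap:
            continue
        any_overlap = True
        if entry.species not in best or ident > best[entry.species][0]:
            best[entry.species] = (ident, entry.sequence)
    if not any_overlap:
        raise ValueError(
            f"query {name!r} shares no region of >= {min_overlap} sites "
            "with any reference entry"
        )

    hits = []
    for species, (ident, ref_seq) in best.items():
        if ident < min_identity:
            continue
        L = min(len(seq), len(ref_seq))
        pw = k2p(seq[:L], ref_seq[:L])
        hits.append(Hit(species=species, percent_identity=ident, k2p_d=pw.d))
    hits.sort(key=lambda h: (-h.percent_identity, h.species))

    if not hits:
        return AssignmentResult(query=name, hits=[], called_species=None)
    top = round(hits[0].percent_identity, 4)
    tied = [h.species for h in hits if round(h.percent_identity, 4) == top]
    if len(tied) > 1:
        return AssignmentResult(
            query=name, hits=hits, called_species=AMBIGUOUS, tied_species=tied
        )
    return AssignmentResult(query=name, hits=hits, called_species=hits[0].species)


def flag_discrepancies(
    assignments: Sequence[AssignmentResult],
    metadata: Mapping[str, tuple[str, bool]],
) -> pd.DataFrame:
    """Flag morphology/molecular disagreements and hybrid evidence.

    ``metadata`` maps each query name to (morphological species,
    hybrid_suspect). A discrepancy is any call differing from the
    morphological label (AMBIGUOUS included, with the tied species recorded);
    hybrid evidence additionally requires the prior hybrid suspicion.
    Flags are written back onto the AssignmentResult objects.
    """
    rows = []
    for a in assignments:
        if a.query not in metadata:
            raise KeyError(f"no morphological label for query {a.query!r}")
        morph, suspect = metadata[a.query]
        a.discrepancy = a.called_species != morph
        a.hybrid_evidence = bool(suspect and a.discrepancy)
        rows.append(
            {
                "query": a.query,
                "morphological_species": morph,
                "called_species": a.called_species,
                "tied_species": ";".join(a.tied_species),
                "top_identity": round(a.hits[0].percent_identity, 4) if a.hits else None,
                "hybrid_suspect": suspect,
                "discrepancy": a.discrepancy,
                "hybrid_evidence": a.hybrid_evidence,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PopulationGroup:
    """Named set of haplotypes defined by a species/location combination."""

    name: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"population group {self.name!r} is empty")


def population_table(
    matrix: DistanceMatrix, groups: Sequence[PopulationGroup]
) -> list[GroupSummary]:
    """Mean and range of pairwise distances for every unordered group pair.

    Self-pairs summarise within-group distances (0 for singleton groups);
    cross-pairs summarise all between-member distances. Groups must be
    disjoint and all members present in the matrix.
    """
    seen: dict[str, str] = {}
    for g in groups:
        for m in g.members:
            if m in seen:
                raise ValueError(
                    f"haplotype {m!r} in both {seen[m]!r} and {g.name!r}"
                )
            if m not in matrix.labels:
                raise ValueError(f"group member {m!r} missing from matrix")
            seen[m] = g.name

    out = []
    for g in groups:
        dists = [
            matrix.get(a, b)
            for a, b in itertools.combinations(g.members, 2)
            if not matrix.is_saturated(a, b)
        ]
        out.append(_summary(g.name, g.name, dists))
    for ga, gb in itertools.combinations(groups, 2):
        dists = [
            matrix.get(a, b)
            for a in ga.members
            for b in gb.members
            if not matrix.is_saturated(a, b)
        ]
        out.append(_summary(ga.name, gb.name, dists))
    return out


def population_report(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    """Square layout with a mean line and a range line per group pair."""
    names = list(dict.fromkeys(s.group_a for s in summaries))
    by_pair = {(s.group_a, s.group_b): s for s in summaries}
    rows = []
    for a in names:
        mean_row, range_row = {"population": a}, {"population": ""}
        for b in names:
            s = by_pair.get((a, b)) or by_pair.get((b, a))
            if s is None:
                mean_row[b] = range_row[b] = ""
            else:
                mean_row[b] = f"{s.mean:.4f}"
                range_row[b] = f"{s.min:.4f}-{s.max:.4f}"
        rows.extend([mean_row, range_row])
    return pd.DataFrame(rows)
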