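"""Config-driven end-to-end barcode survey analysis.

One call reads sequences + metadata, trims to the shared region, collapses
haplotypes, computes the K2P matrix and within/between summaries with the
barcoding-gap report, builds the bootstrap-annotated NJ tree, and (when a
reference library is supplied) writes molecular identifications with
discrepancy and hybrid-evidence flags. Outputs are plain TSV/JSON/Newick
files plus a manifest recording the config, seed and package version; on any
error, partial outputs are removed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .assign import ReferenceLibrary, PopulationGroup, flag_discrepancies, identify
from .assign import population_report, population_table
from .distance import barcode_gap, distance_matrix, group_summaries, summaries_to_frame
from .haplotypes import collapse, default_acronyms, name_haplotypes, new_vs_reference
from .haplotypes import table_to_frame
from .io_seq import join_metadata, read_fasta, read_metadata, trim_to_region
from .phylo import bootstrap, write_newick

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    fasta: str
    meta: str
    out_dir: str
    ref_fasta: str | None = None
    ref_meta: str | None = None
    trim_mode: str = "auto"
    trim_start: int | None = None
    trim_end: int | None = None
    group_key: str = "species"
    bootstrap_reps: int = 1000
    seed: int = 42
    min_identity: float = 97.0
    min_overlap: int = 200
    acronym_file: str | None = None
    population_tables: bool = False

    def __post_init__(self) -> None:
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")


def _read_acronyms(path: str) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"species", "acronym"} <= set(table.columns):
        raise ValueError("acronym file needs species and acronym columns")
    return dict(zip(table["species"], table["acronym"]))


def run(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline; returns the map of output names to paths."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, filename: str) -> Path:
        path = out_dir / filename
        written[name] = path
        return path

    try:
        records = join_metadata(read_fasta(config.fasta),
                                read_metadata(config.meta))
        aligned, dropped = trim_to_region(
            records, config.trim_mode, config.trim_start, config.trim_end
        )
        for rec in dropped:
            logger.warning("dropped record %s during trimming", rec.id)

        tables = collapse(aligned, config.group_key)
        species = [t.group_label.rstrip("*").split(" @ ")[0] for t in tables]
        acronyms = (
            _read_acronyms(config.acronym_file)
            if config.acronym_file
            else default_acronyms(dict.fromkeys(species))
        )
        tables = name_haplotypes(tables, acronyms)
        hap_frame = table_to_frame(tables)

        reference = None
        if config.ref_fasta and config.ref_meta:
            reference = ReferenceLibrary.from_files(config.ref_fasta, config.ref_meta)
            novelty = new_vs_reference(tables, reference)
            hap_frame = hap_frame.merge(
                novelty[["species", "haplotype", "new"]],
                on=["species", "haplotype"], how="left",
            )
        hap_frame.to_csv(emit("haplotypes", "haplotypes.tsv"), sep="\t", index=False)

        haps = [h for t in tables for h in t.haplotypes]
        matrix = distance_matrix(haps)
        matrix.to_dataframe().round(4).to_csv(
            emit("distance_matrix", "distance_matrix.tsv"), sep="\t"
        )

        group_map, exclude = {}, set()
        for table in tables:
            for hap in table.haplotypes:
                if table.hybrid_group:
                    exclude.add(hap.name)
                else:
                    group_map[hap.name] = table.group_label
        summaries = group_summaries(matrix, group_map, exclude)
        summaries_to_frame(summaries).to_csv(
            emit("group_summaries", "group_summaries.tsv"), sep="\t", index=False
        )
        within = [s for s in summaries if s.within]
        between = [s for s in summaries if not s.within]
        gap = barcode_gap(within, between) if between else None
        if gap is not None:
            emit("gap_report", "gap_report.json").write_text(
                json.dumps(
                    {
                        "within_range": list(gap.within_range),
                        "between_range": list(gap.between_range),
                        "overlap": gap.overlap,
                        "fold_ratio": (
                            gap.fold_ratio if gap.fold_ratio != float("inf") else "inf"
                        ),
                    },
                    indent=1,
                )
            )

        if len(haps) >= 3:
            result = bootstrap(haps, config.bootstrap_reps, config.seed)
            emit("tree", "tree.nwk").write_text(
                write_newick(result.tree) + "\n"
            )

        if reference is not None:
            assignments = {
                hap.name: identify(
                    hap, reference, config.min_identity, config.min_overlap
                )
                for t in tables
                for hap in t.haplotypes
            }
            sample_rows = []
            by_id = {r.id: r for r in aligned}
            for table in tables:
                for hap in table.haplotypes:
                    for sid in hap.member_ids:
                        rec = by_id[sid]
                        a = assignments[hap.name]
                        sample_rows.append(
                            (a, sid, rec.species_label, rec.hybrid_suspect, hap.name)
                        )
            report = flag_discrepancies(
                [dataclasses.replace(a, query=sid) for a, sid, *_ in sample_rows],
                {sid: (sp, hy) for _, sid, sp, hy, _ in sample_rows},
            )
            report["haplotype"] = [hname for *_, hname in sample_rows]
            report.to_csv(
                emit("assignments", "assignments.tsv"), sep="\t", index=False
            )

        if config.population_tables:
            loc_tables = name_haplotypes(
                collapse(aligned, "species+location"), acronyms
            )
            loc_haps = [h for t in loc_tables for h in t.haplotypes]
            loc_matrix = distance_matrix(loc_haps)
            groups = [
                PopulationGroup(t.group_label, [h.name for h in t.haplotypes])
                for t in loc_tables
            ]
            population_report(population_table(loc_matrix, groups)).to_csv(
                emit("population_table", "population_table.tsv"),
                sep="\t", index=False,
            )

        manifest = {
            "config": dataclasses.asdict(config),
            "seed": config.seed,
            "version": __version__,
            "n_records": len(records),
            "n_dropped_records": len(dropped),
            "outputs": {k: p.name for k, p in written.items()},
        }
        emit("manifest", "manifest.json").write_text(json.dumps(manifest, indent=1))
        return written
    except Exception:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise
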