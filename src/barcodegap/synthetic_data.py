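"""Synthetic barcode surveys with known ground truth.

Generates a multi-species COI-like survey: a random ultrametric species tree
with an ancestral sequence evolved site-wise under the two-parameter
(Kimura) substitution process, per-species haplotype clusters with skewed
frequencies, optional geographic subpopulations carrying their own
haplotypes, planted "hybrid" samples (a donor species' mitochondrial
haplotype under a different morphological label, flagged as suspect) and
planted "reassignment" samples (label A, sequence from species B, not
flagged). Every downstream stage — collapsing, distances, gap, tree,
identification — can thus be checked against construction-time truth.

Site-wise evolution uses the exact two-parameter transition probabilities at
each branch length (multiple hits handled correctly), so the analytic helper
:func:`expected_k2p` is exact: the K2P estimator applied to the expected
transition/transversion proportions returns the branch length itself.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assign import RefEntry, ReferenceLibrary
from .io_seq import SeqRecord

_BASES = "AGCT"  # codes 0..3; transition partner = code ^ 1


@dataclass
class SimConfig:
    """Survey design parameters.

    Defaults emulate a small-lake fish survey: 530-bp barcodes, shallow
    within-species variation (expected 0.002 substitutions/site between a
    minor haplotype and the species' dominant one), species separated on a
    tree of depth 0.15 so species-pair distances span roughly 0.014-0.30,
    and skewed haplotype frequencies (one dominant variant plus singletons).
    """

    n_species: int = 22
    L: int = 530
    kappa: float = 2.0
    within_divergence: float = 0.002
    between_divergence: float = 0.15
    samples_per_species: int | Sequence[int] = 8
    haplotypes_per_species: int | Sequence[int] | None = None
    n_hybrids: int = 0
    n_reassignments: int = 0
    populations: dict[int, list[tuple[str, int, float]]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 100:
            raise ValueError("L must be >= 100")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0 < self.within_divergence < self.between_divergence:
            raise ValueError("need 0 < within_divergence < between_divergence")

    def sample_sizes(self) -> list[int]:
        if isinstance(self.samples_per_species, int):
            return [self.samples_per_species] * self.n_species
        sizes = list(self.samples_per_species)
        if len(sizes) != self.n_species:
            raise ValueError("samples_per_species length != n_species")
        return sizes


@dataclass
class GroundTruth:
    """Construction-time truth emitted alongside the synthetic dataset.

    Hybrid donors and reassignment sources are *reference-only* species:
    they sit on the same species tree and in the reference library but are
    never surveyed under their own name — the way a misidentified or
    introgressed mitochondrial lineage enters a real survey.
    """

    true_tree: str
    species_names: list[str]
    reference_only_species: list[str]
    acronym_map: dict[str, str]
    species_sequences: dict[str, str]  # every leaf, reference-only included
    haplotype_sequences: dict[str, list[str]]
    true_haplotypes: dict[str, str]  # sample id -> "species/hap_index"
    planted_hybrids: dict[str, str]  # sample id -> donor species
    planted_reassignments: dict[str, str]  # sample id -> true source species
    true_pairwise_expected_d: dict[str, float]  # "spA|spB" -> 2 * MRCA height

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _k80_probs(t: float, kappa: float) -> tuple[float, float, float]:
    """(stay, transition, each-transversion) probabilities at branch length t.

    The process is scaled so t is the expected number of substitutions per
    site: transversion rate to each partner beta = 1/(kappa+2), transition
    rate kappa*beta.
    """
    beta = 1.0 / (kappa + 2.0)
    e_tv = math.exp(-4.0 * beta * t)
    e_ts = math.exp(-2.0 * (kappa + 1.0) * beta * t)
    p_tv_each = 0.25 - 0.25 * e_tv
    p_ts = 0.25 + 0.25 * e_tv - 0.5 * e_ts
    p_stay = 1.0 - p_ts - 2.0 * p_tv_each
    return p_stay, p_ts, p_tv_each


def expected_k2p(branch_length: float, kappa: float = 2.0) -> tuple[float, float, float]:
    """Expected (P, Q, d) at a given divergence; d equals branch_length exactly."""
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    if branch_length == 0:
        return 0.0, 0.0, 0.0
    _, p_ts, p_tv_each = _k80_probs(branch_length, kappa)
    P, Q = p_ts, 2.0 * p_tv_each
    d = -0.5 * math.log(1.0 - 2.0 * P - Q) - 0.25 * math.log(1.0 - 2.0 * Q)
    return P, Q, d


def _evolve(codes: np.ndarray, t: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """Evolve a coded sequence for branch length t under the K80 process."""
    if t <= 0:
        return codes.copy()
    p_stay, p_ts, _ = _k80_probs(t, kappa)
    u = rng.random(codes.size)
    out = codes.copy()
    ts_mask = (u >= p_stay) & (u < p_stay + p_ts)
    out[ts_mask] ^= 1
    tv_mask = u >= p_stay + p_ts
    other_class = np.where(codes[tv_mask] < 2, 2, 0)
    out[tv_mask] = other_class + rng.integers(0, 2, size=tv_mask.sum())
    return out


def _mutate_sites(codes: np.ndarray, n_sub: int, kappa: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply n_sub substitutions at distinct random sites (shallow divergence)."""
    out = codes.copy()
    sites = rng.choice(codes.size, size=min(n_sub, codes.size), replace=False)
    for s in sites:
        if rng.random() < kappa / (kappa + 2.0):
            out[s] ^= 1
        else:
            out[s] = (2 if out[s] < 2 else 0) + rng.integers(0, 2)
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def _random_species_tree(n: int, depth: float, rng: np.random.Generator):
    """Random join order, MRCA heights evenly spread up to ``depth``.

    Returns (root node, per-pair MRCA heights). Nodes are (height, children)
    tuples; leaves are (0.0, species_index).
    """
    active: list[tuple] = [(0.0, i) for i in range(n)]
    clades: list[set[int]] = [{i} for i in range(n)]
    heights = {}
    for step in range(1, n):
        h = depth * step / (n - 1)
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        for a in clades[i]:
            for b in clades[j]:
                heights[frozenset((a, b))] = h
        node = (h, [active[i], active[j]])
        merged = clades[i] | clades[j]
        active = [x for k, x in enumerate(active) if k not in (i, j)] + [node]
        clades = [c for k, c in enumerate(clades) if k not in (i, j)] + [merged]
    return active[0], heights


def _tree_newick(node, parent_height: float, names: list[str]) -> str:
    height = node[0]
    length = parent_height - height
    if isinstance(node[1], int):
        return f"{names[node[1]]}:{length:.6f}"
    inner = ",".join(_tree_newick(c, height, names) for c in node[1])
    return f"({inner}):{length:.6f}"


def _leaf_sequences(node, seq: np.ndarray, parent_height: float, kappa: float,
                    rng: np.random.Generator, out: dict[int, np.ndarray]) -> None:
    height = node[0]
    evolved = _evolve(seq, parent_height - height, kappa, rng)
    if isinstance(node[1], int):
        out[node[1]] = evolved
    else:
        for child in node[1]:
            _leaf_sequences(child, evolved, height, kappa, rng, out)


def _haplotype_counts(n_samples: int, k: int) -> list[int]:
    # skewed: one dominant haplotype, the rest singletons
    k = max(1, min(k, n_samples))
    return [n_samples - k + 1] + [1] * (k - 1)


def _distinct_variant(base: np.ndarray, existing: list[np.ndarray], lam: float,
                      kappa: float, rng: np.random.Generator) -> np.ndarray:
    for _ in range(100):
        m = max(1, int(rng.poisson(lam)))
        var = _mutate_sites(base, m, kappa, rng)
        if not any(np.array_equal(var, e) for e in existing):
            return var
    raise RuntimeError("could not generate a distinct haplotype variant")


def simulate(config: SimConfig) -> tuple[list[SeqRecord], pd.DataFrame, GroundTruth]:
    """Generate (records, metadata table, ground truth) for a survey config.

    Fully reproducible from ``config.seed``; the metadata table uses the same
    TSV dialect the I/O layer reads (id, species, location, hybrid_suspect).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_species
    sizes = config.sample_sizes()

    if config.haplotypes_per_species is None:
        hap_k = [int(min(1 + rng.poisson(0.8), 4, sizes[i])) for i in range(n)]
    elif isinstance(config.haplotypes_per_species, int):
        hap_k = [min(config.haplotypes_per_species, sizes[i]) for i in range(n)]
    else:
        hap_k = list(config.haplotypes_per_species)
        if len(hap_k) != n:
            raise ValueError("haplotypes_per_species length != n_species")
        if any(k > s for k, s in zip(hap_k, sizes)):
            raise ValueError("more haplotypes than samples for some species")

    # donors for planted hybrids/reassignments are extra leaves on the same
    # tree, present in the reference library but never surveyed themselves
    n_donors = config.n_hybrids + config.n_reassignments
    if config.n_reassignments > n:
        raise ValueError("more reassignments than species")
    names = [f"species{i + 1:02d}" for i in range(n)]
    donor_names = [f"refspecies{i + 1:02d}" for i in range(n_donors)]
    all_names = names + donor_names
    acronyms = {name: f"s{i + 1:02d}" for i, name in enumerate(names)}

    root_node, mrca_heights = _random_species_tree(
        n + n_donors, config.between_divergence, rng
    )
    ancestral = rng.integers(0, 4, size=config.L)
    leaf_codes: dict[int, np.ndarray] = {}
    _leaf_sequences(root_node, ancestral, config.between_divergence,
                    config.kappa, rng, leaf_codes)

    # each reassigned species' whole cluster descends from its donor's leaf
    reassigned = {
        int(idx): n + config.n_hybrids + r
        for r, idx in enumerate(
            rng.choice(n, size=config.n_reassignments, replace=False)
        )
    }

    lam = config.L * config.within_divergence
    pops = config.populations or {}
    records: list[SeqRecord] = []
    meta_rows: list[dict] = []
    truth_haps: dict[str, str] = {}
    hap_seqs: dict[str, list[str]] = {}
    planted_reassignments: dict[str, str] = {}

    def add_sample(sid, species, location, suspect, codes):
        records.append(SeqRecord(id=sid, sequence=_decode(codes)))
        meta_rows.append(
            {"id": sid, "species": species, "location": location,
             "hybrid_suspect": "yes" if suspect else "no"}
        )

    for i, name in enumerate(names):
        rep = leaf_codes[reassigned[i]] if i in reassigned else leaf_codes[i]
        if i in pops:
            variants = [rep]
            counter = 0
            for p_idx, (loc, n_loc, extra) in enumerate(pops[i]):
                if p_idx == 0:
                    codes = rep
                else:
                    codes = _distinct_variant(
                        rep, variants, config.L * extra, config.kappa, rng
                    )
                    variants.append(codes)
                for _ in range(n_loc):
                    counter += 1
                    sid = f"{acronyms[name]}_{counter:03d}"
                    add_sample(sid, name, loc, False, codes)
                    truth_haps[sid] = f"{name}/{p_idx}"
                    if i in reassigned:
                        planted_reassignments[sid] = all_names[reassigned[i]]
            hap_seqs[name] = [_decode(v) for v in variants]
        else:
            variants = [rep]
            for _ in range(hap_k[i] - 1):
                variants.append(
                    _distinct_variant(rep, variants, lam, config.kappa, rng)
                )
            counts = _haplotype_counts(sizes[i], len(variants))
            counter = 0
            for h_idx, (codes, c) in enumerate(zip(variants, counts)):
                for _ in range(c):
                    counter += 1
                    sid = f"{acronyms[name]}_{counter:03d}"
                    add_sample(sid, name, "Lake", False, codes)
                    truth_haps[sid] = f"{name}/{h_idx}"
                    if i in reassigned:
                        planted_reassignments[sid] = all_names[reassigned[i]]
            hap_seqs[name] = [_decode(v) for v in variants]

    planted_hybrids: dict[str, str] = {}
    for h in range(config.n_hybrids):
        recipient = int(rng.integers(0, n))
        donor = n + h
        sid = f"hyb_{h + 1:02d}"
        add_sample(sid, names[recipient], "Lake", True, leaf_codes[donor])
        planted_hybrids[sid] = all_names[donor]

    truth = GroundTruth(
        true_tree=_tree_newick(root_node, config.between_divergence, all_names) + ";",
        species_names=names,
        reference_only_species=donor_names,
        acronym_map=acronyms,
        species_sequences={
            name: _decode(leaf_codes[i]) for i, name in enumerate(all_names)
        },
        haplotype_sequences=hap_seqs,
        true_haplotypes=truth_haps,
        planted_hybrids=planted_hybrids,
        planted_reassignments=planted_reassignments,
        true_pairwise_expected_d={
            f"{all_names[min(a, b)]}|{all_names[max(a, b)]}": 2.0 * h
            for pair, h in mrca_heights.items()
            for a, b in [sorted(pair)]
        },
    )
    return records, pd.DataFrame(meta_rows), truth


def reference_from_truth(
    truth: GroundTruth, all_haplotypes: bool = False
) -> ReferenceLibrary:
    """Build a synthetic reference library from ground truth.

    By default one entry per species (its dominant haplotype); with
    ``all_haplotypes`` every observed haplotype of every surveyed species is
    included. Reference-only donor species always contribute their single
    true sequence.
    """
    entries = []
    for species in truth.species_names + truth.reference_only_species:
        seqs = (
            truth.haplotype_sequences.get(
                species, [truth.species_sequences[species]]
            )
            if all_haplotypes
            else [truth.species_sequences[species]]
        )
        for k, seq in enumerate(seqs):
            entries.append(
                RefEntry(
                    id=f"ref_{species}_{k}",
                    sequence=seq,
                    species=species,
                    source_tag="synthetic-reference",
                )
            )
    return ReferenceLibrary(entries)


def galilee_survey_config(seed: int = 0, n_hybrids: int = 2,
                          n_reassignments: int = 1) -> SimConfig:
    """A 22-species survey sized like the study lake's sample and haplotype
    counts (sample sizes 1-23, one to four haplotypes per species)."""
    sizes = [5, 8, 7, 7, 5, 5, 14, 2, 11, 23, 1, 3, 3, 1, 8, 7, 9, 9, 8, 6, 21, 7]
    haps = [1, 4, 2, 2, 3, 1, 4, 1, 2, 2, 1, 2, 1, 1, 2, 1, 2, 3, 1, 2, 1, 1]
    return SimConfig(
        n_species=22,
        samples_per_species=sizes,
        haplotypes_per_species=haps,
        n_hybrids=n_hybrids,
        n_reassignments=n_reassignments,
        seed=seed,
    )
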