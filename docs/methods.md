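# Methods

## Scope and data model

The package analyses a single-locus barcode survey: every sample carries a
unique id, a morphological species label, a sampling location, a
hybrid-suspect flag, and a DNA sequence over the IUPAC alphabet
(uppercased, `U`→`T`). All distance work happens on an *aligned set* — every
sequence cut to one shared window. Trimming is either explicit (0-based
half-open `[start, end)`; reports print 1-based inclusive) or automatic (the
longest contiguous block of columns covered by a non-gap, non-`N` base in
every sequence). COI barcodes are protein-coding and effectively indel-free,
so in-window gaps are tolerated only in explicit mode and handled downstream
by pairwise deletion.

## Haplotype collapsing

Within each group (species, or species+location), sequences identical over
all unambiguous bases are one haplotype. A sequence containing ambiguity
codes joins an existing haplotype only when its IUPAC sets intersect the
haplotype's bases at every position for *exactly one* candidate; otherwise
it becomes its own haplotype flagged `ambiguous_only`. This deterministic
rule replaces the manual curation of chromatograms that field studies
apply. Haplotypes are ordered by descending count with ties broken by first
appearance in input order (reproducibility), and named acronym + `A`,`B`,…
(`AA`,`AB`,… past 26). Samples flagged as suspected hybrids are collapsed
in a parallel group — label and haplotype names suffixed `*` — and excluded
from all species-level distance averages, because a hybrid's mitochondrial
barcode reflects only its maternal lineage and would inflate within-species
variation.

## Distances and the barcoding gap

K2P distances use pairwise deletion (sites with a gap or ambiguity code in
either sequence are skipped) and the transition/transversion split
`d = -½ln(1-2P-Q) - ¼ln(1-2Q)`. A non-positive log argument marks the pair
saturated; saturated pairs are flagged, logged, and excluded from all means
— never silently truncated. Group summaries are **unweighted means over
haplotype pairs**: haplotype frequencies and per-sample weighting never
enter, matching the convention of averaging pairwise haplotype distances.
A single-haplotype group reports within-distance 0 with zero pairs. The gap
report pools ranges across groups; `fold_ratio` is the mean of
between-group means over the mean of within-group means (∞ when all
within-means are 0). Reports round to 4 decimals; tests compare unrounded
values.

## Neighbor-joining and bootstrap

NJ minimises `S(i,j) = (m-2)d(i,j) - Σ_k d(i,k) - Σ_k d(j,k)` at each step,
with two determinism contracts: ties in `S` are broken by the
lexicographically smallest label pair (internal nodes keyed by the smallest
leaf beneath them), and a negative limb length is clamped to zero with the
deficit added to its sibling so the pair's path length is preserved. On
exactly additive matrices the output reproduces the generating tree's
topology and path lengths to 1e-10 (property-tested against an exhaustive
least-squares topology search at 4–5 leaves and against an independent NJ
implementation).

Bootstrap support follows the column-resampling procedure: each replicate
draws L alignment columns with replacement from the haplotype sequences
(one seeded generator per run), recomputes the K2P matrix and NJ tree, and
support is the fraction of retained replicates containing a bipartition.
Replicates hitting a saturated pair are dropped and logged; more than 10%
dropped aborts the run. The reported tree is the original-data NJ tree
annotated with these supports — the standard presentation when a published
figure does not state which replicate tree it shows. Newick output writes
branch lengths (6 decimals by default) and integer percent supports as
internal node labels.

## Reference-based identification

A local reference library (FASTA + taxonomy TSV) stands in for an online
barcode database; no live queries are made. Percent identity is
`100·matches/compared` over pairwise-deleted sites of the shared region
(≥200 sites required; configurable). Hits keep the best identity per
species, ranked descending; the default screen is 97% identity, a
conventional barcoding threshold, configurable because no universal value
exists. Two or more species tying at 4-decimal identity yield an
`AMBIGUOUS` call with the tied species listed, rather than an arbitrary
winner — mirroring how co-equal database hits are reported. A call
differing from the morphological label is a *discrepancy* (a congeneric
call still counts, and an `AMBIGUOUS` call counts, since either disagrees
with the morphological determination); *hybrid evidence* additionally
requires the prior morphological hybrid suspicion. Population tables give
mean and (min, max) of cross-pair distances for every unordered pair of
user-defined haplotype groups, with singleton self-pairs reported as 0.

## Synthetic surveys

The generator emulates a regional multi-species barcode survey:

| parameter | default | meaning |
|---|---|---|
| `L` | 530 bp | analysis-window length |
| `kappa` | 2.0 | transition/transversion rate ratio |
| `within_divergence` | 0.002 subs/site | expected minor-variant distance from the dominant haplotype |
| `between_divergence` | 0.15 subs/site | species-tree depth; pairwise species distances span ≈2·depth/(n−1) to 2·depth |
| `samples_per_species` | 8 (or per-species list) | survey size |
| haplotype counts | skewed `(n−k+1, 1, …, 1)` | one dominant variant plus singletons |

Species sit on a random-join ultrametric tree whose merge heights are
evenly spread up to the depth, so a 25-leaf default survey shows species
pairs from ≈0.012 to 0.30 substitutions/site — the shape of a real
single-lake community with both congeneric and deep family-level splits.
The ancestral sequence (uniform base composition, as the two-parameter
model assumes) evolves **site-wise with the exact two-parameter transition
probabilities**, not by discrete mutation counts, so multiple hits are
handled correctly at deep divergences and the analytic helper
`expected_k2p` is exact: applying the K2P formula to the expected (P, Q) at
branch length t returns t identically. Within species, minor haplotypes add
Poisson(L·within_divergence) substitutions (≥1, resampled until distinct)
to the dominant variant — adequate at shallow divergence where multiple
hits are negligible.

Planted anomalies use **reference-only donor species**: extra leaves on the
same tree that appear in the reference library but are never surveyed under
their own name, the way a misidentified or introgressed lineage enters a
real survey. A *hybrid* is an extra sample carrying a donor's sequence
under a surveyed species' label with the suspect flag set; a *reassignment*
re-roots one surveyed species' whole haplotype cluster on a donor's leaf
(every sample of that species keeps the wrong label, unflagged). A
`galilee_survey_config` preset reproduces a 22-species lake survey design
(per-species sample sizes 1–23, one to four haplotypes each).

What the generator does **not** emulate: sequencing error, indels,
alignment uncertainty, heterogeneous base composition, rate variation
across sites, and within-species phylogeographic structure beyond the
optional per-location haplotype split. Passing recovery tests therefore
shows the pipeline's arithmetic and bookkeeping are right under the model's
own assumptions, not that real chromatogram-derived data are this clean.

## Numerical choices and edge cases

- Saturation sentinel: NaN distance + flag, checked before NJ (which
  refuses saturated matrices rather than guessing).
- `-0.0` branch lengths are normalised to `+0.0` before serialisation.
- Frequencies and distances print at 4 decimals; identity ties are judged
  at 4 decimals.
- Empty groups are omitted, not errors; records too short for an explicit
  trim window are dropped with a logged warning and returned to the caller.
- Determinism: every stochastic step (simulation, bootstrap) consumes a
  single seeded NumPy generator; reruns with the same seed are
  byte-identical, and the run manifest records seed, config and version.

## Problem sizes in the shipped tests

The suite exercises: exact spot checks at 530 bp; estimator recovery at
L=100 000 and across 200 replicates of L=530; NJ recovery for 4–12 leaves
with exhaustive topology search at 4–5; bootstrap with B=100 on two planted
4-leaf clades; and one full 22-species survey (≈170 samples) through the
entire pipeline. These sizes keep the whole suite under a few seconds while
leaving every code path covered at realistic barcode dimensions.

## Known limitations

- K2P only; no gamma rate variation, no GTR, no distance variances.
- NJ only; no likelihood or Bayesian trees, no consensus trees.
- Identification is exact-overlap percent identity, not a model-corrected
  score, and assumes query and reference share the same locus coordinates
  (shared-prefix comparison after trimming).
- The `fold_ratio` is a summary of means, not a hypothesis test for the
  gap.
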