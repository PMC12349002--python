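# Methods

This note defines the algorithms and statistics implemented in `karyoforge`,
in the order the pipeline applies them. Default parameter values are given in
parentheses; all are exposed as function or CLI arguments.

## 1. Coordinates: gene-rank space

All synteny work happens in gene order, not base pairs. A `GeneTable` sorts
gene models by `(chromosome, start, gene_id)` and assigns each gene a *rank*,
0-based and consecutive per chromosome. Ranks are robust to assembly-scale
differences in intergenic content, which dominate genomes with large
repeat loads. Base-pair coordinates are kept alongside for interval
statistics (TE composition) only. Inputs are GFF3 (`gene` features; parsing
stops at a `##FASTA` section) or BED; gene models on sequences outside an
optional chromosome list (scaffolds) are dropped and counted.

## 2. Homology filtering

Aligner tabular hits (12-column outfmt-6 style) are filtered by E-value
(≤ 1e-5) and a per-query best-hit cap (top 5 by bitscore; ties with the 5th
best are all kept so the result does not depend on input order). Exact
(query, subject) duplicates collapse to their best-scoring line.

## 3. Anchors and block chaining

Each surviving homologous pair whose two genes are present in the two gene
tables becomes an *anchor* — the point `(rank_a, rank_b)` on the dot plot of
one chromosome pair. Per chromosome pair, blocks are extracted by iterated
best-chain dynamic programming:

- a legal chain is strictly increasing in `rank_a` and strictly monotone in
  `rank_b` (increasing for "+" blocks, decreasing for "−");
- consecutive anchors are at most `max_gap` (25) ranks apart on both axes;
- the chain score is its anchor count; the best chain is removed and
  extraction repeats while the best score is ≥ `min_pairs` (5).

Ties are broken by smaller `rank_a` span, then smaller starting `rank_a`,
then "+" orientation, making the output deterministic. In self-comparisons
(`self_mode`) blocks that are ≥ 90% identity-diagonal are discarded. The DP
is validated against an exhaustive longest-chain oracle on random instances.

## 4. Chromosome homology classes

For each chromosome pair with blocks, coverage is the fraction of a
chromosome's genes inside the union of the blocks' rank spans. The pair is
called:

- **whole** — reciprocal coverage ≥ θ_whole (0.6) both ways *and* each
  chromosome is the other's best-covered partner;
- **arm** (optional, requires centromere ranks) — the shared material is
  concentrated (≥ θ_arm of the arm, and ≥ θ_arm of all shared coverage)
  within one arm of either chromosome;
- **segmental** — any block survives;
- otherwise the pair is unrelated.

## 5. Two-round ancestral reconstruction

**Round 1 (seeds).** The graph whose edges are all whole-chromosome
relations is split into connected components; each component seeds one
proto-chromosome with its member chromosomes (full rank span) as candidate
segments. A component drawing more than two chromosomes from one species is
a hard error — two are allowed so both homoeologous copies left by a
whole-genome duplication can join their proto.

**Round 2 (residuals).** Every chromosome not in a seed is tested against
every proto: its evidence is the set of its anchors landing inside the
proto's candidate segments of *other* species. If the supporting species
(including the residual's own) number ≥ `min_species` (3), the hull of the
evidence ranks becomes a new candidate segment. Non-overlapping hulls let a
fusion or translocation product split across several protos; hulls
overlapping an already-claimed interval by more than 20% are a conflict and
stay unassigned. Chromosomes assigned nowhere are grouped by mutual
collinearity, and a group spanning ≥ `min_species` species founds a new
proto. Partial protos are merged when ≥ 2 species each carry a chromosome
linked to both and no third proto contradicts the union.

**Representatives.** Within a proto, candidate segments are grouped into
homologous regions (connected components of block-linked segments). Each
region is represented by the candidate with the most distinct
anchor-supported genes — absolute coverage of the region, with
continuity (coverage / rank span) breaking ties. Coverage must be the
primary criterion: a scale-free density ratio would let a short, fully
anchored translocation fragment outrank an intact chromosome and leave the
region effectively unrepresented. The winner is trimmed to the hull of its
anchors into the region, so a fusion chromosome contributes only its
homologous part. Protos are named `AGK1, AGK2, …` by descending gene count,
and their representative segments are materialised as an ancestral gene
table (one chromosome per proto) for painting.

## 6. Karyotype painting

The ancestral gene table is chained against a target genome exactly like any
genome pair (each ancestral gene inherits the homology hits of its source
gene). Every target gene inside a block's rank span takes the block's
proto-chromosome; where blocks overlap, the larger block wins. Runs of
fewer than 3 genes disagreeing with identical neighbours are then absorbed
by majority vote within a centred 30-gene window (up to 5 passes). Genes in
no block stay unpainted (`NA`). The pre-smoothing assignment is retained as
per-gene support.

## 7. Block statistics

- **Collinearity degree** — total gene pairs / block count for one
  comparison; compared across comparisons with a one-way ANOVA (classical F
  and p via the F distribution, plus a label-permutation p with the +1
  Monte-Carlo correction). All-identical values give F = 0, p = 1.
- **Syntenic depth** — per reference gene, the number of blocks whose span
  contains it; the mode of the nonzero depths is reported as `mode:1`. A
  2:1 mode against a putative ancestor is the single-WGD signature and
  is robust to substantial post-WGD gene loss, because block spans bridge
  scattered deletions shorter than `max_gap`.
- **Arm randomization test** — under the null, each of `n` blocks lands on
  arm *a* with probability proportional to arm length. The statistic is
  `Σ (obs − exp)² / exp`; p is Monte-Carlo with the +1 correction
  (`(1 + #{sim ≥ obs}) / (n_sim + 1)`), so it is never exactly zero. The
  test's null calibration (uniform p-values, nominal type-I error) is
  checked by simulation.
- **TE composition** — per block (bp span from first to last anchor gene)
  and its two 30-gene flanks, the percent of span covered by each TE class
  (Copia, Gypsy, LINE1, Other; labels normalised from free-text annotations).
  Same-class intervals are merged before measuring so overlaps never double
  count; flanks truncated at chromosome ends are flagged. A span-weighted
  block-vs-flank contrast summarises enrichment.

## 8. Forward simulator

An ancestor of `n_protos` (12) chromosomes with 200–500 genes each evolves
independently along each branch of a star tree. Per branch, in fixed order:
optional whole-genome duplication (every chromosome duplicated, second
copies marked as subgenome 2), reciprocal translocations, fissions, fusions,
inversions (counts per branch), then per-gene loss (probability
`loss_fraction`, optionally biased toward subgenome 2) and gene gain
(`gain_fraction` of the gene count, inserted uniformly, with no ancestral
origin). Every event is logged with its full parameters; replaying the log
from the stored ancestor must reproduce the emitted gene tables exactly,
which is tested.

Gene identifiers encode nothing about ancestry. Homology tables are derived
from shared ancestral origins with noise: each true pair is dropped with
probability `p_missing` (0.05) and spurious uniform pairs are added at rate
`p_spurious` (0.05) of the true count, with E-values sampled to survive the
standard filter; self-comparisons always keep perfect identity hits. TE
intervals are scattered per class by Poisson intensities; designated rank
windows (kept clear of chromosome ends and of each other) can receive a
LINE1 intensity multiplier to create a known block-vs-flank contrast.

## 9. Recovery scoring

Inferred paintings are compared with the truth over all genes with an
ancestral origin. Inferred proto labels are matched to true protos by a
maximum-agreement assignment on the contingency table (Hungarian algorithm);
reported are painting accuracy (among painted genes), overall accuracy
(unpainted counts as wrong), the unpainted fraction, and the adjusted Rand
index of the two partitions (label-free agreement).

## Limitations

- A proto-chromosome intact in no descendant cannot be seeded from
  whole-chromosome conservation and is lost; its genes stay unpainted.
- Centromere positions are inputs, never inferred; arm-level relations and
  the arm test are only available where they are supplied.
- The simulator's star tree has no shared internal branches, so convergent
  rearrangements across species are rarer than on a realistic phylogeny;
  recovery figures should be read in that light.
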