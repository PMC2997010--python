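# Methods

## Block semantics

Detection operates on gene order, not sequence. Within each chromosome,
genes are totally ordered by `(start, end, gene_id)`; the tie-break is a
package convention so that any permutation of input rows reads to an
identical genome. Coordinates are 1-based inclusive throughout (GFF3
convention); BED output converts at the boundary.

A candidate block is an interval pair; its genes partition into matched,
in-map-mismatch and out-map-mismatch sets as defined in the README. The
order/strand condition is decided exactly, including one-to-many
orthology: writing the matched genes of the two intervals as the rows and
columns of a bipartite matrix whose cells are correspondence pairs (with
the required strand relation), a covering selection with no order
inversion exists iff a staircase lattice path (steps right, down,
diagonal) runs from the first cell to the last touching only
correspondence cells. Ties in either coordinate realize tandem
co-orthologs: several adjacent genes sharing one partner join a block
without contributing order information beyond their run. This check is an
O(rows x cols) dynamic program in the production path and an independent
memoized top-down search in the oracle; a third, purely enumerative
check over all pair subsets backs both on tiny candidates in the unit
tests.

Mismatch caps: each side of a block must satisfy the absolute cap *and*
the percentage cap for each mismatch kind. The percentage denominator is
that side's total interval gene count — with caps `i%` and interval size
`n`, at most `floor(i/100 * n)` mismatches are allowed. Both caps of a
kind must hold on both sides. `min_size`/`max_size` count matched genes,
not interval genes.

Maximality: the reported set is the valid candidates for which no
one-gene extension of either interval (four directions) is valid, minus
candidates whose both intervals are contained in another such candidate's
intervals. One-sided containment with a disjoint partner interval is kept
and flagged *nested* (parent = the containing block with the most matched
genes; ties broken by block id). Overlapping maximal blocks are all
reported; coverage accounting uses span unions, so nothing is counted
twice. Blocks never span chromosome boundaries. Detection is fully
deterministic; output is ordered by A-chromosome, A-start, then
descending interval size.

The search prunes without changing semantics: chromosome pairs without
enough anchors are skipped; an A-interval stops growing once its
unavoidable mismatches (out-map genes; in-map genes with no partner on
the target chromosome) exceed the absolute caps; partner intervals are
enumerated inside the anchor image padded by the total admissible
mismatch count, with exact O(1) prefix-sum checks on the B side and a
single-partner-anchor lower bound on the A side gating the full check.
When an absolute cap is unset and only percentage caps bind, the padding
falls back to the whole chromosome (correctness over speed). Practical
scale is thousands of genes; beyond that is out of scope.

## Analytics

*Coverage* is the union of block spans divided by chromosome length
(default length proxy: largest gene end; a lengths table overrides),
totals length-weighted. Degenerate single-gene "blocks" for uncovered
in-map genes can be included; by construction they can only raise
coverage. *Size statistics* are computed on A-genome spans (the genome
the study reports on); gene counts are matched genes. *Distribution
matrices* count non-nested and nested blocks separately per chromosome
pair, with margins and a homologous-cell fraction under a configurable
chromosome homology map (default: equal names).

*Mann-Whitney U* (two-sided) uses the exact null for tie-free samples
with both n <= 20 and the tie-corrected normal approximation otherwise;
the two branches agree within 0.01 at the crossover (asserted in tests).
Group selectors are arbitrary predicates over blocks, which covers the
sex-chromosome-versus-autosome and arm-versus-center comparisons; blocks
are assigned to arm/center regions by the A-side midpoint.

*Random breakage*: the null places the observed number of segments
(k - 1 uniform breakpoints) on the concatenated genome; the p-value of a
block span is the fraction of replicates whose **largest** segment
reaches that span, with +1 pseudo-counts. All spans of a run share one
null sample, so a genome-wide screen costs one simulation. Adjustment is
Benjamini-Hochberg by default (Bonferroni by flag). Calibration is
asserted: segmentations generated by the null survive BH screening at
alpha = 0.05 in >= 94% of runs, and a planted 30%-of-genome block among
100 segments is rejected far below 0.01 (closed form ~ 100 x 0.7^99).

## Operons and tandems

A *conserved operon* is one whose members are all matched genes of a
single block — an operational definition chosen because published
conservation figures derive from external studies; a user-supplied
conserved-operon list can replace it. An *operonic block* has at least
half (boundary included) of its A-interval genes — mismatches in the
denominator — in conserved operons. Tandem asymmetries are connected
components of the within-block correspondence whose sides have unequal
counts and are adjacency-contiguous on both sides; interleaved ("loose")
components are reported only on request.

## Annotation refinement

Out-map mismatches inside blocks localize missing or defective gene
models: the block's partner interval is the prediction search space. The
package consumes prediction records from any external spliced aligner
(running one is deliberately out of scope — the contribution is the
decision procedure) and filters them by the published criteria: at least
60% query-protein coverage, inclusive, and no internal stop codons.

Classification of a filtered prediction against the target annotation:

- overlaps nothing → **new gene**;
- overlaps one out-map model → **replace** if the prediction covers its
  query at least as well as the model's own support, else discard;
- overlaps one in-map model: if the prediction covers >= 90% of the model
  it is the same locus → discard as redundant. A partial hit indicates a
  chimeric (fused) model: **split** into the predicted piece and the
  remainder (pieces under 50 bp are not viable and the action is
  discarded; overlapping reciprocal re-predictions also discard). If the
  hit model lies in the genome declared *trusted*, the defect is instead
  on the query side: the query gene is **merged** with the hit model's
  adjacent ortholog;
- overlaps two adjacent models → **merge** them into one;
- anything else → discard with the reason.

The redundancy gate defaults to 0.9 rather than reusing the 60% filter
threshold: gene lengths are broadly distributed, so one true gene of a
fused pair routinely covers well over 60% of the chimeric model, and a
0.6 gate would discard a large share of genuinely defective models; 90%
coverage is the level at which prediction and model plausibly describe
the same locus. It is configurable (`RefinementConfig.redundancy_threshold`).

Trust asymmetry: a genome may be declared trusted (e.g. a deeply curated
reference); its existing models are never rewritten — predictions
implicating them either drive actions on the draft side or are
discarded. New genes are admissible in either genome.

`apply_actions` enforces that no model is touched twice, mints new ids
under a configurable prefix, and maintains the bookkeeping identity
initial − deleted + added = final, tallied per action kind in the shape
of a curation summary table. New ortholog pairs are accepted at
PID >= 40% and e-value <= 1e-10, both inclusive; PID is global
Needleman-Wunsch percent identity (BLOSUM62, gap open −10, extend −0.5;
identities / alignment columns, best over co-optimal alignments) and
e-values are always aligner-supplied, never recomputed.

## Simulator

The generator emulates the shape of the real inputs at a compact,
nematode-like scale: lognormal gene lengths (mean 3 kb, sigma 0.8 on the
log scale) and intergenic gaps (mean 2 kb, sigma 1.0), i.e. about one
gene per 5 kb, random strands — all configurable. A rearrangement script
(inversions, transpositions, deletions, insertions, tandem and segmental
duplications, reciprocal translocations) is applied sequentially to the
ancestor's gene order; the derived genome gets fresh coordinates with
inherited gene lengths, and the induced correspondence makes duplications
one-to-many and indels out-map.

The truth ledger is derived by an independent scan of the derived gene
order (maximal runs of source-consecutive genes with uniform strand
relation; nested = ancestor-interval containment), not by running the
detector. Random scripts keep every operation's footprint, plus a
two-gene buffer, disjoint from all others ("spacing beyond merging
reach"); under that guarantee strict detection must equal the ledger
exactly, which the suite asserts across operation mixes and seeds.
Annotation defects are injected as: fusion of two adjacent one-to-one
models (the chimera keeps the longer half's orthology, as a best-hit
orthology caller would); fission of one model into two fragments with
orthology severed entirely (neither fragment would survive a
reciprocal-best-hit call); and dropped ortholog pairs. Each defect
records its expected corrective action (split / merge / replace), and
noiseless prediction records (full query coverage, true target locus)
are fabricated from the ledger for testing the classifier.

What the simulator does **not** emulate: nucleotide sequence, gene
structure (exons), gene-family birth-death dynamics, noisy orthology
inference, or assembly artifacts. Passing tests therefore demonstrate
algorithmic correctness under the stated model, not robustness to the
error modes of real annotations and real ortholog callers.

## Problem sizes in the test suite

The randomized suites use instances the exhaustive oracle can verify:
oracle-equivalence runs 200 instances up to 30 genes per genome over
mismatch caps 0–3 and 0–50% in all three modes; planted-truth recovery
uses two chromosomes of 50 genes with six spaced operations across
twelve seeds; calibration suites use 50 seeds at 1,500–10,000 null
replicates. These sizes are chosen so every expected value is
independently checkable; the detector itself has no scale-dependent
logic.

## Known limitations

- Only pairwise (two-genome) detection; multi-genome analysis is out of
  scope.
- The search is exact but enumerative; percentage-only mismatch caps
  disable window pruning and can be slow on large chromosomes.
- The split/merge branches act on whole spans; exon-level model surgery
  is left to the upstream predictor.
- The random-breakage null conditions on the observed block count and
  tests only the maximal-segment statistic.
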