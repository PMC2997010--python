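# syntenyscan

Anchor-based synteny block detection between two gene-order genomes, with
the downstream analyses a comparative-genomics study needs: coverage and
size tables, chromosome-distribution matrices, rank tests, random-breakage
significance, operonic-block and tandem-cluster classification, a
synteny-guided annotation-refinement engine, and a genome-rearrangement
simulator with provable planted ground truth.

## Who this is for

Comparative genomicists working with pairs of annotated genomes — e.g. a
well-curated reference (such as *Caenorhabditis elegans*) and a draft
sister genome (*C. briggsae*) — who want to (1) find all maximal synteny
blocks given an ortholog table, (2) characterize them statistically, and
(3) exploit breaks in synteny to find and repair defective gene models.

## The model

Genes are anchors. Given genomes *G1*, *G2* (per gene: chromosome, start,
end, strand) and a correspondence file of ortholog pairs (one-to-many
allowed), a gene is **in-map** if it has at least one ortholog in the other
genome and **out-map** otherwise. A *candidate block* is a pair of
contiguous gene intervals, one per genome. Each interval's genes partition
into matched genes (an ortholog inside the partner interval), **in-map
mismatches** (orthologs exist but all lie elsewhere) and **out-map
mismatches** (no ortholog at all). A candidate is **valid** when

1. matched gene counts on both sides lie within `[min_size, max_size]`
   (default: at least 2);
2. per side, in-map and out-map mismatch counts respect both an absolute
   cap (`-i`, `-o`) and a percentage-of-interval cap (`-ip`, `-op`);
3. a system of matched pairs covering every matched gene on both sides
   satisfies the order/strand mode:
   - `rs` — colinear order with consistent strands, or inverted order with
     reversed strands (the signature of a true inversion);
   - `r_s` — all four order × strand combinations, uniform per block;
   - `free` — gene content only.

A **perfect block** (the defaults: zero mismatches, mode `rs`, ≥ 2 genes)
conserves content, order and strandedness exactly; an **imperfect block**
tolerates configurable interruption. Reported blocks are the valid
candidates that are *maximal*: no one-gene extension of either interval is
valid, and no block has both intervals inside another's. A block whose
interval in one genome sits inside a larger block's interval while its
partner interval lies elsewhere is **nested** — the signature of a
segmental duplication — and is reported with its parent.

An independent exhaustive oracle (`enumerate_blocks_oracle`) re-derives the
same semantics by brute force; the test suite holds the production search
to exact agreement with it on hundreds of randomized instances.

## Worked example

Nine consecutive genes on chromosome III with one-to-one orthologs in
identical order; the ortholog of gene 6 is strand-inverted. Strict
perfect-block detection splits the region in two; relaxing order/strand
constraints merges it:

```python
from syntenyscan.model import (CorrespondenceMap, DetectionParams,
                               GeneMarker, Genome, Mode)
from syntenyscan.detection import find_synteny_blocks

genes_a, genes_b, pairs = [], [], []
for i in range(9):
    strand_b = "-" if i == 5 else "+"      # gene 6 inverted in genome B
    genes_a.append(GeneMarker(f"ce_{i+1}", "chrIII", 2000*i+100, 2000*i+1500, "+"))
    genes_b.append(GeneMarker(f"cb_{i+1}", "chrIII", 2000*i+100, 2000*i+1500, strand_b))
    pairs.append((f"ce_{i+1}", f"cb_{i+1}"))
ce, cb = Genome("celegans", genes_a), Genome("cbriggsae", genes_b)
corr = CorrespondenceMap(pairs)

for b in find_synteny_blocks(ce, cb, corr, DetectionParams()):
    print(b.block_id, b.size_genes, b.orientation, b.strand_pattern,
          f"{b.interval_a.chrom}:{b.interval_a.start_bp}-{b.interval_a.end_bp}")
for b in find_synteny_blocks(ce, cb, corr, DetectionParams(mode=Mode.FREE)):
    print(b.block_id, b.size_genes, b.orientation, b.strand_pattern)
```

prints

```
SB00001 5 colinear consistent chrIII:100-9500
SB00002 3 colinear consistent chrIII:12100-17500
SB00001 9 unordered mixed
```

— two perfect blocks of 5 and 3 genes separated by the strand-flipped
gene (which belongs to neither), and a single 9-gene block once
strandedness is allowed to vary.

The same run from the shell:

```sh
syntenyscan detect --genome-a ce.tsv --genome-b cb.tsv --corr orthologs.tsv \
    --min-size 2 -i 0 -o 0 --mode rs --out blocks.tsv
syntenyscan stats --blocks blocks.tsv --genome-a ce.tsv --out-prefix tables
```

## File formats

- **genome table** — TSV: `gene_id  chrom  start  end  strand`
  (1-based inclusive; header optional). GFF3 is also accepted
  (`read_gff3`); multi-isoform genes are represented by their longest
  isoform (greatest summed CDS length).
- **correspondence** — TSV: `gene_A  gene_B`; duplicates collapse,
  one-to-many allowed. Pairs naming unknown genes are dropped with a
  report (lenient, default) or rejected (`--strict`). To use InParanoid
  output, export each ortholog group's member pairs to two columns.
- **blocks** — TSV with full per-block ledgers (round-trips through
  `read_blocks`) and a BED dialect (0-based half-open, two records per
  block).
- **operons** — TSV: `operon_id  chrom  member1,member2,...`.
- optional chromosome **lengths** (`chrom  length`) and **region**
  definitions (`chrom  start  end  label`, e.g. arm/center).

## Subcommands

`simulate` (ancestor + rearranged derived genome + truth ledger),
`detect`, `stats`, `operons`, `tandem`, `refine`. Every run writes a
provenance JSON (parameters, version, input checksums) next to its
output. See `docs/methods.md` for the scientific details and design
choices, including the annotation-refinement decision tree.

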