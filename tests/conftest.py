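"""Shared fixtures: small hand-built genomes and randomized instances."""

from __future__ import annotations

import numpy as np
import pytest

from syntenyscan.model import CorrespondenceMap, GeneMarker, Genome


def build_pair(
    layout_a: list[tuple[str, str, str]],
    layout_b: list[tuple[str, str, str]],
    pairs: list[tuple[str, str]],
    gene_len: int = 800,
    gap: int = 200,
):
    """Build a two-genome instance from (gene_id, chrom, strand) layouts.

    Genes are laid out left to right in list order with uniform lengths,
    so ordinals match list positions within each chromosome.
    """

    def genes(layout):
        out = []
        pos: dict[str, int] = {}
        for gid, chrom, strand in layout:
            p = pos.get(chrom, 1) + gap
            out.append(GeneMarker(gid, chrom, p, p + gene_len - 1, strand))
            pos[chrom] = p + gene_len - 1
        return out

    return (
        Genome("A", genes(layout_a)),
        Genome("B", genes(layout_b)),
        CorrespondenceMap(pairs),
    )


def strand_inversion_instance(n: int = 9, flipped: int = 5):
    """Nine colinear one-to-one genes; one ortholog strand-inverted.

    Reconstructs the worked example where strict detection yields blocks
    of five and three genes separated by the strand-flipped gene, and
    relaxing strandedness merges the whole region.
    """
    layout_a = [(f"a{i + 1}", "chrIII", "+") for i in range(n)]
    layout_b = [
        (f"b{i + 1}", "chrIII", "-" if i == flipped else "+") for i in range(n)
    ]
    pairs = [(f"a{i + 1}", f"b{i + 1}") for i in range(n)]
    return build_pair(layout_a, layout_b, pairs)


def identity_instance(n: int = 6, chrom: str = "chr1"):
    strands = ["+" if i % 2 else "-" for i in range(n)]
    layout_a = [(f"g{i + 1}", chrom, strands[i]) for i in range(n)]
    layout_b = [(f"h{i + 1}", chrom, strands[i]) for i in range(n)]
    pairs = [(f"g{i + 1}", f"h{i + 1}") for i in range(n)]
    return build_pair(layout_a, layout_b, pairs)


def random_instance(rng: np.random.Generator, lo: int = 4, hi: int = 14):
    """A random two-genome instance with mixed 1-1/1-many/absent orthology."""

    def mk(prefix, n, nchrom):
        genes = []
        per = [n // nchrom] * nchrom
        per[0] += n - sum(per)
        k = 0
        for ci, cnt in enumerate(per):
            pos = 1
            for _ in range(cnt):
                k += 1
                length = int(rng.integers(100, 900))
                pos += int(rng.integers(50, 500))
                genes.append(
                    GeneMarker(
                        f"{prefix}{k}", f"c{ci + 1}", pos, pos + length - 1,
                        "+" if rng.random() < 0.5 else "-",
                    )
                )
                pos += length
        return genes

    na = int(rng.integers(lo, hi + 1))
    nb = int(rng.integers(lo, hi + 1))
    genome_a = Genome("A", mk("a", na, int(rng.integers(1, 3))))
    genome_b = Genome("B", mk("b", nb, int(rng.integers(1, 3))))
    ids_b = [g.gene_id for g in genome_b]
    pairs = set()
    for g in genome_a:
        if rng.random() < 0.8:
            for b in rng.choice(ids_b, size=int(rng.integers(1, 3)), replace=False):
                pairs.add((g.gene_id, str(b)))
    return genome_a, genome_b, CorrespondenceMap(pairs)


def block_key(b):
    """Canonical comparison key: intervals, ledgers, labels, nesting."""
    return (
        b.interval_a.chrom, b.interval_a.start_ord, b.interval_a.end_ord,
        b.interval_b.chrom, b.interval_b.start_ord, b.interval_b.end_ord,
        b.matched_genes_a, b.matched_genes_b,
        b.in_map_mismatches_a, b.in_map_mismatches_b,
        b.out_map_mismatches_a, b.out_map_mismatches_b,
        b.orientation, b.strand_pattern, b.nested,
    )


def truth_key(b):
    """Interval/orientation key matching the simulator's TruthBlock.key."""
    return (
        b.interval_a.chrom, b.interval_a.start_ord, b.interval_a.end_ord,
        b.interval_b.chrom, b.interval_b.start_ord, b.interval_b.end_ord,
        b.orientation, b.strand_pattern, b.nested,
    )


@pytest.fixture
def figure_instance():
    return strand_inversion_instance()


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_920)
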