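"""Post-detection analytics: coverage, size statistics, chromosome
distribution, regional comparisons and random-breakage significance.

Block spans for size statistics are measured on the A genome (first gene
start to last gene end); coverage is the union of block spans divided by
chromosome length, with totals length-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import Genome, SyntenyBlock

__all__ = [
    "CoverageReport",
    "genome_coverage",
    "size_stats",
    "DistributionMatrix",
    "distribution_matrix",
    "compare_block_sizes",
    "assign_regions",
    "random_breakage_test",
    "random_breakage_pvalues",
    "adjust_pvalues",
]


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals as a sorted disjoint list."""
    ivs = sorted(intervals)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


@dataclass
class CoverageReport:
    per_chrom: dict[str, float]          # covered fraction in [0, 1]
    covered_bp: dict[str, int]
    lengths: dict[str, int]

    @property
    def total(self) -> float:
        total_len = sum(self.lengths.values())
        return sum(self.covered_bp.values()) / total_len if total_len else 0.0

    @property
    def total_pct(self) -> float:
        return 100.0 * self.total


def genome_coverage(
    blocks: Iterable[SyntenyBlock],
    genome: Genome,
    singletons: Iterable[SyntenyBlock] = (),
    lengths: Optional[dict[str, int]] = None,
) -> CoverageReport:
    """Fraction of each chromosome (and the genome) covered by block spans.

    Overlapping blocks are not double-counted. Pass the degenerate
    single-gene blocks from :func:`syntenyscan.detection.singleton_blocks`
    to include in-map singletons; doing so can only raise coverage.
    Chromosome lengths default to the largest gene end.
    """
    if lengths is None:
        lengths = {c: genome.chrom_length(c) for c in genome.chromosomes}
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}
    for blk in list(blocks) + list(singletons):
        try:
            iv = blk.interval_for(genome.genome_id)
        except KeyError:
            raise ValueError(
                f"block {blk.block_id} has no interval in genome {genome.genome_id!r}"
            ) from None
        if iv.chrom not in spans:
            raise ValueError(
                f"block {blk.block_id} lies on unknown chromosome {iv.chrom!r}"
            )
        spans[iv.chrom].append((iv.start_bp, min(iv.end_bp, lengths[iv.chrom])))
    covered = {
        c: sum(e - s + 1 for s, e in merge_intervals(v)) for c, v in spans.items()
    }
    frac = {c: covered[c] / lengths[c] for c in lengths}
    return CoverageReport(per_chrom=frac, covered_bp=covered, lengths=dict(lengths))


def size_stats(
    blocks: Sequence[SyntenyBlock], by_chromosome: bool = False
) -> pd.DataFrame:
    """Mean/median/range of block spans (kb) and gene counts, A-genome side.

    One row per chromosome when ``by_chromosome``, plus a ``total`` row.
    Empty input yields an empty frame.
    """
    if not blocks:
        return pd.DataFrame(
            columns=["n_blocks", "mean_kb", "median_kb", "min_kb", "max_kb",
                     "min_genes", "max_genes"]
        )
    rows = {}
    groups: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        groups.setdefault(b.interval_a.chrom, []).append(b)
    keys = sorted(groups) if by_chromosome else []
    for key in keys + ["total"]:
        grp = groups.get(key, list(blocks)) if key != "total" else list(blocks)
        kb = np.array([b.interval_a.span_bp / 1000.0 for b in grp])
        genes = np.array([b.size_genes for b in grp])
        rows[key] = {
            "n_blocks": len(grp),
            "mean_kb": float(kb.mean()),
            "median_kb": float(np.median(kb)),
            "min_kb": float(kb.min()),
            "max_kb": float(kb.max()),
            "min_genes": int(genes.min()),
            "max_genes": int(genes.max()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class DistributionMatrix:
    """Block counts per (A chromosome, B chromosome) pair.

    ``counts`` holds non-nested blocks, ``nested_counts`` nested ones
    (reported in parentheses alongside in the published layout). The
    homologous fraction is taken over all blocks using the supplied
    chromosome homology mapping.
    """

    counts: pd.DataFrame
    nested_counts: pd.DataFrame
    homology_map: dict[str, str]

    @property
    def total(self) -> int:
        return int(self.counts.values.sum() + self.nested_counts.values.sum())

    @property
    def row_margins(self) -> pd.Series:
        return (self.counts + self.nested_counts).sum(axis=1)

    @property
    def col_margins(self) -> pd.Series:
        return (self.counts + self.nested_counts).sum(axis=0)

    @property
    def homologous_count(self) -> int:
        n = 0
        both = self.counts + self.nested_counts
        for ca, cb in self.homology_map.items():
            if ca in both.index and cb in both.columns:
                n += int(both.loc[ca, cb])
        return n

    @property
    def homologous_fraction(self) -> float:
        return self.homologous_count / self.total if self.total else 0.0


def distribution_matrix(
    blocks: Sequence[SyntenyBlock],
    homology_map: Optional[dict[str, str]] = None,
) -> DistributionMatrix:
    """Tabulate blocks by chromosome pair, nested blocks counted apart.

    ``homology_map`` pairs A-chromosome names with their homologous
    B-chromosome names; by default chromosomes of equal name are
    homologous.
    """
    rows = sorted({b.interval_a.chrom for b in blocks})
    cols = sorted({b.interval_b.chrom for b in blocks})
    counts = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    nested = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for b in blocks:
        tgt = nested if b.nested else counts
        tgt.loc[b.interval_a.chrom, b.interval_b.chrom] += 1
    if homology_map is None:
        homology_map = {c: c for c in rows}
    return DistributionMatrix(counts=counts, nested_counts=nested, homology_map=homology_map)


def compare_block_sizes(
    blocks: Sequence[SyntenyBlock],
    group1: Callable[[SyntenyBlock], bool],
    group2: Callable[[SyntenyBlock], bool],
    values: Callable[[SyntenyBlock], float] = lambda b: b.interval_a.span_bp,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of block sizes.

    Exact null distribution for small tie-free samples (both n <= 20),
    tie-corrected normal approximation otherwise. Returns ``(U, p)``.
    """
    x = [values(b) for b in blocks if group1(b)]
    y = [values(b) for b in blocks if group2(b)]
    return mannwhitney(x, y)


def mannwhitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 20 and len(y) <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def assign_regions(
    blocks: Sequence[SyntenyBlock],
    regions: Sequence[tuple[str, int, int, str]],
) -> dict[str, list[SyntenyBlock]]:
    """Group blocks by the region label containing their A-side midpoint.

    Blocks whose midpoint falls in no region are collected under
    ``"unassigned"``.
    """
    out: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        iv = b.interval_a
        mid = (iv.start_bp + iv.end_bp) / 2.0
        label = "unassigned"
        for chrom, s, e, lab in regions:
            if chrom == iv.chrom and s <= mid <= e:
                label = lab
                break
        out.setdefault(label, []).append(b)
    return out


def _max_segment_null(
    total_length: float, n_segments: int, n_iter: int, rng: np.random.Generator
) -> np.ndarray:
    """Null distribution of the largest segment under random breakage.

    ``n_segments - 1`` breakpoints fall uniformly on a line of the given
    length; returns the maximal segment length of each replicate.
    """
    if n_segments <= 1:
        return np.full(n_iter, float(total_length))
    cuts = np.sort(rng.uniform(0.0, total_length, size=(n_iter, n_segments - 1)), axis=1)
    bounded = np.concatenate(
        [np.zeros((n_iter, 1)), cuts, np.full((n_iter, 1), float(total_length))], axis=1
    )
    return np.diff(bounded, axis=1).max(axis=1)


def random_breakage_pvalues(
    spans: Sequence[float],
    total_length: float,
    n_segments: int,
    n_iter: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo p-values for block spans under the random breakage null.

    The null places the observed number of segments at random on the
    concatenated genome; the p-value of a span is the fraction of
    replicates whose *largest* segment is at least that long, with a +1
    pseudo-count on numerator and denominator. All spans share one null
    sample, so the run is reproducible and cheap.
    """
    import warnings as _warnings

    if n_iter < 100:
        _warnings.warn("n_iter < 100 gives very coarse p-values", stacklevel=2)
    rng = np.random.default_rng(seed)
    null_max = _max_segment_null(total_length, n_segments, n_iter, rng)
    spans = np.asarray(spans, dtype=float)
    exceed = (null_max[None, :] >= spans[:, None]).sum(axis=1)
    return (exceed + 1) / (n_iter + 1)


def random_breakage_test(
    span: float,
    total_length: float,
    n_segments: int,
    n_iter: int = 10_000,
    seed: int = 0,
) -> float:
    """P-value of a single block span under the random breakage model."""
    return float(
        random_breakage_pvalues([span], total_length, n_segments, n_iter, seed)[0]
    )


def adjust_pvalues(pvalues: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini-Hochberg default)."""
    from statsmodels.stats.multitest import multipletests

    if len(pvalues) == 0:
        return np.array([])
    _, adj, _, _ = multipletests(list(pvalues), method=method)
    return adj
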