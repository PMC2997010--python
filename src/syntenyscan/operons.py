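"""Operonic-block classification and tandem expansion/contraction calls.

An operon is *conserved* when every member gene is a matched gene of one
single synteny block (a user-supplied conserved-operon list can replace
this rule). An *operonic block* has at least half of its A-interval genes
belonging to conserved operons. Tandem asymmetries are adjacent runs of
co-orthologous genes of unequal size on the two sides of a block --
lineage-specific gene-family expansion or contraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import CorrespondenceMap, Genome, SyntenyBlock, ValidationError
from .simulate import OperonAnnotation
from .stats import CoverageReport, merge_intervals

__all__ = [
    "conserved_operon_set",
    "operonic_blocks",
    "operon_coverage",
    "TandemAsymmetry",
    "tandem_asymmetries",
]


def conserved_operon_set(
    operons: Sequence[OperonAnnotation],
    blocks: Sequence[SyntenyBlock],
    genome: Optional[Genome] = None,
) -> set[str]:
    """Operons whose members are all matched genes of one single block."""
    if genome is not None:
        for op in operons:
            unknown = [m for m in op.members if m not in genome]
            if unknown:
                raise ValidationError(
                    f"operon {op.operon_id} references unknown genes: {unknown}"
                )
    conserved = set()
    for op in operons:
        members = set(op.members)
        for b in blocks:
            if members <= b.matched_genes_a or members <= b.matched_genes_b:
                conserved.add(op.operon_id)
                break
    return conserved


def operonic_blocks(
    blocks: Sequence[SyntenyBlock],
    conserved_operon_genes: Iterable[str],
    genome_a: Genome,
    threshold: float = 0.5,
) -> list[SyntenyBlock]:
    """Blocks with >= ``threshold`` of their A-interval genes operonic.

    The denominator is the interval's total gene count (mismatches
    included); "at least half" includes the boundary. The qualifying set
    is monotone non-increasing in the threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError("threshold must lie in (0, 1]")
    operonic_set = set(conserved_operon_genes)
    out = []
    for b in blocks:
        iv = b.interval_a
        genes = genome_a.genes(iv.chrom)[iv.start_ord : iv.end_ord + 1]
        n_op = sum(1 for g in genes if g.gene_id in operonic_set)
        if n_op / len(genes) >= threshold:
            out.append(b)
    return out


def operon_coverage(
    operons: Sequence[OperonAnnotation],
    genome: Genome,
    lengths: Optional[dict[str, int]] = None,
) -> CoverageReport:
    """Fraction of the genome covered by operon spans (union, no double count)."""
    if lengths is None:
        lengths = {c: genome.chrom_length(c) for c in genome.chromosomes}
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}
    for op in operons:
        genes = [genome.gene(m) for m in op.members]
        chroms = {g.chrom for g in genes}
        if len(chroms) != 1:
            raise ValidationError(f"operon {op.operon_id} spans chromosomes {chroms}")
        chrom = chroms.pop()
        spans[chrom].append(
            (min(g.start for g in genes), min(max(g.end for g in genes), lengths[chrom]))
        )
    covered = {
        c: sum(e - s + 1 for s, e in merge_intervals(v)) for c, v in spans.items()
    }
    return CoverageReport(
        per_chrom={c: covered[c] / lengths[c] for c in lengths},
        covered_bp=covered,
        lengths=dict(lengths),
    )


@dataclass(frozen=True)
class TandemAsymmetry:
    """Unequal adjacent co-ortholog runs on the two sides of a block."""

    block_id: str
    genes_a: tuple[str, ...]
    genes_b: tuple[str, ...]
    direction: str  # A_expanded | B_expanded

    @property
    def n_a(self) -> int:
        return len(self.genes_a)

    @property
    def n_b(self) -> int:
        return len(self.genes_b)


def _contiguous(ordinals: list[int]) -> bool:
    s = sorted(ordinals)
    return all(b - a == 1 for a, b in zip(s, s[1:]))


def tandem_asymmetries(
    blocks: Sequence[SyntenyBlock],
    corr: CorrespondenceMap,
    genome_a: Genome,
    genome_b: Genome,
    include_loose: bool = False,
) -> list[TandemAsymmetry]:
    """Find tandem expansions/contractions inside blocks.

    Within each block, matched genes are grouped into connected components
    of the correspondence relation; a component whose sides have unequal
    gene counts and whose genes form adjacency-contiguous runs on both
    sides is an asymmetry (direction named after the larger side).
    Components with interleaved, non-contiguous runs are reported only
    when ``include_loose`` is set.
    """
    out = []
    for b in blocks:
        genes_a = sorted(b.matched_genes_a, key=lambda g: genome_a.position(g)[1])
        genes_b_set = b.matched_genes_b
        # union-find over the block's bipartite correspondence
        parent: dict[str, str] = {}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(x: str, y: str) -> None:
            rx, ry = find(x), find(y)
            if rx != ry:
                parent[rx] = ry

        for g in genes_a:
            parent[f"a:{g}"] = f"a:{g}"
        for g in genes_b_set:
            parent[f"b:{g}"] = f"b:{g}"
        for g in genes_a:
            for p in corr.partners_a.get(g, frozenset()):
                if p in genes_b_set:
                    union(f"a:{g}", f"b:{p}")
        comps: dict[str, tuple[list[str], list[str]]] = {}
        for key in parent:
            side, gid = key.split(":", 1)
            comps.setdefault(find(key), ([], []))[0 if side == "a" else 1].append(gid)
        for side_a, side_b in comps.values():
            if not side_a or not side_b or len(side_a) == len(side_b):
                continue
            tight = _contiguous(
                [genome_a.position(g)[1] for g in side_a]
            ) and _contiguous([genome_b.position(g)[1] for g in side_b])
            if not tight and not include_loose:
                continue
            side_a.sort(key=lambda g: genome_a.position(g)[1])
            side_b.sort(key=lambda g: genome_b.position(g)[1])
            out.append(
                TandemAsymmetry(
                    block_id=b.block_id,
                    genes_a=tuple(side_a),
                    genes_b=tuple(side_b),
                    direction="A_expanded" if len(side_a) > len(side_b) else "B_expanded",
                )
            )
    return out
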