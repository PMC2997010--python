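"""Domain types for gene-order genomes, ortholog correspondences and synteny blocks.

Coordinates are 1-based and inclusive on both ends throughout the package
(the GFF3 convention); BED export converts to 0-based half-open at the
serialization boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional, Sequence

__all__ = [
    "GeneMarker",
    "Genome",
    "CorrespondenceMap",
    "MarkerStatus",
    "classify_markers",
    "Mode",
    "DetectionParams",
    "BlockInterval",
    "SyntenyBlock",
    "ValidationError",
]

STRANDS = ("+", "-")


class ValidationError(ValueError):
    """Raised when an input object violates a structural contract."""


@dataclass(frozen=True)
class GeneMarker:
    """A gene (or any genetic marker) used as a synteny anchor.

    ``start``/``end`` are 1-based inclusive base-pair coordinates on
    ``chrom``; ``strand`` is ``"+"`` or ``"-"``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if self.start < 1:
            raise ValidationError(
                f"gene {self.gene_id}: coordinates are 1-based, got start={self.start}"
            )
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start ({self.start}) > end ({self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


class Genome:
    """An ordered collection of gene markers grouped by chromosome.

    Genes within a chromosome are kept in a deterministic total order,
    sorted by ``(start, end, gene_id)``; chromosomes are ordered
    lexicographically by name so that any permutation of the same input
    rows yields an identical object.
    """

    def __init__(self, genome_id: str, genes: Iterable[GeneMarker]):
        self.genome_id = genome_id
        by_chrom: dict[str, list[GeneMarker]] = {}
        seen: set[str] = set()
        for g in genes:
            if g.gene_id in seen:
                raise ValidationError(
                    f"genome {genome_id}: duplicate gene_id {g.gene_id!r}"
                )
            seen.add(g.gene_id)
            by_chrom.setdefault(g.chrom, []).append(g)
        self._genes_by_chrom: dict[str, tuple[GeneMarker, ...]] = {}
        self._index: dict[str, tuple[str, int]] = {}
        for chrom in sorted(by_chrom):
            ordered = tuple(
                sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
            )
            self._genes_by_chrom[chrom] = ordered
            for i, g in enumerate(ordered):
                self._index[g.gene_id] = (chrom, i)

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self._genes_by_chrom)

    def genes(self, chrom: str) -> tuple[GeneMarker, ...]:
        return self._genes_by_chrom[chrom]

    def __iter__(self) -> Iterator[GeneMarker]:
        for chrom in self.chromosomes:
            yield from self._genes_by_chrom[chrom]

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def position(self, gene_id: str) -> tuple[str, int]:
        """Return ``(chromosome, ordinal)`` of a gene; ordinals are 0-based."""
        try:
            return self._index[gene_id]
        except KeyError:
            raise KeyError(
                f"gene {gene_id!r} not in genome {self.genome_id}"
            ) from None

    def gene(self, gene_id: str) -> GeneMarker:
        chrom, i = self.position(gene_id)
        return self._genes_by_chrom[chrom][i]

    def chrom_length(self, chrom: str) -> int:
        """Chromosome length proxy: the largest gene end coordinate."""
        return max(g.end for g in self._genes_by_chrom[chrom])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return (
            self.genome_id == other.genome_id
            and self._genes_by_chrom == other._genes_by_chrom
        )

    def __repr__(self) -> str:
        return (
            f"Genome({self.genome_id!r}, {len(self)} genes, "
            f"{len(self.chromosomes)} chromosomes)"
        )


class CorrespondenceMap:
    """A symmetric ortholog relation between the gene sets of two genomes.

    One-to-many and many-to-many relations are permitted; duplicated pairs
    collapse to one.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.pairs: frozenset[tuple[str, str]] = frozenset(
            (str(a), str(b)) for a, b in pairs
        )
        partners_a: dict[str, set[str]] = {}
        partners_b: dict[str, set[str]] = {}
        for a, b in self.pairs:
            partners_a.setdefault(a, set()).add(b)
            partners_b.setdefault(b, set()).add(a)
        self.partners_a: dict[str, frozenset[str]] = {
            k: frozenset(v) for k, v in partners_a.items()
        }
        self.partners_b: dict[str, frozenset[str]] = {
            k: frozenset(v) for k, v in partners_b.items()
        }

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def validate(self, genome_a: Genome, genome_b: Genome) -> list[tuple[str, str]]:
        """Return the pairs whose genes are missing from the genomes."""
        return sorted(
            (a, b)
            for a, b in self.pairs
            if a not in genome_a or b not in genome_b
        )

    def restricted_to(self, genome_a: Genome, genome_b: Genome) -> "CorrespondenceMap":
        """Drop pairs referencing unknown genes (lenient-mode view)."""
        return CorrespondenceMap(
            (a, b) for a, b in self.pairs if a in genome_a and b in genome_b
        )

    def merged_with(self, pairs: Iterable[tuple[str, str]]) -> "CorrespondenceMap":
        return CorrespondenceMap(list(self.pairs) + [tuple(p) for p in pairs])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CorrespondenceMap):
            return NotImplemented
        return self.pairs == other.pairs

    def __repr__(self) -> str:
        return f"CorrespondenceMap({len(self.pairs)} pairs)"


@dataclass(frozen=True)
class MarkerStatus:
    """Partition of each genome's genes into in-map and out-map sets.

    A gene is *in-map* when it has at least one ortholog in the other
    genome, *out-map* otherwise.
    """

    in_map_a: frozenset[str]
    out_map_a: frozenset[str]
    in_map_b: frozenset[str]
    out_map_b: frozenset[str]

    def is_in_map(self, genome_side: str, gene_id: str) -> bool:
        if genome_side == "a":
            return gene_id in self.in_map_a
        if genome_side == "b":
            return gene_id in self.in_map_b
        raise ValueError(f"genome_side must be 'a' or 'b', got {genome_side!r}")


def classify_markers(
    genome_a: Genome, genome_b: Genome, corr: CorrespondenceMap
) -> MarkerStatus:
    """Partition both genomes' genes into in-map / out-map sets."""
    in_a = frozenset(g.gene_id for g in genome_a if g.gene_id in corr.partners_a)
    in_b = frozenset(g.gene_id for g in genome_b if g.gene_id in corr.partners_b)
    return MarkerStatus(
        in_map_a=in_a,
        out_map_a=frozenset(g.gene_id for g in genome_a) - in_a,
        in_map_b=in_b,
        out_map_b=frozenset(g.gene_id for g in genome_b) - in_b,
    )


class Mode(str, Enum):
    """Order/strand coupling admitted inside a block.

    RS
        Only colinear order with consistent strands, or inverted order
        with reversed strands (the coupling of a true inversion).
    R_S
        All four order x strand combinations, each uniform across the
        block.
    FREE
        No order or strand constraint; content conservation only.
    """

    RS = "rs"
    R_S = "r_s"
    FREE = "free"

    @classmethod
    def coerce(cls, value: "str | Mode") -> "Mode":
        if isinstance(value, Mode):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValidationError(
                f"unknown mode {value!r}; expected one of rs, r_s, free"
            ) from None


@dataclass(frozen=True)
class DetectionParams:
    """Block-validity parameters.

    ``*_max_count`` caps are absolute mismatch counts per block side
    (``None`` = unlimited); ``*_max_pct`` caps are percentages of the
    side's total gene count. Both caps of a kind must hold on both sides.
    The defaults reproduce the perfect-block configuration: at least two
    matched genes, zero mismatches, mode ``rs``.
    """

    min_size: int = 2
    max_size: Optional[int] = None
    in_map_max_count: Optional[int] = 0
    in_map_max_pct: float = 100.0
    out_map_max_count: Optional[int] = 0
    out_map_max_pct: float = 100.0
    mode: Mode = Mode.RS
    report_nested: bool = True
    include_singletons: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Mode.coerce(self.mode))
        if self.min_size < 1:
            raise ValidationError("min_size must be >= 1")
        if self.max_size is not None and self.max_size < self.min_size:
            raise ValidationError("max_size must be >= min_size")
        for name in ("in_map_max_count", "out_map_max_count"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("in_map_max_pct", "out_map_max_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name} must be in [0, 100]")


@dataclass(frozen=True)
class BlockInterval:
    """A contiguous run of genes on one chromosome of one genome."""

    chrom: str
    start_ord: int  # 0-based ordinal of the first gene
    end_ord: int    # 0-based ordinal of the last gene, inclusive
    start_bp: int   # start of the first gene
    end_bp: int     # end of the last gene

    @property
    def n_genes(self) -> int:
        return self.end_ord - self.start_ord + 1

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def contains(self, other: "BlockInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start_ord <= other.start_ord
            and other.end_ord <= self.end_ord
        )

    def disjoint(self, other: "BlockInterval") -> bool:
        return (
            self.chrom != other.chrom
            or self.end_ord < other.start_ord
            or other.end_ord < self.start_ord
        )


@dataclass
class SyntenyBlock:
    """A pair of gene intervals with matched pairs and mismatch ledgers.

    Every gene of each interval belongs to exactly one of: the matched
    set, the in-map mismatch set or the out-map mismatch set of its side.
    ``orientation`` is ``colinear``/``inverted``/``unordered``;
    ``strand_pattern`` is ``consistent``/``reversed``/``mixed``.
    """

    block_id: str
    genome_a_id: str
    genome_b_id: str
    interval_a: BlockInterval
    interval_b: BlockInterval
    matched_pairs: tuple[tuple[str, str], ...]
    in_map_mismatches_a: frozenset[str]
    in_map_mismatches_b: frozenset[str]
    out_map_mismatches_a: frozenset[str]
    out_map_mismatches_b: frozenset[str]
    orientation: str
    strand_pattern: str
    nested: bool = False
    parent_id: Optional[str] = None
    singleton: bool = False

    @property
    def matched_genes_a(self) -> frozenset[str]:
        return frozenset(a for a, _ in self.matched_pairs)

    @property
    def matched_genes_b(self) -> frozenset[str]:
        return frozenset(b for _, b in self.matched_pairs)

    @property
    def n_matched_a(self) -> int:
        return len(self.matched_genes_a)

    @property
    def n_matched_b(self) -> int:
        return len(self.matched_genes_b)

    @property
    def size_genes(self) -> int:
        """Block size in genes, counted on the A side."""
        return self.n_matched_a

    def interval_for(self, genome_id: str) -> BlockInterval:
        if genome_id == self.genome_a_id:
            return self.interval_a
        if genome_id == self.genome_b_id:
            return self.interval_b
        raise KeyError(f"block {self.block_id} has no interval in {genome_id!r}")

    def mismatch_counts(self) -> dict[str, int]:
        return {
            "in_map_a": len(self.in_map_mismatches_a),
            "in_map_b": len(self.in_map_mismatches_b),
            "out_map_a": len(self.out_map_mismatches_a),
            "out_map_b": len(self.out_map_mismatches_b),
        }
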