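"""Synthetic gene-order genomes with planted, provable ground truth.

The generator emulates the shape of the real inputs the detector consumes:
an "ancestor" genome of ordered gene markers, a derived genome produced by
an explicit rearrangement script (inversions, transpositions, indels,
tandem and segmental duplications, reciprocal translocations), the ortholog
correspondence induced by the script, and a :class:`TruthLedger` listing
the maximal perfect blocks (mode ``rs``, zero mismatches) a correct
detector must report, including inverted orientations and nested
(segmental-duplication) blocks.

Scale defaults loosely imitate a compact nematode-like genome: one gene
per ~5 kb with mean gene length ~3 kb, broadly (lognormally) distributed.
All randomness flows from explicit integer seeds through a single
``numpy`` generator per artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .model import (
    CorrespondenceMap,
    GeneMarker,
    Genome,
    ValidationError,
)
from .refinement import PredictionRecord

__all__ = [
    "AncestorSpec",
    "Inversion",
    "Transposition",
    "Deletion",
    "Insertion",
    "TandemDuplication",
    "SegmentalDuplication",
    "Translocation",
    "RearrangementScript",
    "TruthBlock",
    "DefectRecord",
    "TruthLedger",
    "OperonAnnotation",
    "generate_ancestor",
    "apply_script",
    "inject_defects",
    "make_operons",
    "prediction_records_for_defects",
]


@dataclass(frozen=True)
class AncestorSpec:
    """Parameters of the ancestral genome draw.

    Gene and intergenic lengths are lognormal with the given means (bp);
    sigma values are on the log scale. ``strand_prob`` is the probability
    of the ``+`` strand.
    """

    n_chromosomes: int = 2
    genes_per_chromosome: int = 100
    mean_gene_length: float = 3000.0
    gene_length_sigma: float = 0.8
    mean_intergenic: float = 2000.0
    intergenic_sigma: float = 1.0
    strand_prob: float = 0.5
    min_gene_length: int = 150
    min_intergenic: int = 50
    chrom_prefix: str = "chr"
    gene_prefix: str = "anc"
    genome_id: str = "ancestor"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValidationError("chromosome and gene counts must be positive")
        if not 0.0 <= self.strand_prob <= 1.0:
            raise ValidationError("strand_prob must be in [0, 1]")


def _lognormal(rng: np.random.Generator, mean: float, sigma: float, size: int) -> np.ndarray:
    mu = np.log(mean) - sigma**2 / 2.0
    return rng.lognormal(mu, sigma, size=size)


def generate_ancestor(spec: AncestorSpec) -> Genome:
    """Draw the ancestral genome; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    genes = []
    for ci in range(spec.n_chromosomes):
        chrom = f"{spec.chrom_prefix}{ci + 1:02d}"
        n = spec.genes_per_chromosome
        lengths = np.maximum(
            _lognormal(rng, spec.mean_gene_length, spec.gene_length_sigma, n),
            spec.min_gene_length,
        ).astype(int)
        gaps = np.maximum(
            _lognormal(rng, spec.mean_intergenic, spec.intergenic_sigma, n),
            spec.min_intergenic,
        ).astype(int)
        strands = np.where(rng.random(n) < spec.strand_prob, "+", "-")
        pos = 1
        for gi in range(n):
            pos += int(gaps[gi])
            start = pos
            end = start + int(lengths[gi]) - 1
            genes.append(
                GeneMarker(
                    f"{spec.gene_prefix}_{chrom}_g{gi + 1:04d}",
                    chrom,
                    start,
                    end,
                    str(strands[gi]),
                )
            )
            pos = end + 1
    return Genome(spec.genome_id, genes)


# ---------------------------------------------------------------------------
# Rearrangement operations (ordinals refer to the derived gene order at the
# moment the operation is applied; intervals are inclusive).

@dataclass(frozen=True)
class Inversion:
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class Transposition:
    chrom: str
    start: int
    end: int
    dest_chrom: str
    dest_index: int  # insertion point in the destination after removal


@dataclass(frozen=True)
class Deletion:
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class Insertion:
    chrom: str
    index: int
    n_genes: int


@dataclass(frozen=True)
class TandemDuplication:
    chrom: str
    start: int
    end: int
    copies: int = 1


@dataclass(frozen=True)
class SegmentalDuplication:
    chrom: str
    start: int
    end: int
    dest_chrom: str
    dest_index: int


@dataclass(frozen=True)
class Translocation:
    """Reciprocal exchange of the suffixes starting at the two indices."""

    chrom_1: str
    index_1: int
    chrom_2: str
    index_2: int


Operation = Union[
    Inversion, Transposition, Deletion, Insertion,
    TandemDuplication, SegmentalDuplication, Translocation,
]


class _DGene:
    """One gene of the derived genome under construction."""

    __slots__ = ("source_id", "src_chrom", "src_ord", "src_strand", "strand",
                 "length", "touched")

    def __init__(self, source_id, src_chrom, src_ord, src_strand, strand,
                 length, touched=False):
        self.source_id = source_id
        self.src_chrom = src_chrom
        self.src_ord = src_ord
        self.src_strand = src_strand
        self.strand = strand
        self.length = length
        self.touched = touched

    def copy(self) -> "_DGene":
        return _DGene(self.source_id, self.src_chrom, self.src_ord,
                      self.src_strand, self.strand, self.length, self.touched)

    @property
    def rel_same(self) -> Optional[bool]:
        if self.source_id is None:
            return None
        return self.strand == self.src_strand


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


@dataclass(frozen=True)
class TruthBlock:
    """A block a correct strict detector must report, in ordinal terms."""

    chrom_a: str       # ancestor chromosome
    a_start_ord: int
    a_end_ord: int
    chrom_b: str       # derived chromosome
    b_start_ord: int
    b_end_ord: int
    orientation: str   # colinear | inverted
    strand_pattern: str  # consistent | reversed
    nested: bool = False

    @property
    def key(self):
        return (
            self.chrom_a, self.a_start_ord, self.a_end_ord,
            self.chrom_b, self.b_start_ord, self.b_end_ord,
            self.orientation, self.strand_pattern, self.nested,
        )


@dataclass(frozen=True)
class DefectRecord:
    """One injected annotation defect and its expected corrective action."""

    kind: str                  # fusion | fission | drop_ortholog
    genome_id: str             # genome whose annotation was corrupted
    removed: tuple[str, ...]
    added: tuple[str, ...]
    query_gene: str            # out-map gene expected to drive the repair
    query_genome_id: str
    target_chrom: str
    target_span: tuple[int, int]  # true locus of the query's ortholog
    expected_action: str       # split | merge | replace


@dataclass
class TruthLedger:
    blocks: list[TruthBlock] = field(default_factory=list)
    in_map_ancestor: frozenset[str] = frozenset()
    out_map_ancestor: frozenset[str] = frozenset()
    in_map_derived: frozenset[str] = frozenset()
    out_map_derived: frozenset[str] = frozenset()
    defects: list[DefectRecord] = field(default_factory=list)

    def block_keys(self) -> frozenset:
        return frozenset(b.key for b in self.blocks)


@dataclass(frozen=True)
class RearrangementScript:
    """An ordered list of rearrangement operations plus a seed.

    The seed drives the stochastic parts of realization (novel-gene
    lengths, intergenic gaps of the derived genome).
    """

    ops: tuple[Operation, ...] = ()
    seed: int = 0

    @classmethod
    def random(
        cls,
        ancestor: Genome,
        n_ops: int,
        seed: int,
        kinds: Sequence[str] = (
            "inversion", "transposition", "deletion", "insertion",
            "tandem_duplication", "segmental_duplication",
        ),
        segment_range: tuple[int, int] = (2, 4),
        buffer: int = 2,
    ) -> "RearrangementScript":
        """Sample a script whose operations are spaced beyond merging reach.

        Each operation's footprint (source, destination and ``buffer``
        flanking genes on each side) is kept disjoint from every other
        footprint, so the truth ledger's blocks cannot merge or interact.
        Operations that no longer fit are skipped, so fewer than ``n_ops``
        may be emitted on small genomes.
        """
        rng = np.random.default_rng(seed)
        state = _initial_state(ancestor)
        ops: list[Operation] = []
        for _ in range(n_ops):
            kind = str(rng.choice(list(kinds)))
            op = _sample_op(state, kind, rng, segment_range, buffer)
            if op is None:
                continue
            _apply_op(state, op, rng, len(ops))
            ops.append(op)
        return cls(ops=tuple(ops), seed=int(rng.integers(0, 2**31 - 1)))


def _initial_state(ancestor: Genome) -> dict[str, list[_DGene]]:
    state: dict[str, list[_DGene]] = {}
    for chrom in ancestor.chromosomes:
        state[chrom] = [
            _DGene(g.gene_id, chrom, i, g.strand, g.strand, g.length)
            for i, g in enumerate(ancestor.genes(chrom))
        ]
    return state


def _pristine_stretches(genes: list[_DGene]) -> list[tuple[int, int]]:
    """Maximal runs of untouched, source-colinear genes (inclusive bounds)."""
    runs = []
    start = None
    prev: Optional[_DGene] = None
    for i, g in enumerate(genes):
        ok = g.source_id is not None and not g.touched and g.rel_same is True
        contiguous = (
            ok
            and prev is not None
            and prev.src_chrom == g.src_chrom
            and g.src_ord == prev.src_ord + 1
        )
        if ok and (start is None or contiguous):
            if start is None:
                start = i
        else:
            if start is not None:
                runs.append((start, i - 1))
            start = i if ok else None
        prev = g if ok else None
    if start is not None:
        runs.append((start, len(genes) - 1))
    return runs


def _mark(genes: list[_DGene], start: int, end: int, buffer: int) -> None:
    for i in range(max(0, start - buffer), min(len(genes), end + buffer + 1)):
        genes[i].touched = True


def _sample_op(state, kind, rng, segment_range, buffer) -> Optional[Operation]:
    seg = int(rng.integers(segment_range[0], segment_range[1] + 1))
    chroms = sorted(state)

    def pick_site(need: int, exclude_chrom: Optional[str] = None):
        options = []
        for chrom in chroms:
            if chrom == exclude_chrom:
                continue
            for s, e in _pristine_stretches(state[chrom]):
                if e - s + 1 >= need:
                    options.append((chrom, s, e))
        if not options:
            return None
        chrom, s, e = options[int(rng.integers(len(options)))]
        lo = s + buffer
        hi = e - buffer - need + 1
        if hi < lo:
            return None
        start = int(rng.integers(lo, hi + 1))
        return chrom, start

    src = pick_site(seg + 2 * buffer)
    if src is None:
        return None
    chrom, start = src
    end = start + seg - 1

    if kind == "inversion":
        op = Inversion(chrom, start, end)
    elif kind == "deletion":
        op = Deletion(chrom, start, end)
    elif kind == "tandem_duplication":
        op = TandemDuplication(chrom, start, end, copies=int(rng.integers(1, 3)))
    elif kind == "insertion":
        op = Insertion(chrom, start, n_genes=seg)
    elif kind in ("transposition", "segmental_duplication"):
        # Temporarily reserve the source before picking a destination.
        _mark(state[chrom], start, end, buffer)
        dest = pick_site(2 * buffer + 1)
        if dest is None:
            return None
        dchrom, dstart = dest
        dest_index = dstart + buffer
        if kind == "transposition":
            if dchrom == chrom:
                if start <= dest_index <= end + 1:
                    return None
                if dest_index > end:
                    dest_index -= seg
            op = Transposition(chrom, start, end, dchrom, dest_index)
        else:
            op = SegmentalDuplication(chrom, start, end, dchrom, dest_index)
    elif kind == "translocation":
        _mark(state[chrom], start, end, buffer)
        dest = pick_site(2 * buffer + 1, exclude_chrom=chrom)
        if dest is None:
            return None
        dchrom, dstart = dest
        op = Translocation(chrom, start, dchrom, dstart + buffer)
    else:
        raise ValidationError(f"unknown operation kind {kind!r}")
    return op


def _apply_op(state, op, rng: np.random.Generator, op_index: int) -> None:
    def bounds_ok(chrom, start, end):
        return chrom in state and 0 <= start <= end < len(state[chrom])

    buffer = 1  # touched halo applied at execution time

    if isinstance(op, Inversion):
        if not bounds_ok(op.chrom, op.start, op.end):
            raise ValidationError(f"op {op_index}: inversion interval invalid")
        genes = state[op.chrom]
        seg = genes[op.start : op.end + 1][::-1]
        for g in seg:
            g.strand = _flip(g.strand)
        genes[op.start : op.end + 1] = seg
        _mark(genes, op.start, op.end, buffer)
    elif isinstance(op, Deletion):
        if not bounds_ok(op.chrom, op.start, op.end):
            raise ValidationError(f"op {op_index}: deletion interval invalid")
        genes = state[op.chrom]
        del genes[op.start : op.end + 1]
        _mark(genes, op.start, op.start - 1, buffer + 1)
    elif isinstance(op, Insertion):
        genes = state[op.chrom]
        if not (0 <= op.index <= len(genes)) or op.n_genes < 1:
            raise ValidationError(f"op {op_index}: insertion point invalid")
        novel = [
            _DGene(None, None, None, None,
                   "+" if rng.random() < 0.5 else "-",
                   int(max(150, rng.lognormal(np.log(3000) - 0.32, 0.8))),
                   touched=True)
            for _ in range(op.n_genes)
        ]
        genes[op.index : op.index] = novel
        _mark(genes, op.index, op.index + op.n_genes - 1, buffer)
    elif isinstance(op, TandemDuplication):
        if not bounds_ok(op.chrom, op.start, op.end) or op.copies < 1:
            raise ValidationError(f"op {op_index}: tandem duplication invalid")
        genes = state[op.chrom]
        seg = [g.copy() for g in genes[op.start : op.end + 1]]
        insert = []
        for _ in range(op.copies):
            insert.extend(g.copy() for g in seg)
        genes[op.end + 1 : op.end + 1] = insert
        _mark(genes, op.start, op.end + len(insert), buffer)
    elif isinstance(op, Transposition):
        if not bounds_ok(op.chrom, op.start, op.end):
            raise ValidationError(f"op {op_index}: transposition source invalid")
        genes = state[op.chrom]
        seg = genes[op.start : op.end + 1]
        del genes[op.start : op.end + 1]
        dest = state.get(op.dest_chrom)
        if dest is None or not (0 <= op.dest_index <= len(dest)):
            raise ValidationError(f"op {op_index}: transposition destination invalid")
        dest[op.dest_index : op.dest_index] = seg
        junction = op.start
        if dest is genes and op.dest_index <= op.start:
            junction += len(seg)
        _mark(genes, junction, junction - 1, buffer + 1)
        _mark(dest, op.dest_index, op.dest_index + len(seg) - 1, buffer)
    elif isinstance(op, SegmentalDuplication):
        if not bounds_ok(op.chrom, op.start, op.end):
            raise ValidationError(f"op {op_index}: duplication source invalid")
        seg = [g.copy() for g in state[op.chrom][op.start : op.end + 1]]
        for g in seg:
            g.touched = True
        dest = state.get(op.dest_chrom)
        if dest is None or not (0 <= op.dest_index <= len(dest)):
            raise ValidationError(f"op {op_index}: duplication destination invalid")
        dest[op.dest_index : op.dest_index] = seg
        _mark(state[op.chrom], op.start, op.end, 0)
        _mark(dest, op.dest_index, op.dest_index + len(seg) - 1, buffer)
    elif isinstance(op, Translocation):
        if op.chrom_1 == op.chrom_2:
            raise ValidationError(f"op {op_index}: translocation needs two chromosomes")
        g1, g2 = state.get(op.chrom_1), state.get(op.chrom_2)
        if g1 is None or g2 is None or not (
            0 <= op.index_1 <= len(g1) and 0 <= op.index_2 <= len(g2)
        ):
            raise ValidationError(f"op {op_index}: translocation indices invalid")
        tail1, tail2 = g1[op.index_1 :], g2[op.index_2 :]
        g1[op.index_1 :] = tail2
        g2[op.index_2 :] = tail1
        _mark(g1, op.index_1, op.index_1, buffer)
        _mark(g2, op.index_2, op.index_2, buffer)
    else:
        raise ValidationError(f"op {op_index}: unknown operation {op!r}")


def _truth_scan(
    state: dict[str, list[_DGene]], min_size: int = 2
) -> list[TruthBlock]:
    """Derive the strict-mode truth blocks from the derived gene order."""
    runs: list[TruthBlock] = []
    for chrom in sorted(state):
        genes = state[chrom]
        i = 0
        cur: list[tuple[int, _DGene]] = []
        cur_rel: Optional[bool] = None

        def close():
            nonlocal cur, cur_rel
            if cur:
                ords = [g.src_ord for _, g in cur]
                if len(cur) >= min_size and len(set(ords)) >= min_size:
                    runs.append(
                        TruthBlock(
                            chrom_a=cur[0][1].src_chrom,
                            a_start_ord=min(ords),
                            a_end_ord=max(ords),
                            chrom_b=chrom,
                            b_start_ord=cur[0][0],
                            b_end_ord=cur[-1][0],
                            orientation="colinear" if cur_rel else "inverted",
                            strand_pattern="consistent" if cur_rel else "reversed",
                        )
                    )
            cur, cur_rel = [], None

        for i, g in enumerate(genes):
            rel = g.rel_same
            if rel is None:
                close()
                continue
            if cur:
                last = cur[-1][1]
                step = 1 if cur_rel else -1
                compatible = (
                    rel == cur_rel
                    and g.src_chrom == last.src_chrom
                    and g.src_ord in (last.src_ord, last.src_ord + step)
                )
                if not compatible:
                    close()
            if not cur:
                cur_rel = rel
            cur.append((i, g))
        close()

    # Nested: ancestor interval strictly inside another run's; derived
    # intervals of distinct runs never overlap, so that side is automatic.
    out = []
    for r in runs:
        nested = any(
            o is not r
            and o.chrom_a == r.chrom_a
            and o.a_start_ord <= r.a_start_ord
            and r.a_end_ord <= o.a_end_ord
            and (o.a_start_ord, o.a_end_ord) != (r.a_start_ord, r.a_end_ord)
            for o in runs
        )
        out.append(replace(r, nested=nested) if nested else r)
    return out


def apply_script(
    ancestor: Genome,
    script: RearrangementScript,
    derived_id: str = "derived",
    derived_prefix: str = "d",
    min_size: int = 2,
    spec: Optional[AncestorSpec] = None,
) -> tuple[Genome, CorrespondenceMap, TruthLedger]:
    """Realize a rearrangement script against an ancestor genome.

    Returns the derived genome (fresh coordinates, inherited gene lengths),
    the induced ortholog correspondence (duplications yield one-to-many,
    indels yield out-map genes) and the truth ledger of strict-mode blocks.
    """
    if spec is None:
        spec = AncestorSpec()
    state = _initial_state(ancestor)
    for g_list in state.values():
        for g in g_list:
            g.touched = False
    rng = np.random.default_rng(script.seed)
    for k, op in enumerate(script.ops):
        _apply_op(state, op, rng, k)

    genes = []
    pairs = []
    counter = 0
    for chrom in sorted(state):
        pos = 1
        n = len(state[chrom])
        gaps = np.maximum(
            _lognormal(rng, spec.mean_intergenic, spec.intergenic_sigma, max(n, 1)),
            spec.min_intergenic,
        ).astype(int)
        for i, g in enumerate(state[chrom]):
            counter += 1
            gid = f"{derived_prefix}{counter:05d}"
            pos += int(gaps[i])
            start = pos
            end = start + g.length - 1
            genes.append(GeneMarker(gid, chrom, start, end, g.strand))
            pos = end + 1
            if g.source_id is not None:
                pairs.append((g.source_id, gid))
    derived = Genome(derived_id, genes)
    corr = CorrespondenceMap(pairs)

    sources_with_copy = {a for a, _ in pairs}
    derived_in = {b for _, b in pairs}
    ledger = TruthLedger(
        blocks=_truth_scan(state, min_size=min_size),
        in_map_ancestor=frozenset(sources_with_copy),
        out_map_ancestor=frozenset(g.gene_id for g in ancestor) - frozenset(sources_with_copy),
        in_map_derived=frozenset(derived_in),
        out_map_derived=frozenset(g.gene_id for g in derived) - frozenset(derived_in),
    )
    return derived, corr, ledger


# ---------------------------------------------------------------------------
# Annotation defects

def inject_defects(
    genome: Genome,
    corr: CorrespondenceMap,
    rates: dict[str, float],
    seed: int,
    side: str = "b",
) -> tuple[Genome, CorrespondenceMap, list[DefectRecord]]:
    """Corrupt an annotation the way draft gene models are corrupted.

    ``rates`` maps ``{"split", "merge", "drop_ortholog"}`` to per-site
    probabilities. A *split* defect fuses two adjacent models into one
    chimeric model that keeps the longer half's orthology (the repair is a
    split); a *merge* defect breaks one model into two fragments and
    severs its orthology entirely -- neither fragment would survive a
    reciprocal-best-hit call -- so the repair is a merge; *drop_ortholog*
    removes an ortholog pair, leaving both genes out-map (the repair is a
    replacement prediction over the existing model). ``side`` says which
    side of ``corr`` the genome occupies ('a' or 'b').
    """
    for k, v in rates.items():
        if k not in ("split", "merge", "drop_ortholog"):
            raise ValidationError(f"unknown defect kind {k!r}")
        if not 0.0 <= v <= 1.0:
            raise ValidationError("defect rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    partners = corr.partners_b if side == "b" else corr.partners_a
    other_partners = corr.partners_a if side == "b" else corr.partners_b
    one_to_one = {
        g: next(iter(p))
        for g, p in partners.items()
        if len(p) == 1 and len(other_partners[next(iter(p))]) == 1
    }

    def oriented(local: str, other: str) -> tuple[str, str]:
        return (other, local) if side == "b" else (local, other)

    removed_pairs: set[tuple[str, str]] = set()
    added_pairs: set[tuple[str, str]] = set()
    removed_genes: set[str] = set()
    added_genes: list[GeneMarker] = []
    defects: list[DefectRecord] = []
    used: set[str] = set()
    n_fus = n_fis = 0

    # Fusions: adjacent one-to-one pairs collapse into one chimeric model.
    for chrom in genome.chromosomes:
        genes = genome.genes(chrom)
        i = 0
        while i < len(genes) - 1:
            u, v = genes[i], genes[i + 1]
            if (
                u.gene_id in one_to_one
                and v.gene_id in one_to_one
                and u.gene_id not in used
                and v.gene_id not in used
            ):
                if rng.random() < rates.get("split", 0.0):
                    n_fus += 1
                    fused_id = f"FUS{n_fus:04d}"
                    keep, lose = (u, v) if u.length >= v.length else (v, u)
                    added_genes.append(
                        GeneMarker(fused_id, chrom, u.start, v.end, u.strand)
                    )
                    removed_genes.update((u.gene_id, v.gene_id))
                    removed_pairs.add(oriented(u.gene_id, one_to_one[u.gene_id]))
                    removed_pairs.add(oriented(v.gene_id, one_to_one[v.gene_id]))
                    added_pairs.add(oriented(fused_id, one_to_one[keep.gene_id]))
                    defects.append(
                        DefectRecord(
                            kind="fusion",
                            genome_id=genome.genome_id,
                            removed=(u.gene_id, v.gene_id),
                            added=(fused_id,),
                            query_gene=one_to_one[lose.gene_id],
                            query_genome_id="other",
                            target_chrom=chrom,
                            target_span=(lose.start, lose.end),
                            expected_action="split",
                        )
                    )
                    used.update((u.gene_id, v.gene_id))
                    i += 2
                    continue
            i += 1

    # Fissions: one model becomes two fragments with a small internal gap.
    for g in genome:
        if g.gene_id not in one_to_one or g.gene_id in used or g.length < 600:
            continue
        if rng.random() < rates.get("merge", 0.0):
            n_fis += 1
            frac = rng.uniform(0.35, 0.65)
            cut = g.start + int(g.length * frac)
            gap = min(100, max(1, (g.end - cut) // 4))
            id5, id3 = f"{g.gene_id}_5p", f"{g.gene_id}_3p"
            added_genes.append(GeneMarker(id5, g.chrom, g.start, cut, g.strand))
            added_genes.append(GeneMarker(id3, g.chrom, cut + gap, g.end, g.strand))
            removed_genes.add(g.gene_id)
            removed_pairs.add(oriented(g.gene_id, one_to_one[g.gene_id]))
            defects.append(
                DefectRecord(
                    kind="fission",
                    genome_id=genome.genome_id,
                    removed=(g.gene_id,),
                    added=(id5, id3),
                    query_gene=one_to_one[g.gene_id],
                    query_genome_id="other",
                    target_chrom=g.chrom,
                    target_span=(g.start, g.end),
                    expected_action="merge",
                )
            )
            used.add(g.gene_id)

    # Dropped orthology: the pair vanishes, the models stay.
    for g in genome:
        if g.gene_id not in one_to_one or g.gene_id in used:
            continue
        if rng.random() < rates.get("drop_ortholog", 0.0):
            removed_pairs.add(oriented(g.gene_id, one_to_one[g.gene_id]))
            defects.append(
                DefectRecord(
                    kind="drop_ortholog",
                    genome_id=genome.genome_id,
                    removed=(),
                    added=(),
                    query_gene=one_to_one[g.gene_id],
                    query_genome_id="other",
                    target_chrom=g.chrom,
                    target_span=(g.start, g.end),
                    expected_action="replace",
                )
            )
            used.add(g.gene_id)

    new_genome = Genome(
        genome.genome_id,
        [g for g in genome if g.gene_id not in removed_genes] + added_genes,
    )
    new_corr = CorrespondenceMap(
        (corr.pairs - removed_pairs) | added_pairs
    )
    return new_genome, new_corr, defects


@dataclass(frozen=True)
class OperonAnnotation:
    """An operon: 2+ adjacent genes on one chromosome of one genome."""

    operon_id: str
    chrom: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValidationError("operons contain at least two genes")


def make_operons(
    genome: Genome,
    n: int,
    size_range: tuple[int, int] = (2, 8),
    seed: int = 0,
) -> list[OperonAnnotation]:
    """Plant ``n`` non-overlapping operons of adjacent genes."""
    rng = np.random.default_rng(seed)
    slots = []
    for chrom in genome.chromosomes:
        count = len(genome.genes(chrom))
        pos = 0
        while pos + size_range[0] <= count:
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            size = min(size, count - pos)
            if size >= size_range[0]:
                slots.append((chrom, pos, size))
            pos += size + 1  # one-gene spacer keeps operons non-overlapping
    if len(slots) < n:
        raise ValidationError(
            f"cannot place {n} operons: only {len(slots)} eligible sites"
        )
    chosen = sorted(rng.choice(len(slots), size=n, replace=False).tolist())
    operons = []
    for k, slot_index in enumerate(chosen):
        chrom, pos, size = slots[slot_index]
        members = tuple(
            g.gene_id for g in genome.genes(chrom)[pos : pos + size]
        )
        operons.append(OperonAnnotation(f"OP{k + 1:04d}", chrom, members))
    return operons


def prediction_records_for_defects(
    defects: Iterable[DefectRecord],
    query_genome_id: str,
    target_genome_id: str,
) -> list[PredictionRecord]:
    """Noiseless spliced-alignment records implied by injected defects.

    Each record is what a perfect homology-based predictor would return
    for the defect's out-map query gene: full query coverage, no internal
    stops, target span equal to the true locus of the query's ortholog.
    """
    records = []
    for k, d in enumerate(defects):
        records.append(
            PredictionRecord(
                prediction_id=f"PRED{k + 1:04d}",
                query_gene_id=d.query_gene,
                query_genome_id=query_genome_id,
                target_genome_id=target_genome_id,
                target_chrom=d.target_chrom,
                target_start=d.target_span[0],
                target_end=d.target_span[1],
                query_coverage=1.0,
                has_internal_stop=False,
            )
        )
    return records
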