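"""Maximal synteny block detection between two gene-order genomes.

A candidate is a pair of contiguous gene intervals, one per genome, each
confined to a single chromosome. Genes of each interval partition into

* matched genes -- with at least one ortholog inside the partner interval,
* in-map mismatches -- orthologs exist, but all outside the partner interval,
* out-map mismatches -- no ortholog anywhere (genome-specific genes or
  annotation gaps).

A candidate is valid when matched counts fall within the size limits, both
mismatch ledgers respect their count and percentage caps on both sides, and
an order/strand-consistent system of matched pairs covers every matched gene
on both sides (see :func:`validate_block`). Reported blocks are the valid
candidates that are maximal: no single-gene extension of either interval is
valid, and no reported block has both intervals contained in another
reported block (one-sided containment with a disjoint partner interval is a
*nested* block -- the signature of a segmental duplication -- and is
reported with its parent).

Detection is deterministic: no randomness anywhere, output ordered by
A-chromosome, A-start and descending matched size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import (
    BlockInterval,
    CorrespondenceMap,
    DetectionParams,
    Genome,
    Mode,
    SyntenyBlock,
    classify_markers,
)

__all__ = [
    "BlockCandidate",
    "validate_block",
    "find_synteny_blocks",
    "flag_nested",
    "singleton_blocks",
]

# Canonical precedence of (order, strand) combinations used when labelling a
# block that is feasible under more than one combination.
_ALL_COMBOS: tuple[tuple[str, str], ...] = (
    ("colinear", "consistent"),
    ("inverted", "reversed"),
    ("colinear", "reversed"),
    ("inverted", "consistent"),
)
_MODE_COMBOS: dict[Mode, tuple[tuple[str, str], ...]] = {
    Mode.RS: (("colinear", "consistent"), ("inverted", "reversed")),
    Mode.R_S: _ALL_COMBOS,
    Mode.FREE: _ALL_COMBOS,  # used for labelling only; FREE never rejects
}


@dataclass(frozen=True)
class BlockCandidate:
    """Ordinal interval pair; ordinals are 0-based per chromosome."""

    chrom_a: str
    a_start: int
    a_end: int
    chrom_b: str
    b_start: int
    b_end: int

    def __post_init__(self) -> None:
        if self.a_start > self.a_end or self.b_start > self.b_end:
            raise ValueError("candidate intervals must be non-empty")


@dataclass
class _Ledger:
    matched_a: list[int]
    matched_b: list[int]
    imm_a: list[int]
    imm_b: list[int]
    omm_a: list[int]
    omm_b: list[int]
    edges: list[tuple[int, int]]  # (a_ord, b_ord) correspondence pairs inside


class _PairContext:
    """Anchor geometry of one (chrom_a, chrom_b) pair, precomputed once."""

    def __init__(
        self,
        genome_a: Genome,
        genome_b: Genome,
        corr: CorrespondenceMap,
        chrom_a: str,
        chrom_b: str,
    ):
        self.chrom_a = chrom_a
        self.chrom_b = chrom_b
        self.genes_a = genome_a.genes(chrom_a)
        self.genes_b = genome_b.genes(chrom_b)
        pos_a = {g.gene_id: i for i, g in enumerate(self.genes_a)}
        pos_b = {g.gene_id: i for i, g in enumerate(self.genes_b)}

        self.partners_on_b: list[tuple[int, ...]] = []
        self.inmap_a: list[bool] = []
        for g in self.genes_a:
            ps = corr.partners_a.get(g.gene_id, frozenset())
            self.inmap_a.append(bool(ps))
            self.partners_on_b.append(tuple(sorted(pos_b[p] for p in ps if p in pos_b)))
        self.partners_on_a: list[tuple[int, ...]] = []
        self.inmap_b: list[bool] = []
        for g in self.genes_b:
            ps = corr.partners_b.get(g.gene_id, frozenset())
            self.inmap_b.append(bool(ps))
            self.partners_on_a.append(tuple(sorted(pos_a[p] for p in ps if p in pos_a)))

        self.strand_a = tuple(g.strand for g in self.genes_a)
        self.strand_b = tuple(g.strand for g in self.genes_b)
        self.n_anchor_pairs = sum(len(p) for p in self.partners_on_b)

    def classify(self, c: BlockCandidate) -> _Ledger:
        led = _Ledger([], [], [], [], [], [], [])
        for ai in range(c.a_start, c.a_end + 1):
            inside = [b for b in self.partners_on_b[ai] if c.b_start <= b <= c.b_end]
            if inside:
                led.matched_a.append(ai)
                led.edges.extend((ai, b) for b in inside)
            elif self.inmap_a[ai]:
                led.imm_a.append(ai)
            else:
                led.omm_a.append(ai)
        for bi in range(c.b_start, c.b_end + 1):
            inside_any = any(
                c.a_start <= a <= c.a_end for a in self.partners_on_a[bi]
            )
            if inside_any:
                led.matched_b.append(bi)
            elif self.inmap_b[bi]:
                led.imm_b.append(bi)
            else:
                led.omm_b.append(bi)
        return led

    def edge_strand_consistent(self, a: int, b: int) -> bool:
        return self.strand_a[a] == self.strand_b[b]


def _staircase_feasible(
    rows: Sequence[int],
    cols: Sequence[int],
    edges: frozenset[tuple[int, int]] | set[tuple[int, int]],
) -> Optional[list[tuple[int, int]]]:
    """Monotone covering of rows and cols by edge cells, or None.

    A covering system of matched pairs with no order inversion exists iff a
    staircase lattice path (steps right/down/diagonal) runs from the first
    (row, col) cell to the last, touching only correspondence cells. Ties in
    either coordinate realize tandem co-orthologs. Returns one canonical
    path (diagonal-preferring backtrack) as the matched-pair selection.
    """
    p, q = len(rows), len(cols)
    if p == 0 or q == 0:
        return None
    reach = [[False] * q for _ in range(p)]
    for i in range(p):
        for j in range(q):
            if (rows[i], cols[j]) not in edges:
                continue
            if i == 0 and j == 0:
                reach[i][j] = True
            elif (
                (i > 0 and j > 0 and reach[i - 1][j - 1])
                or (i > 0 and reach[i - 1][j])
                or (j > 0 and reach[i][j - 1])
            ):
                reach[i][j] = True
    if not reach[p - 1][q - 1]:
        return None
    path: list[tuple[int, int]] = []
    i, j = p - 1, q - 1
    while True:
        path.append((rows[i], cols[j]))
        if i == 0 and j == 0:
            break
        if i > 0 and j > 0 and reach[i - 1][j - 1]:
            i, j = i - 1, j - 1
        elif i > 0 and reach[i - 1][j]:
            i -= 1
        else:
            j -= 1
    path.reverse()
    return path


def _combo_selection(
    ctx: _PairContext, led: _Ledger, orientation: str, strand: str
) -> Optional[list[tuple[int, int]]]:
    """Matched-pair selection realizing one (order, strand) combination."""
    want_same = strand == "consistent"
    edges = {
        (a, b)
        for a, b in led.edges
        if ctx.edge_strand_consistent(a, b) == want_same
    }
    rows = sorted(set(led.matched_a))
    cols = sorted(set(led.matched_b))
    if orientation == "inverted":
        cols = cols[::-1]
    return _staircase_feasible(rows, cols, edges)


def _check_candidate(
    ctx: _PairContext, c: BlockCandidate, params: DetectionParams
) -> tuple[bool, str, Optional[_Ledger], Optional[tuple[str, str]], Optional[list]]:
    """Full validity check; returns (ok, reason, ledger, combo, selection)."""
    led = ctx.classify(c)
    n_a = c.a_end - c.a_start + 1
    n_b = c.b_end - c.b_start + 1

    for side, matched, n in (("A", led.matched_a, n_a), ("B", led.matched_b, n_b)):
        k = len(set(matched))
        if k < params.min_size:
            return False, f"matched gene count on side {side} below min_size", led, None, None
        if params.max_size is not None and k > params.max_size:
            return False, f"matched gene count on side {side} above max_size", led, None, None
    for side, mm, n, cap, pct, kind in (
        ("A", led.omm_a, n_a, params.out_map_max_count, params.out_map_max_pct, "out-map"),
        ("B", led.omm_b, n_b, params.out_map_max_count, params.out_map_max_pct, "out-map"),
        ("A", led.imm_a, n_a, params.in_map_max_count, params.in_map_max_pct, "in-map"),
        ("B", led.imm_b, n_b, params.in_map_max_count, params.in_map_max_pct, "in-map"),
    ):
        m = len(mm)
        if cap is not None and m > cap:
            return False, f"{kind} mismatch count on side {side} exceeds cap", led, None, None
        if m * 100.0 > pct * n + 1e-9:
            return False, f"{kind} mismatch percentage on side {side} exceeds cap", led, None, None

    combos = _MODE_COMBOS[params.mode]
    for orientation, strand in combos:
        sel = _combo_selection(ctx, led, orientation, strand)
        if sel is not None:
            return True, "ok", led, (orientation, strand), sel
    if params.mode is Mode.FREE:
        # Content conservation only: every matched gene has a partner inside
        # by construction, so the candidate stands; label it descriptively.
        sel = sorted(set(led.edges))
        rels = {ctx.edge_strand_consistent(a, b) for a, b in led.edges}
        strand = (
            "consistent" if rels == {True}
            else "reversed" if rels == {False}
            else "mixed"
        )
        return True, "ok", led, ("unordered", strand), sel
    return False, "no order/strand-consistent matched-pair cover under mode", led, None, None


def validate_block(
    candidate: BlockCandidate,
    genome_a: Genome,
    genome_b: Genome,
    corr: CorrespondenceMap,
    params: DetectionParams,
) -> tuple[bool, str]:
    """Check one candidate interval pair against the validity conditions.

    Returns ``(ok, diagnostics)`` where diagnostics names the first violated
    condition (size limits, mismatch caps, then order/strand cover).
    """
    for chrom, genome, name in (
        (candidate.chrom_a, genome_a, "A"),
        (candidate.chrom_b, genome_b, "B"),
    ):
        if chrom not in genome.chromosomes:
            raise ValueError(f"chromosome {chrom!r} not in genome {name}")
    na = len(genome_a.genes(candidate.chrom_a))
    nb = len(genome_b.genes(candidate.chrom_b))
    if candidate.a_end >= na or candidate.b_end >= nb:
        raise ValueError("candidate interval exceeds chromosome bounds")
    ctx = _PairContext(genome_a, genome_b, corr, candidate.chrom_a, candidate.chrom_b)
    ok, reason, _, _, _ = _check_candidate(ctx, candidate, params)
    return ok, reason


def _mismatch_slack(params: DetectionParams, n_other: int) -> int:
    """Upper bound on mismatch genes a partner interval can carry."""
    caps = []
    for cap in (params.in_map_max_count, params.out_map_max_count):
        caps.append(cap if cap is not None else n_other)
    return min(sum(caps), n_other)


def _search_pair(
    ctx: _PairContext, params: DetectionParams
) -> dict[BlockCandidate, tuple]:
    """All valid candidates on one chromosome pair, with check results."""
    n_a = len(ctx.genes_a)
    n_b = len(ctx.genes_b)
    out_cap = params.out_map_max_count
    in_cap = params.in_map_max_count
    slack = _mismatch_slack(params, n_b)
    valid: dict[BlockCandidate, tuple] = {}
    cache: dict[BlockCandidate, tuple] = {}

    def check(c: BlockCandidate):
        res = cache.get(c)
        if res is None:
            res = _check_candidate(ctx, c, params)
            cache[c] = res
        return res

    in_pct = params.in_map_max_pct
    out_pct = params.out_map_max_pct

    for a_start in range(n_a):
        omm_lb = 0   # guaranteed out-map mismatches, independent of B interval
        imm_lb = 0   # in-map genes with no partner on chrom_b at all
        anchors = 0  # genes with >= 1 partner on chrom_b
        lo = hi = None
        part_count = [0] * n_b    # partners of the A interval, per B position
        single_pos: list[int] = []  # B position of each single-partner A gene
        for a_end in range(a_start, n_a):
            ps = ctx.partners_on_b[a_end]
            if ps:
                anchors += 1
                lo = ps[0] if lo is None else min(lo, ps[0])
                hi = ps[-1] if hi is None else max(hi, ps[-1])
                for p in ps:
                    part_count[p] += 1
                if len(ps) == 1:
                    single_pos.append(ps[0])
            elif ctx.inmap_a[a_end]:
                imm_lb += 1
            else:
                omm_lb += 1
            if out_cap is not None and omm_lb > out_cap:
                break
            if in_cap is not None and imm_lb > in_cap:
                break
            if anchors < params.min_size:
                continue
            n_a_int = a_end - a_start + 1
            w0 = max(0, lo - slack)
            w1 = min(n_b - 1, hi + slack)
            width = w1 - w0 + 1
            # Prefix sums over the window: matched B genes, guaranteed B-side
            # mismatches (exact), and single-partner A anchors (whose absence
            # from the B interval is a certain in-map mismatch on side A).
            pm = [0] * (width + 1)
            pi = [0] * (width + 1)
            po = [0] * (width + 1)
            for k in range(width):
                b = w0 + k
                is_part = part_count[b] > 0
                pm[k + 1] = pm[k] + (1 if is_part else 0)
                pi[k + 1] = pi[k] + (1 if (not is_part and ctx.inmap_b[b]) else 0)
                po[k + 1] = po[k] + (1 if (not is_part and not ctx.inmap_b[b]) else 0)
            sp = sorted(single_pos)
            import bisect as _bisect

            for b_start in range(w0, w1 + 1):
                for b_end in range(b_start, w1 + 1):
                    k0, k1 = b_start - w0, b_end - w0 + 1
                    omm_b = po[k1] - po[k0]
                    imm_b = pi[k1] - pi[k0]
                    if out_cap is not None and omm_b > out_cap:
                        break
                    if in_cap is not None and imm_b > in_cap:
                        break
                    n_b_int = b_end - b_start + 1
                    matched_b = pm[k1] - pm[k0]
                    if matched_b < params.min_size:
                        continue
                    if params.max_size is not None and matched_b > params.max_size:
                        break
                    if omm_b * 100.0 > out_pct * n_b_int + 1e-9:
                        continue
                    if imm_b * 100.0 > in_pct * n_b_int + 1e-9:
                        continue
                    # certain A-side in-map mismatches: single-partner anchors
                    # whose sole partner lies outside [b_start, b_end]
                    imm_a_lb = imm_lb + (
                        _bisect.bisect_left(sp, b_start)
                        + len(sp)
                        - _bisect.bisect_right(sp, b_end)
                    )
                    if in_cap is not None and imm_a_lb > in_cap:
                        continue
                    if imm_a_lb * 100.0 > in_pct * n_a_int + 1e-9:
                        continue
                    c = BlockCandidate(
                        ctx.chrom_a, a_start, a_end, ctx.chrom_b, b_start, b_end
                    )
                    res = check(c)
                    if res[0]:
                        valid[c] = res

    # Extension maximality: a valid candidate extended by one gene on any of
    # the four ends must not stay valid.
    maximal: dict[BlockCandidate, tuple] = {}
    for c, res in valid.items():
        extensions = []
        if c.a_start > 0:
            extensions.append(
                BlockCandidate(c.chrom_a, c.a_start - 1, c.a_end, c.chrom_b, c.b_start, c.b_end)
            )
        if c.a_end < n_a - 1:
            extensions.append(
                BlockCandidate(c.chrom_a, c.a_start, c.a_end + 1, c.chrom_b, c.b_start, c.b_end)
            )
        if c.b_start > 0:
            extensions.append(
                BlockCandidate(c.chrom_a, c.a_start, c.a_end, c.chrom_b, c.b_start - 1, c.b_end)
            )
        if c.b_end < n_b - 1:
            extensions.append(
                BlockCandidate(c.chrom_a, c.a_start, c.a_end, c.chrom_b, c.b_start, c.b_end + 1)
            )
        if not any(check(e)[0] for e in extensions):
            maximal[c] = res

    # Containment dominance: both intervals inside another extension-maximal
    # candidate's intervals => only the outer one is reported directly.
    keys = list(maximal)
    kept: dict[BlockCandidate, tuple] = {}
    for c in keys:
        dominated = any(
            d != c
            and d.a_start <= c.a_start
            and c.a_end <= d.a_end
            and d.b_start <= c.b_start
            and c.b_end <= d.b_end
            for d in keys
        )
        if not dominated:
            kept[c] = maximal[c]
    return kept


def _build_block(
    block_id: str,
    genome_a: Genome,
    genome_b: Genome,
    ctx: _PairContext,
    c: BlockCandidate,
    res: tuple,
) -> SyntenyBlock:
    _, _, led, combo, sel = res
    ga = ctx.genes_a
    gb = ctx.genes_b
    interval_a = BlockInterval(
        c.chrom_a, c.a_start, c.a_end, ga[c.a_start].start, ga[c.a_end].end
    )
    interval_b = BlockInterval(
        c.chrom_b, c.b_start, c.b_end, gb[c.b_start].start, gb[c.b_end].end
    )
    pairs = tuple(
        (ga[a].gene_id, gb[b].gene_id) for a, b in sorted(sel)
    )
    orientation, strand = combo
    return SyntenyBlock(
        block_id=block_id,
        genome_a_id=genome_a.genome_id,
        genome_b_id=genome_b.genome_id,
        interval_a=interval_a,
        interval_b=interval_b,
        matched_pairs=pairs,
        in_map_mismatches_a=frozenset(ga[i].gene_id for i in led.imm_a),
        in_map_mismatches_b=frozenset(gb[i].gene_id for i in led.imm_b),
        out_map_mismatches_a=frozenset(ga[i].gene_id for i in led.omm_a),
        out_map_mismatches_b=frozenset(gb[i].gene_id for i in led.omm_b),
        orientation=orientation,
        strand_pattern=strand,
    )


def find_synteny_blocks(
    genome_a: Genome,
    genome_b: Genome,
    corr: CorrespondenceMap,
    params: DetectionParams | None = None,
) -> list[SyntenyBlock]:
    """Find all maximal synteny blocks between two genomes.

    Anchor-guided search: only chromosome pairs sharing enough ortholog
    anchors are scanned, candidate A-intervals stop growing once their
    unavoidable mismatch load exceeds the count caps, and partner intervals
    are enumerated inside the anchor window padded by the admissible
    mismatch slack. Semantics are fixed by :func:`validate_block` plus
    maximality, and are independently realized by
    :func:`syntenyscan.oracle.enumerate_blocks_oracle`.

    Empty genomes or an empty correspondence yield an empty list.
    """
    if params is None:
        params = DetectionParams()
    found: list[tuple[_PairContext, BlockCandidate, tuple]] = []
    for chrom_a in genome_a.chromosomes:
        for chrom_b in genome_b.chromosomes:
            ctx = _PairContext(genome_a, genome_b, corr, chrom_a, chrom_b)
            if ctx.n_anchor_pairs < params.min_size:
                continue
            for c, res in _search_pair(ctx, params).items():
                found.append((ctx, c, res))

    found.sort(
        key=lambda t: (
            t[1].chrom_a,
            t[1].a_start,
            -(t[1].a_end - t[1].a_start),
            t[1].chrom_b,
            t[1].b_start,
            t[1].b_end,
        )
    )
    blocks = [
        _build_block(f"SB{i + 1:05d}", genome_a, genome_b, ctx, c, res)
        for i, (ctx, c, res) in enumerate(found)
    ]
    blocks = flag_nested(blocks)
    if not params.report_nested:
        blocks = [b for b in blocks if not b.nested]
    return blocks


def flag_nested(blocks: list[SyntenyBlock]) -> list[SyntenyBlock]:
    """Set nested flags and parent ids on a detection result.

    A block is nested when its interval in one genome lies strictly inside
    a larger block's interval in that genome while its interval in the
    other genome is disjoint from that block's. The parent is the
    containing block with the most matched genes (ties: first block id).
    """
    for b in blocks:
        parents = []
        for other in blocks:
            if other is b:
                continue
            contains_a = (
                other.interval_a.contains(b.interval_a)
                and other.interval_a != b.interval_a
            )
            contains_b = (
                other.interval_b.contains(b.interval_b)
                and other.interval_b != b.interval_b
            )
            if (contains_a and other.interval_b.disjoint(b.interval_b)) or (
                contains_b and other.interval_a.disjoint(b.interval_a)
            ):
                parents.append(other)
        if parents:
            parents.sort(key=lambda o: (-o.n_matched_a, o.block_id))
            b.nested = True
            b.parent_id = parents[0].block_id
        else:
            b.nested = False
            b.parent_id = None
    return blocks


def singleton_blocks(
    genome_a: Genome,
    genome_b: Genome,
    corr: CorrespondenceMap,
    blocks: Iterable[SyntenyBlock],
) -> list[SyntenyBlock]:
    """Degenerate one-gene "blocks" for in-map genes not covered by blocks.

    Used only by coverage accounting: including them can only raise the
    covered fraction. Each uncovered in-map gene is paired with its
    lexicographically first partner.
    """
    status = classify_markers(genome_a, genome_b, corr)
    covered_a: set[str] = set()
    covered_b: set[str] = set()
    blocks = list(blocks)
    for blk in blocks:
        ga = genome_a.genes(blk.interval_a.chrom)
        covered_a.update(
            ga[i].gene_id for i in range(blk.interval_a.start_ord, blk.interval_a.end_ord + 1)
        )
        gb = genome_b.genes(blk.interval_b.chrom)
        covered_b.update(
            gb[i].gene_id for i in range(blk.interval_b.start_ord, blk.interval_b.end_ord + 1)
        )

    singles: dict[tuple[str, str], SyntenyBlock] = {}

    def make(gene_a_id: str, gene_b_id: str) -> None:
        key = (gene_a_id, gene_b_id)
        if key in singles:
            return
        chrom_a, ia = genome_a.position(gene_a_id)
        chrom_b, ib = genome_b.position(gene_b_id)
        ga = genome_a.gene(gene_a_id)
        gb = genome_b.gene(gene_b_id)
        singles[key] = SyntenyBlock(
            block_id=f"SG{len(singles) + 1:05d}",
            genome_a_id=genome_a.genome_id,
            genome_b_id=genome_b.genome_id,
            interval_a=BlockInterval(chrom_a, ia, ia, ga.start, ga.end),
            interval_b=BlockInterval(chrom_b, ib, ib, gb.start, gb.end),
            matched_pairs=((gene_a_id, gene_b_id),),
            in_map_mismatches_a=frozenset(),
            in_map_mismatches_b=frozenset(),
            out_map_mismatches_a=frozenset(),
            out_map_mismatches_b=frozenset(),
            orientation="unordered",
            strand_pattern=(
                "consistent" if ga.strand == gb.strand else "reversed"
            ),
            singleton=True,
        )

    for gid in sorted(status.in_map_a - covered_a):
        make(gid, min(corr.partners_a[gid]))
    for gid in sorted(status.in_map_b - covered_b):
        make(min(corr.partners_b[gid]), gid)
    return list(singles.values())
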