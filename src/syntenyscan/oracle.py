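"""Brute-force enumeration oracle for synteny block detection.

Re-derives the block semantics from first principles: every interval pair
on every chromosome pair is generated and checked by straight-line code
that touches only the raw :class:`Genome` and :class:`CorrespondenceMap`
objects. Intended for small inputs (tens of genes per genome); the main
search in :mod:`syntenyscan.detection` must agree with this module on any
input, and the test suite enforces that on randomized instances.

The order/strand cover here is decided by a memoized top-down search over
partner selections rather than the bottom-up staircase table used by the
main path, so the two implementations share no feasibility code.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Optional

from .model import (
    BlockInterval,
    CorrespondenceMap,
    DetectionParams,
    Genome,
    Mode,
    SyntenyBlock,
)

__all__ = ["enumerate_blocks_oracle"]


def _cover_search(
    rows: tuple[int, ...], cols: tuple[int, ...], edges: frozenset[tuple[int, int]]
) -> Optional[tuple[tuple[int, int], ...]]:
    """Top-down search for a monotone covering selection of matched pairs.

    Walks both ordinal lists front-to-back; at each step the current
    (row, col) cell must be a correspondence edge, after which the walk may
    advance the row, the column, or both. Succeeds when both lists are
    exhausted together.
    """
    if not rows or not cols:
        return None

    @lru_cache(maxsize=None)
    def go(i: int, j: int) -> Optional[tuple[tuple[int, int], ...]]:
        if (rows[i], cols[j]) not in edges:
            return None
        here = ((rows[i], cols[j]),)
        if i == len(rows) - 1 and j == len(cols) - 1:
            return here
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < len(rows) and nj < len(cols):
                rest = go(ni, nj)
                if rest is not None:
                    return here + rest
        return None

    return go(0, 0)


def enumerate_blocks_oracle(
    genome_a: Genome,
    genome_b: Genome,
    corr: CorrespondenceMap,
    params: DetectionParams | None = None,
) -> list[SyntenyBlock]:
    """Enumerate all maximal synteny blocks by exhaustive interval search."""
    if params is None:
        params = DetectionParams()
    mode = params.mode

    partners_a = corr.partners_a
    partners_b = corr.partners_b

    def evaluate(chrom_a, chrom_b, a0, a1, b0, b1):
        """Classify and check one candidate from scratch; None if invalid."""
        genes_a = genome_a.genes(chrom_a)[a0 : a1 + 1]
        genes_b = genome_b.genes(chrom_b)[b0 : b1 + 1]
        ids_b_inside = {g.gene_id for g in genes_b}
        ids_a_inside = {g.gene_id for g in genes_a}

        matched_a, imm_a, omm_a = [], [], []
        edges_by_id = []
        for g in genes_a:
            ps = partners_a.get(g.gene_id, frozenset())
            inside = sorted(ps & ids_b_inside)
            if inside:
                matched_a.append(g.gene_id)
                edges_by_id.extend((g.gene_id, p) for p in inside)
            elif ps:
                imm_a.append(g.gene_id)
            else:
                omm_a.append(g.gene_id)
        matched_b, imm_b, omm_b = [], [], []
        for g in genes_b:
            ps = partners_b.get(g.gene_id, frozenset())
            if ps & ids_a_inside:
                matched_b.append(g.gene_id)
            elif ps:
                imm_b.append(g.gene_id)
            else:
                omm_b.append(g.gene_id)

        n_a, n_b = len(genes_a), len(genes_b)
        if len(matched_a) < params.min_size or len(matched_b) < params.min_size:
            return None
        if params.max_size is not None and (
            len(matched_a) > params.max_size or len(matched_b) > params.max_size
        ):
            return None
        for mm, n, cap, pct in (
            (omm_a, n_a, params.out_map_max_count, params.out_map_max_pct),
            (omm_b, n_b, params.out_map_max_count, params.out_map_max_pct),
            (imm_a, n_a, params.in_map_max_count, params.in_map_max_pct),
            (imm_b, n_b, params.in_map_max_count, params.in_map_max_pct),
        ):
            if cap is not None and len(mm) > cap:
                return None
            if len(mm) * 100.0 > pct * n + 1e-9:
                return None

        # Order/strand cover, by ordinal within the candidate.
        ord_a = {g.gene_id: i for i, g in enumerate(genes_a)}
        ord_b = {g.gene_id: i for i, g in enumerate(genes_b)}
        strand_of = {g.gene_id: g.strand for g in genes_a}
        strand_of.update({g.gene_id: g.strand for g in genes_b})
        rows = tuple(sorted(ord_a[g] for g in matched_a))
        cols_fwd = tuple(sorted(ord_b[g] for g in matched_b))
        gene_a_at = {ord_a[g]: g for g in matched_a}
        gene_b_at = {ord_b[g]: g for g in matched_b}

        def edge_set(want_same: bool) -> frozenset[tuple[int, int]]:
            return frozenset(
                (ord_a[ga], ord_b[gb])
                for ga, gb in edges_by_id
                if (strand_of[ga] == strand_of[gb]) == want_same
            )

        combos = [
            ("colinear", "consistent", cols_fwd, edge_set(True)),
            ("inverted", "reversed", cols_fwd[::-1], edge_set(False)),
            ("colinear", "reversed", cols_fwd, edge_set(False)),
            ("inverted", "consistent", cols_fwd[::-1], edge_set(True)),
        ]
        if mode is Mode.RS:
            combos = combos[:2]
        selection = None
        label = None
        for orientation, strand, cols, edges in combos:
            sel = _cover_search(rows, cols, edges)
            if sel is not None:
                selection = sel
                label = (orientation, strand)
                break
        if selection is None:
            if mode is not Mode.FREE:
                return None
            rels = {
                strand_of[ga] == strand_of[gb] for ga, gb in edges_by_id
            }
            label = (
                "unordered",
                "consistent" if rels == {True}
                else "reversed" if rels == {False}
                else "mixed",
            )
            pairs = tuple(
                sorted(
                    (ord_a[ga], ord_b[gb]) for ga, gb in edges_by_id
                )
            )
        else:
            pairs = tuple(sorted(selection))

        return {
            "pairs": tuple((gene_a_at[i], gene_b_at[j]) for i, j in pairs),
            "imm_a": frozenset(imm_a),
            "imm_b": frozenset(imm_b),
            "omm_a": frozenset(omm_a),
            "omm_b": frozenset(omm_b),
            "label": label,
            "genes_a": genes_a,
            "genes_b": genes_b,
        }

    valid: dict[tuple, dict] = {}
    for chrom_a in genome_a.chromosomes:
        n_a = len(genome_a.genes(chrom_a))
        for chrom_b in genome_b.chromosomes:
            n_b = len(genome_b.genes(chrom_b))
            for a0 in range(n_a):
                for a1 in range(a0, n_a):
                    for b0 in range(n_b):
                        for b1 in range(b0, n_b):
                            res = evaluate(chrom_a, chrom_b, a0, a1, b0, b1)
                            if res is not None:
                                valid[(chrom_a, a0, a1, chrom_b, b0, b1)] = res

    def is_valid(key) -> bool:
        if key in valid:
            return True
        chrom_a, a0, a1, chrom_b, b0, b1 = key
        if a0 < 0 or b0 < 0:
            return False
        if a1 >= len(genome_a.genes(chrom_a)) or b1 >= len(genome_b.genes(chrom_b)):
            return False
        return evaluate(chrom_a, chrom_b, a0, a1, b0, b1) is not None

    maximal = {}
    for key, res in valid.items():
        chrom_a, a0, a1, chrom_b, b0, b1 = key
        grown = [
            (chrom_a, a0 - 1, a1, chrom_b, b0, b1),
            (chrom_a, a0, a1 + 1, chrom_b, b0, b1),
            (chrom_a, a0, a1, chrom_b, b0 - 1, b1),
            (chrom_a, a0, a1, chrom_b, b0, b1 + 1),
        ]
        if not any(is_valid(k) for k in grown):
            maximal[key] = res

    kept = {}
    for key, res in maximal.items():
        chrom_a, a0, a1, chrom_b, b0, b1 = key
        dominated = any(
            k != key
            and k[0] == chrom_a
            and k[3] == chrom_b
            and k[1] <= a0
            and a1 <= k[2]
            and k[4] <= b0
            and b1 <= k[5]
            for k in maximal
        )
        if not dominated:
            kept[key] = res

    ordered = sorted(
        kept, key=lambda k: (k[0], k[1], -(k[2] - k[1]), k[3], k[4], k[5])
    )
    blocks = []
    for i, key in enumerate(ordered):
        chrom_a, a0, a1, chrom_b, b0, b1 = key
        res = kept[key]
        genes_a = res["genes_a"]
        genes_b = res["genes_b"]
        blocks.append(
            SyntenyBlock(
                block_id=f"SB{i + 1:05d}",
                genome_a_id=genome_a.genome_id,
                genome_b_id=genome_b.genome_id,
                interval_a=BlockInterval(
                    chrom_a, a0, a1, genes_a[0].start, genes_a[-1].end
                ),
                interval_b=BlockInterval(
                    chrom_b, b0, b1, genes_b[0].start, genes_b[-1].end
                ),
                matched_pairs=res["pairs"],
                in_map_mismatches_a=res["imm_a"],
                in_map_mismatches_b=res["imm_b"],
                out_map_mismatches_a=res["omm_a"],
                out_map_mismatches_b=res["omm_b"],
                orientation=res["label"][0],
                strand_pattern=res["label"][1],
            )
        )

    # Nested flagging: one-sided strict containment with a disjoint partner.
    for b in blocks:
        parents = []
        for other in blocks:
            if other is b:
                continue
            in_a = other.interval_a.contains(b.interval_a) and other.interval_a != b.interval_a
            in_b = other.interval_b.contains(b.interval_b) and other.interval_b != b.interval_b
            if (in_a and other.interval_b.disjoint(b.interval_b)) or (
                in_b and other.interval_a.disjoint(b.interval_a)
            ):
                parents.append(other)
        if parents:
            parents.sort(key=lambda o: (-o.n_matched_a, o.block_id))
            b.nested = True
            b.parent_id = parents[0].block_id
    if not params.report_nested:
        blocks = [b for b in blocks if not b.nested]
    return blocks
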