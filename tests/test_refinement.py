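"""Prediction filtering, action classification, bookkeeping and orthology."""

from __future__ import annotations

import numpy as np
import pytest

from syntenyscan.model import (
    CorrespondenceMap,
    DetectionParams,
    GeneMarker,
    Genome,
    ValidationError,
    classify_markers,
)
from syntenyscan.detection import find_synteny_blocks
from syntenyscan.refinement import (
    OrthologAssignment,
    PredictionRecord,
    RefinementAction,
    RefinementConfig,
    apply_actions,
    assign_orthologs,
    classify_prediction,
    filter_predictions,
    outmap_candidates,
    percent_identity,
)

from conftest import build_pair, identity_instance


def record(**kwargs) -> PredictionRecord:
    base = dict(
        prediction_id="p1", query_gene_id="q1", query_genome_id="A",
        target_genome_id="B", target_chrom="chr1",
        target_start=100, target_end=900, query_coverage=1.0,
    )
    base.update(kwargs)
    return PredictionRecord(**base)


class TestOutmapCandidates:
    def test_clean_blocks_emit_nothing(self):
        genome_a, genome_b, corr = identity_instance(5)
        blocks = find_synteny_blocks(genome_a, genome_b, corr, DetectionParams())
        status = classify_markers(genome_a, genome_b, corr)
        assert outmap_candidates(blocks, status) == []

    def test_embedded_out_map_gene_targets_partner_interval(self):
        """One ortholog-less gene inside an otherwise perfect region becomes
        a candidate whose search space is the block's partner interval."""
        layout_a = [(f"g{i}", "c1", "+") for i in range(6)]
        layout_b = [(f"h{i}", "c1", "+") for i in range(6)]
        pairs = [(f"g{i}", f"h{i}") for i in range(6) if i != 3]
        genome_a, genome_b, corr = build_pair(layout_a, layout_b, pairs)
        params = DetectionParams(out_map_max_count=2, out_map_max_pct=100.0)
        blocks = find_synteny_blocks(genome_a, genome_b, corr, params)
        status = classify_markers(genome_a, genome_b, corr)
        cands = outmap_candidates(blocks, status)
        big = max(blocks, key=lambda b: b.size_genes)
        assert ("g3", "a", big.block_id, big.interval_b) in cands
        assert ("h3", "b", big.block_id, big.interval_a) in cands

    def test_candidate_count_matches_ledger_recount(self, rng):
        from conftest import random_instance

        for _ in range(6):
            genome_a, genome_b, corr = random_instance(rng)
            params = DetectionParams(out_map_max_count=3, in_map_max_count=1)
            blocks = find_synteny_blocks(genome_a, genome_b, corr, params)
            status = classify_markers(genome_a, genome_b, corr)
            cands = outmap_candidates(blocks, status)
            expected = sum(
                len(b.out_map_mismatches_a) + len(b.out_map_mismatches_b)
                for b in blocks
            )
            assert len(cands) == expected


class TestFilterPredictions:
    @pytest.mark.parametrize(
        "coverage,stop,kept",
        [
            (0.59, False, False),  # just below the published threshold
            (0.60, False, True),   # boundary inclusive: "at least 60%"
            (0.95, True, False),   # internal stop codon always rejects
            (1.0, False, True),
        ],
    )
    def test_boundary_behavior(self, coverage, stop, kept):
        recs = [record(query_coverage=coverage, has_internal_stop=stop)]
        assert bool(filter_predictions(recs)) is kept

    def test_idempotent_and_order_independent(self, rng):
        recs = [
            record(prediction_id=f"p{i}", query_coverage=float(c))
            for i, c in enumerate(rng.uniform(0, 1, 30))
        ]
        once = filter_predictions(recs)
        assert filter_predictions(once) == once
        shuffled = list(recs)
        rng.shuffle(shuffled)
        assert {r.prediction_id for r in filter_predictions(shuffled)} == {
            r.prediction_id for r in once
        }


class TestClassifyPrediction:
    def _target(self):
        return Genome("B", [
            GeneMarker("m1", "chr1", 1_000, 3_000, "+"),
            GeneMarker("m2", "chr1", 5_000, 6_000, "+"),
            GeneMarker("m3", "chr1", 6_200, 7_500, "+"),
        ])

    def test_intergenic_prediction_is_new_gene(self):
        act = classify_prediction(
            record(target_start=3_500, target_end=4_500),
            self._target(), in_map_target=frozenset(),
        )
        assert act.kind == "new_gene"
        assert act.new_models == (("chr1", 3_500, 4_500, "+"),)

    def test_prediction_over_out_map_model_replaces_it(self):
        act = classify_prediction(
            record(target_start=900, target_end=3_100),
            self._target(), in_map_target=frozenset(),
        )
        assert act.kind == "replace"
        assert act.removed == ("m1",)

    def test_weaker_prediction_is_discarded(self):
        act = classify_prediction(
            record(target_start=900, target_end=3_100, query_coverage=0.7,
                   target_support=0.9),
            self._target(), in_map_target=frozenset(),
        )
        assert act.kind == "discard"

    def test_partial_hit_on_chimeric_model_splits_it(self):
        """A prediction covering only part of an in-map model indicates a
        fused model: split into the predicted piece plus the remainder."""
        act = classify_prediction(
            record(target_start=1_000, target_end=1_800),
            self._target(), in_map_target=frozenset({"m1"}),
        )
        assert act.kind == "split"
        assert act.removed == ("m1",)
        assert len(act.new_models) == 2
        spans = sorted((s, e) for _, s, e, _ in act.new_models)
        assert spans == [(1_000, 1_800), (1_801, 3_000)]

    def test_near_complete_hit_is_redundant(self):
        act = classify_prediction(
            record(target_start=1_000, target_end=2_950),
            self._target(), in_map_target=frozenset({"m1"}),
        )
        assert act.kind == "discard"
        assert "redundant" in act.rule

    def test_prediction_spanning_adjacent_fragments_merges_them(self):
        """Two fragment models under one prediction merge into one model
        (the published two-into-one curation case)."""
        act = classify_prediction(
            record(target_start=4_900, target_end=7_600),
            self._target(), in_map_target=frozenset(),
        )
        assert act.kind == "merge"
        assert act.removed == ("m2", "m3")
        assert act.new_models == (("chr1", 5_000, 7_500, "+"),)

    def test_trusted_genome_models_never_rewritten(self):
        cfg = RefinementConfig(trusted_genome_id="B")
        act = classify_prediction(
            record(target_start=900, target_end=3_100),
            self._target(), in_map_target=frozenset(), config=cfg,
        )
        assert act.kind == "discard"
        act = classify_prediction(
            record(target_start=4_900, target_end=7_600),
            self._target(), in_map_target=frozenset(), config=cfg,
        )
        assert act.kind == "discard"

    def test_partial_hit_on_trusted_model_merges_query_fragments(self):
        """When the partially-hit in-map model lives in the trusted genome,
        the defect is on the query side: the query gene is merged with the
        hit model's adjacent ortholog."""
        trusted = Genome("T", [GeneMarker("g1", "cA", 1_000, 4_000, "+")])
        draft = Genome("D", [
            GeneMarker("r", "cB", 500, 1_800, "+"),
            GeneMarker("q", "cB", 1_900, 3_000, "+"),
        ])
        corr = CorrespondenceMap([("g1", "r")])
        rec = record(
            query_gene_id="q", query_genome_id="D", target_genome_id="T",
            target_chrom="cA", target_start=2_500, target_end=4_000,
        )
        act = classify_prediction(
            rec, trusted, in_map_target={"g1"}, corr=corr, query_genome=draft,
            config=RefinementConfig(trusted_genome_id="T"),
        )
        assert act.kind == "merge"
        assert act.removed == ("q", "r")
        assert act.target_genome_id == "D"
        assert act.new_models == (("cB", 500, 3_000, "+"),)

    def test_unknown_chromosome_raises(self):
        with pytest.raises(ValidationError):
            classify_prediction(
                record(target_chrom="nope"), self._target(), frozenset()
            )


class TestApplyActions:
    def _genome(self, n=10):
        return Genome("B", [
            GeneMarker(f"m{i}", "c1", 1 + i * 1_000, 900 + i * 1_000, "+")
            for i in range(n)
        ])

    def test_split_adds_one_gene(self):
        genome = self._genome(10)
        act = RefinementAction(
            kind="split", target_genome_id="B", removed=("m4",),
            new_models=(("c1", 4_001, 4_400, "+"), ("c1", 4_401, 4_900, "+")),
        )
        revised, report = apply_actions(genome, [act])
        assert len(revised) == 11
        assert report.identity_holds()

    def test_merge_removes_one_gene(self):
        genome = self._genome(10)
        act = RefinementAction(
            kind="merge", target_genome_id="B", removed=("m4", "m5"),
            new_models=(("c1", 4_001, 5_900, "+"),),
        )
        revised, report = apply_actions(genome, [act])
        assert len(revised) == 9
        assert report.merged_genes == 2
        assert report.identity_holds()

    def test_conflicting_actions_rejected(self):
        genome = self._genome(5)
        a1 = RefinementAction(
            kind="split", target_genome_id="B", removed=("m2",),
            new_models=(("c1", 2_001, 2_400, "+"), ("c1", 2_401, 2_900, "+")),
        )
        a2 = RefinementAction(
            kind="merge", target_genome_id="B", removed=("m2", "m3"),
            new_models=(("c1", 2_001, 3_900, "+"),),
        )
        with pytest.raises(ValidationError, match="m2"):
            apply_actions(genome, [a1, a2])

    def test_random_action_batches_respect_identity(self, rng):
        """The gene-count identity initial - deleted + added = final holds
        for arbitrary consistent batches."""
        for _ in range(10):
            genome = self._genome(20)
            ids = [g.gene_id for g in genome]
            rng.shuffle(ids)
            actions, cursor = [], 0
            for kind in rng.choice(
                ["split", "merge", "new_gene", "replace"], size=6
            ):
                if kind == "split":
                    gid = ids[cursor]; cursor += 1
                    g = genome.gene(gid)
                    mid = (g.start + g.end) // 2
                    actions.append(RefinementAction(
                        kind="split", target_genome_id="B", removed=(gid,),
                        new_models=((g.chrom, g.start, mid, g.strand),
                                    (g.chrom, mid + 1, g.end, g.strand)),
                    ))
                elif kind == "merge":
                    g1, g2 = ids[cursor], ids[cursor + 1]; cursor += 2
                    ga, gb = genome.gene(g1), genome.gene(g2)
                    actions.append(RefinementAction(
                        kind="merge", target_genome_id="B",
                        removed=tuple(sorted((g1, g2))),
                        new_models=((ga.chrom, min(ga.start, gb.start),
                                     max(ga.end, gb.end), ga.strand),),
                    ))
                elif kind == "replace":
                    gid = ids[cursor]; cursor += 1
                    g = genome.gene(gid)
                    actions.append(RefinementAction(
                        kind="replace", target_genome_id="B", removed=(gid,),
                        new_models=((g.chrom, g.start, g.end + 50, g.strand),),
                    ))
                else:
                    actions.append(RefinementAction(
                        kind="new_gene", target_genome_id="B",
                        new_models=(("c2", 1 + cursor * 100, 90 + cursor * 100, "+"),),
                    ))
            revised, report = apply_actions(genome, actions)
            assert report.identity_holds()
            assert report.final_genes == len(revised)


class TestPercentIdentity:
    def test_identical_sequences(self):
        assert percent_identity("MKVLA", "MKVLA") == pytest.approx(100.0)

    def test_single_substitution_no_gaps(self):
        assert percent_identity("AAAA", "AATA") == pytest.approx(75.0)

    def test_non_amino_acid_rejected(self):
        with pytest.raises(ValidationError):
            percent_identity("MKV1", "MKVL")
        with pytest.raises(ValidationError):
            percent_identity("", "MKVL")

    def test_agrees_with_dp_oracle_on_short_pairs(self, rng):
        """An independent affine-gap DP (same scoring) reproduces the PID
        within one point on random short peptide pairs."""
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        aas = "ACDEFGHIKLMNPQRSTVWY"

        def oracle_pid(a, b, open_=-10.0, ext=-0.5):
            # Gotoh with full traceback over co-optimal alignments; returns
            # the best PID among them (depth-limited enumeration).
            n, m = len(a), len(b)
            NEG = float("-inf")
            M = [[NEG] * (m + 1) for _ in range(n + 1)]
            X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
            Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
            M[0][0] = 0.0
            for i in range(1, n + 1):
                X[i][0] = open_ + ext * (i - 1)
            for j in range(1, m + 1):
                Y[0][j] = open_ + ext * (j - 1)
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    s = blosum[a[i - 1], b[j - 1]]
                    M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
                    X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + ext,
                                  Y[i - 1][j] + open_)
                    Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + ext,
                                  X[i][j - 1] + open_)
            best_score = max(M[n][m], X[n][m], Y[n][m])

            best = [0.0]

            def walk(i, j, state, ident, cols):
                if i == 0 and j == 0:
                    best[0] = max(best[0], 100.0 * ident / cols if cols else 0.0)
                    return
                if state == "M":
                    s = blosum[a[i - 1], b[j - 1]]
                    for prev in ("M", "X", "Y"):
                        val = {"M": M, "X": X, "Y": Y}[prev][i - 1][j - 1]
                        if val + s == M[i][j]:
                            walk(i - 1, j - 1, prev,
                                 ident + (a[i - 1] == b[j - 1]), cols + 1)
                elif state == "X":
                    if i == 0:
                        return
                    for prev, pen in (("M", open_), ("X", ext), ("Y", open_)):
                        val = {"M": M, "X": X, "Y": Y}[prev][i - 1][j]
                        if val + pen == X[i][j]:
                            walk(i - 1, j, prev, ident, cols + 1)
                else:
                    if j == 0:
                        return
                    for prev, pen in (("M", open_), ("Y", ext), ("X", open_)):
                        val = {"M": M, "X": X, "Y": Y}[prev][i][j - 1]
                        if val + pen == Y[i][j]:
                            walk(i, j - 1, prev, ident, cols + 1)

            for state, table in (("M", M), ("X", X), ("Y", Y)):
                if table[n][m] == best_score:
                    walk(n, m, state, 0, 0)
            return best[0], best_score

        for _ in range(15):
            a = "".join(rng.choice(list(aas), size=int(rng.integers(3, 10))))
            b = "".join(rng.choice(list(aas), size=int(rng.integers(3, 10))))
            got = percent_identity(a, b)
            want, _ = oracle_pid(a, b)
            assert got == pytest.approx(want, abs=1.0), (a, b)


class TestAssignOrthologs:
    @pytest.mark.parametrize(
        "pid,e,accepted",
        [
            (40.0, 1e-10, True),   # both boundaries inclusive
            (39.9, 1e-10, False),
            (40.0, 2e-10, False),
            (85.0, 1e-50, True),
        ],
    )
    def test_threshold_boundaries(self, pid, e, accepted):
        got = assign_orthologs([OrthologAssignment("a1", "b1", pid, e)])
        assert bool(got) is accepted

    def test_merging_adds_only_novel_pairs_and_stays_symmetric(self):
        corr = CorrespondenceMap([("a1", "b1")])
        cands = [
            OrthologAssignment("a1", "b1", 90.0, 1e-40),  # already present
            OrthologAssignment("a2", "b2", 55.0, 1e-20),
            OrthologAssignment("a3", "b3", 10.0, 1e-20),  # rejected
        ]
        accepted, merged = assign_orthologs(cands, corr=corr)
        assert {(p.gene_a, p.gene_b) for p in accepted} == {("a1", "b1"), ("a2", "b2")}
        assert len(merged) == 2
        assert merged.partners_a["a2"] == frozenset({"b2"})
        assert merged.partners_b["b2"] == frozenset({"a2"})
        assert "a3" not in merged.partners_a
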