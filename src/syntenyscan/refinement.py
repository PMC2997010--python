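"""Synteny-guided annotation refinement.

Out-map mismatch genes inside synteny blocks usually mean one of two
things: a genome-specific gene, or a defective/missing gene model in the
partner genome. Given spliced-alignment prediction records produced by an
external homology-based predictor (the package never runs one itself),
this module filters them, classifies each into a curation action
(new gene, split, merge, replace, or discard with a reason), applies the
actions with strict gene-count bookkeeping, and accepts new ortholog
pairs by percent identity and e-value.

The decision tree is asymmetric by design: one genome may be declared
*trusted* (well curated), in which case its models are never rewritten --
a prediction implicating a trusted model instead drives a merge of the
draft-genome models, or is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import (
    BlockInterval,
    CorrespondenceMap,
    GeneMarker,
    Genome,
    MarkerStatus,
    SyntenyBlock,
    ValidationError,
)

__all__ = [
    "PredictionRecord",
    "RefinementAction",
    "RefinementConfig",
    "OrthologAssignment",
    "ChangeReport",
    "outmap_candidates",
    "filter_predictions",
    "classify_prediction",
    "apply_actions",
    "percent_identity",
    "assign_orthologs",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PredictionRecord:
    """One spliced-alignment gene prediction from an external aligner.

    ``query_coverage`` is the fraction of the query protein covered by
    the prediction (in [0, 1]); ``target_support`` is the coverage the
    overlapped existing model already enjoys from its own evidence, used
    when arbitrating replacements; ``companion_span`` optionally carries
    the re-prediction of the hit model's retained ortholog against the
    same region (reciprocal evidence for the split branch).
    """

    prediction_id: str
    query_gene_id: str
    query_genome_id: str
    target_genome_id: str
    target_chrom: str
    target_start: int
    target_end: int
    query_coverage: float
    has_internal_stop: bool = False
    target_strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()
    pid: Optional[float] = None
    e_value: Optional[float] = None
    target_support: float = 0.0
    companion_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValidationError("query_coverage must lie in [0, 1]")
        if self.target_start > self.target_end:
            raise ValidationError("target span is inverted")
        last = None
        for s, e in self.exons:
            if s > e or s < self.target_start or e > self.target_end:
                raise ValidationError("exon outside target span")
            if last is not None and s <= last:
                raise ValidationError("exons overlap or are unordered")
            last = e


@dataclass(frozen=True)
class RefinementAction:
    """A curation decision derived from one prediction."""

    kind: str  # new_gene | split | merge | replace | discard
    target_genome_id: str
    removed: tuple[str, ...] = ()
    new_models: tuple[tuple[str, int, int, str], ...] = ()  # (chrom, start, end, strand)
    prediction_id: str = ""
    rule: str = ""

    def __post_init__(self) -> None:
        if self.kind == "split" and not (len(self.removed) == 1 and len(self.new_models) >= 2):
            raise ValidationError("split must turn one model into two or more")
        if self.kind == "merge" and not (len(self.removed) >= 2 and len(self.new_models) == 1):
            raise ValidationError("merge must turn two or more models into one")
        if self.kind == "new_gene" and (self.removed or len(self.new_models) != 1):
            raise ValidationError("new_gene adds exactly one model")


@dataclass(frozen=True)
class RefinementConfig:
    """Thresholds of the decision procedure.

    ``query_coverage_min`` is the published filtration criterion: a
    prediction must cover at least 60% of its query protein.
    ``redundancy_threshold`` governs the in-map branch: a prediction
    covering at least this fraction of an existing supported model is
    considered the same locus and discarded; partial hits indicate a
    chimeric model and trigger the split/merge branches.
    """

    query_coverage_min: float = 0.6
    redundancy_threshold: float = 0.9
    trusted_genome_id: Optional[str] = None
    pid_min: float = 40.0
    e_value_max: float = 1e-10


@dataclass(frozen=True)
class OrthologAssignment:
    gene_a: str
    gene_b: str
    pid: float
    e_value: float


def outmap_candidates(
    blocks: Sequence[SyntenyBlock],
    status: MarkerStatus,
    max_out: int = 20,
) -> list[tuple[str, str, str, BlockInterval]]:
    """Prediction search spaces for out-map mismatch genes inside blocks.

    For every out-map mismatch gene of every block (on either side), emit
    ``(gene_id, query_side, block_id, target_interval)`` where the target
    interval is the block's partner interval -- the genomic region in
    which the missing ortholog, if any, must reside. Blocks carrying more
    than ``max_out`` out-map mismatches on a side are skipped for that
    side.
    """
    out = []
    for b in blocks:
        if len(b.out_map_mismatches_a) <= max_out:
            for gid in sorted(b.out_map_mismatches_a):
                out.append((gid, "a", b.block_id, b.interval_b))
        if len(b.out_map_mismatches_b) <= max_out:
            for gid in sorted(b.out_map_mismatches_b):
                out.append((gid, "b", b.block_id, b.interval_a))
    return out


def filter_predictions(
    records: Iterable[PredictionRecord],
    min_coverage: float = 0.6,
) -> list[PredictionRecord]:
    """Keep predictions covering >= 60% of the query with no internal stop.

    Both bounds follow the published wording: coverage exactly at the
    threshold is accepted. Filtering is idempotent and order-independent.
    """
    return [
        r
        for r in records
        if r.query_coverage >= min_coverage and not r.has_internal_stop
    ]


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0) + 1)


def classify_prediction(
    record: PredictionRecord,
    target_genome: Genome,
    in_map_target: frozenset[str] | set[str],
    corr: Optional[CorrespondenceMap] = None,
    query_genome: Optional[Genome] = None,
    config: Optional[RefinementConfig] = None,
) -> RefinementAction:
    """Classify one filtered prediction into a curation action.

    Decision tree:

    * no overlap with any existing model -> ``new_gene``;
    * one existing out-map model -> ``replace`` when the prediction covers
      its query at least as well as the model's own support (and the
      target genome is not trusted), else ``discard``;
    * one existing in-map model covered below the redundancy threshold ->
      ``split`` the (draft) model into the predicted piece plus the
      remainder; when the hit model lies in the trusted genome the defect
      is on the query side instead, and the query gene is merged with the
      hit model's ortholog when they are adjacent;
    * two adjacent models both overlapped by the prediction -> ``merge``;
    * anything else -> ``discard`` with the reason.
    """
    if config is None:
        config = RefinementConfig()
    if record.target_chrom not in target_genome.chromosomes:
        raise ValidationError(
            f"prediction {record.prediction_id}: unknown chromosome "
            f"{record.target_chrom!r} in genome {target_genome.genome_id}"
        )
    s, e = record.target_start, record.target_end
    hits = [
        g
        for g in target_genome.genes(record.target_chrom)
        if _overlap(s, e, g.start, g.end) > 0
    ]
    trusted = config.trusted_genome_id == target_genome.genome_id

    def discard(reason: str) -> RefinementAction:
        return RefinementAction(
            kind="discard",
            target_genome_id=target_genome.genome_id,
            prediction_id=record.prediction_id,
            rule=reason,
        )

    if not hits:
        # New genes are admissible even in a trusted genome.
        return RefinementAction(
            kind="new_gene",
            target_genome_id=target_genome.genome_id,
            new_models=((record.target_chrom, s, e, record.target_strand),),
            prediction_id=record.prediction_id,
            rule="intergenic/intronic prediction",
        )

    if len(hits) == 1:
        m = hits[0]
        if m.gene_id not in in_map_target:
            if record.query_coverage < record.target_support:
                return discard("prediction weaker than existing model support")
            if trusted:
                return discard("out-map model lies in the trusted genome")
            return RefinementAction(
                kind="replace",
                target_genome_id=target_genome.genome_id,
                removed=(m.gene_id,),
                new_models=((record.target_chrom, s, e, m.strand),),
                prediction_id=record.prediction_id,
                rule="prediction supersedes unsupported out-map model",
            )
        cov = _overlap(s, e, m.start, m.end) / m.length
        if cov >= config.redundancy_threshold:
            return discard("prediction redundant with supported in-map model")
        if record.companion_span is not None and _overlap(
            s, e, record.companion_span[0], record.companion_span[1]
        ) > 0:
            return discard("reciprocal predictions overlap")
        if trusted:
            # The partial hit on a curated model points at a fission on the
            # query side: merge the query gene with the hit model's ortholog.
            if corr is None or query_genome is None:
                return discard("trusted in-map hit without reciprocal context")
            orthos = [
                p
                for p in corr.partners_b.get(m.gene_id, corr.partners_a.get(m.gene_id, frozenset()))
                if p in query_genome
            ]
            q = record.query_gene_id
            merge_partner = None
            if q in query_genome:
                qchrom, qord = query_genome.position(q)
                for p in orthos:
                    pchrom, pord = query_genome.position(p)
                    if pchrom == qchrom and abs(pord - qord) == 1:
                        merge_partner = p
                        break
            if merge_partner is None:
                return discard("no adjacent ortholog to merge with on query side")
            qg = query_genome.gene(q)
            pg = query_genome.gene(merge_partner)
            return RefinementAction(
                kind="merge",
                target_genome_id=query_genome.genome_id,
                removed=tuple(sorted((q, merge_partner))),
                new_models=(
                    (qg.chrom, min(qg.start, pg.start), max(qg.end, pg.end), qg.strand),
                ),
                prediction_id=record.prediction_id,
                rule="partial hit on trusted model: query-side fragments merged",
            )
        # Draft-genome chimeric model: split into prediction + remainder.
        pieces = []
        ov0, ov1 = max(s, m.start), min(e, m.end)
        if ov0 - m.start >= 50:
            pieces.append((m.chrom, m.start, ov0 - 1, m.strand))
        pieces.append((m.chrom, ov0, ov1, m.strand))
        if m.end - ov1 >= 50:
            pieces.append((m.chrom, ov1 + 1, m.end, m.strand))
        if len(pieces) < 2:
            return discard("partial hit leaves no viable remainder model")
        return RefinementAction(
            kind="split",
            target_genome_id=target_genome.genome_id,
            removed=(m.gene_id,),
            new_models=tuple(pieces),
            prediction_id=record.prediction_id,
            rule="chimeric draft model split at prediction boundary",
        )

    if len(hits) == 2:
        g1, g2 = hits
        _, o1 = target_genome.position(g1.gene_id)
        _, o2 = target_genome.position(g2.gene_id)
        if abs(o1 - o2) == 1:
            if trusted:
                return discard("merge implicates models in the trusted genome")
            return RefinementAction(
                kind="merge",
                target_genome_id=target_genome.genome_id,
                removed=tuple(sorted((g1.gene_id, g2.gene_id))),
                new_models=(
                    (g1.chrom, min(g1.start, g2.start), max(g1.end, g2.end), g1.strand),
                ),
                prediction_id=record.prediction_id,
                rule="prediction spans two adjacent fragment models",
            )
        return discard("prediction spans two non-adjacent models")

    return discard(f"prediction overlaps {len(hits)} models; ambiguous")


@dataclass
class ChangeReport:
    """Gene-count bookkeeping over one batch of refinement actions."""

    genome_id: str
    initial_genes: int
    outmap_replaced: int = 0
    split_genes: int = 0
    merged_genes: int = 0
    predictions_added_split: int = 0
    predictions_added_merge: int = 0
    new_genes: int = 0
    final_genes: int = 0

    @property
    def genes_deleted(self) -> int:
        return self.outmap_replaced + self.split_genes + self.merged_genes

    @property
    def genes_added(self) -> int:
        return (
            self.outmap_replaced
            + self.predictions_added_split
            + self.predictions_added_merge
            + self.new_genes
        )

    def identity_holds(self) -> bool:
        return self.initial_genes - self.genes_deleted + self.genes_added == self.final_genes

    def as_rows(self) -> list[tuple[str, int]]:
        return [
            ("Initial number of genes", self.initial_genes),
            ("Outmap genes replaced by predictions", self.outmap_replaced),
            ("Split genes", self.split_genes),
            ("Merged genes", self.merged_genes),
            ("Predictions added because of split genes", self.predictions_added_split),
            ("Predictions added because of merged genes", self.predictions_added_merge),
            ("Genes added because of new genes", self.new_genes),
            ("Final number of genes", self.final_genes),
        ]


def apply_actions(
    genome: Genome,
    actions: Sequence[RefinementAction],
    id_prefix: str = "NEW",
) -> tuple[Genome, ChangeReport]:
    """Apply curation actions to an annotation.

    Actions must all target this genome and be mutually consistent (no
    existing model touched twice); violations raise with the conflict
    set. Replacement/split/merge products and new genes are minted ids
    ``<prefix>00001`` onward, in action order.
    """
    touched: dict[str, list[int]] = {}
    for i, act in enumerate(actions):
        if act.kind == "discard":
            continue
        if act.target_genome_id != genome.genome_id:
            raise ValidationError(
                f"action {i} targets genome {act.target_genome_id!r}, "
                f"not {genome.genome_id!r}"
            )
        for gid in act.removed:
            touched.setdefault(gid, []).append(i)
    conflicts = {g: ix for g, ix in touched.items() if len(ix) > 1}
    if conflicts:
        raise ValidationError(f"conflicting actions touch models: {sorted(conflicts)}")
    missing = [g for g in touched if g not in genome]
    if missing:
        raise ValidationError(f"actions reference unknown models: {sorted(missing)}")

    report = ChangeReport(genome_id=genome.genome_id, initial_genes=len(genome))
    keep = {g.gene_id: g for g in genome}
    added: list[GeneMarker] = []
    counter = 0

    def mint() -> str:
        nonlocal counter
        counter += 1
        return f"{id_prefix}{counter:05d}"

    for act in actions:
        if act.kind == "discard":
            continue
        for gid in act.removed:
            del keep[gid]
        for chrom, start, end, strand in act.new_models:
            added.append(GeneMarker(mint(), chrom, start, end, strand))
        if act.kind == "replace":
            report.outmap_replaced += 1
        elif act.kind == "split":
            report.split_genes += len(act.removed)
            report.predictions_added_split += len(act.new_models)
        elif act.kind == "merge":
            report.merged_genes += len(act.removed)
            report.predictions_added_merge += len(act.new_models)
        elif act.kind == "new_gene":
            report.new_genes += len(act.new_models)
        else:
            raise ValidationError(f"unknown action kind {act.kind!r}")

    revised = Genome(genome.genome_id, list(keep.values()) + added)
    report.final_genes = len(revised)
    assert report.identity_holds()
    return revised, report


def percent_identity(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
    max_alignments: int = 256,
) -> float:
    """Global-alignment percent identity between two protein sequences.

    Needleman-Wunsch with affine gaps and a standard substitution matrix;
    PID = identical aligned positions / alignment columns x 100, taking
    the best PID over co-optimal alignments (capped for safety). Raises
    on empty sequences or non-amino-acid symbols.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValidationError(f"{name} is empty")
        bad = set(seq.upper()) - _AA
        if bad:
            raise ValidationError(f"{name} contains non-amino-acid symbols: {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    best = 0.0
    for k, aln in enumerate(aligner.align(seq_a.upper(), seq_b.upper())):
        counts = aln.counts()
        pid = 100.0 * counts.identities / aln.length
        best = max(best, pid)
        if k + 1 >= max_alignments:
            break
    return best


def assign_orthologs(
    candidate_pairs: Iterable[OrthologAssignment],
    corr: Optional[CorrespondenceMap] = None,
    pid_min: float = 40.0,
    e_value_max: float = 1e-10,
):
    """Accept new ortholog pairs at PID >= 40% and e-value <= 1e-10.

    Both boundaries are inclusive. Returns the accepted assignments, or
    ``(accepted, merged_map)`` when an existing correspondence is given.
    """
    accepted = [
        p
        for p in candidate_pairs
        if p.pid >= pid_min and p.e_value <= e_value_max
    ]
    if corr is None:
        return accepted
    merged = corr.merged_with((p.gene_a, p.gene_b) for p in accepted)
    return accepted, merged
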