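"""Readers and writers for every file format the tool touches.

Formats
-------
genome table
    TSV with five columns: gene_id, chrom, start, end, strand. Header
    optional (detected), ``#`` lines are comments. 1-based inclusive.
GFF3
    gene/mRNA/CDS features linked by ID/Parent; a gene locus is
    represented by its longest isoform (greatest summed CDS length,
    ties broken by genomic span then isoform id).
correspondence table
    TSV with two columns gene_A gene_B; extra columns ignored,
    duplicates collapse.
blocks
    TSV (one row per block, full ledgers, byte-stable) and a BED dialect
    (two records per block, one per genome; 0-based half-open).
operons
    TSV: operon_id, chrom, comma-separated member gene ids.
"""

from __future__ import annotations

import os
import sys
import warnings
from typing import Iterable, Optional, Sequence, TextIO

from .model import (
    BlockInterval,
    CorrespondenceMap,
    GeneMarker,
    Genome,
    SyntenyBlock,
    ValidationError,
)

__all__ = [
    "read_genome_table",
    "write_genome_table",
    "read_gff3",
    "read_correspondence",
    "write_correspondence",
    "read_blocks",
    "write_blocks",
    "read_operons",
    "write_operons",
    "read_lengths",
    "read_regions",
    "ParseError",
]


class ParseError(ValueError):
    """A malformed input row; the message names the file and line number."""


def _open_lines(path) -> list[str]:
    with open(path, "rt", encoding="utf-8") as fh:
        return fh.readlines()


def read_genome_table(path, genome_id: Optional[str] = None) -> Genome:
    """Read a five-column genome table into a :class:`Genome`.

    Rows are re-sorted into the deterministic per-chromosome gene order,
    so any permutation of the same rows yields an identical genome.
    """
    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    genes = []
    for lineno, line in enumerate(_open_lines(path), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ParseError(
                f"{path}:{lineno}: expected 5 tab-separated columns, got {len(fields)}"
            )
        gene_id, chrom, start_s, end_s, strand = (f.strip() for f in fields)
        if lineno == 1 and not (start_s.isdigit() and end_s.isdigit()):
            continue  # header row
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: non-integer coordinate ({start_s!r}, {end_s!r})"
            ) from None
        try:
            genes.append(GeneMarker(gene_id, chrom, start, end, strand))
        except ValidationError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return Genome(genome_id, genes)


def write_genome_table(genome: Genome, path, header: bool = True) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genome:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")


def read_gff3(path, genome_id: Optional[str] = None, feature_type: str = "gene") -> Genome:
    """Reduce a GFF3 annotation to one marker per gene locus.

    A multi-isoform gene is represented by the span of its longest
    isoform, where "longest" means greatest summed CDS length; ties break
    by greater genomic span, then lexicographic isoform id. Isoforms
    without CDS children fall back to their own span; genes without
    linked isoforms fall back to the gene feature span (with a warning
    when isoform-like children exist but lack Parent linkage).
    """
    import gffutils

    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type(feature_type):
        ranked = []
        for iso in db.children(gene, level=1):
            cds_len = sum(
                c.end - c.start + 1 for c in db.children(iso, featuretype="CDS")
            )
            span = iso.end - iso.start + 1
            ranked.append((-(cds_len if cds_len else span), -span, iso.id, iso))
        if ranked:
            rep = sorted(ranked, key=lambda t: t[:3])[0][3]
            start, end = rep.start, rep.end
        else:
            orphan_kids = any(
                f.featuretype in ("mRNA", "transcript")
                for f in db.region(seqid=gene.seqid, start=gene.start, end=gene.end)
                if f.id != gene.id
            )
            if orphan_kids:
                warnings.warn(
                    f"gene {gene.id}: no Parent-linked isoforms; using gene span",
                    stacklevel=2,
                )
            start, end = gene.start, gene.end
        genes.append(
            GeneMarker(gene.id, gene.seqid, start, end, gene.strand or "+")
        )
    return Genome(genome_id, genes)


def read_correspondence(
    path,
    genome_a: Optional[Genome] = None,
    genome_b: Optional[Genome] = None,
    strict: bool = False,
):
    """Read an ortholog-pair table.

    With genomes supplied, pairs referencing unknown genes are collected
    into a report; strict mode raises, lenient mode (default) drops them
    with a warning. Returns ``CorrespondenceMap`` or, when genomes are
    given, ``(CorrespondenceMap, orphan_report)``.
    """
    pairs = []
    for lineno, line in enumerate(_open_lines(path), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected at least 2 columns")
        pairs.append((fields[0].strip(), fields[1].strip()))
    corr = CorrespondenceMap(pairs)
    if genome_a is None or genome_b is None:
        return corr
    orphans = corr.validate(genome_a, genome_b)
    if orphans:
        if strict:
            raise ValidationError(
                f"{path}: {len(orphans)} pairs reference unknown genes, "
                f"first: {orphans[0]}"
            )
        warnings.warn(
            f"{path}: dropped {len(orphans)} pairs referencing unknown genes",
            stacklevel=2,
        )
        corr = corr.restricted_to(genome_a, genome_b)
    return corr, orphans


def write_correspondence(corr: CorrespondenceMap, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for a, b in sorted(corr.pairs):
            fh.write(f"{a}\t{b}\n")


_BLOCK_COLUMNS = [
    "block_id", "genome_a", "chrom_a", "a_start_ord", "a_end_ord",
    "a_start_bp", "a_end_bp", "n_genes_a", "genome_b", "chrom_b",
    "b_start_ord", "b_end_ord", "b_start_bp", "b_end_bp", "n_genes_b",
    "n_matched_a", "n_matched_b", "matched_pairs",
    "in_map_mismatches_a", "in_map_mismatches_b",
    "out_map_mismatches_a", "out_map_mismatches_b",
    "orientation", "strand_pattern", "nested", "parent_id", "singleton",
]


def _fmt_set(s: frozenset[str]) -> str:
    return ",".join(sorted(s)) if s else "."


def _parse_set(s: str) -> frozenset[str]:
    return frozenset() if s == "." else frozenset(s.split(","))


def write_blocks(blocks: Sequence[SyntenyBlock], path, format: str = "tsv") -> None:
    """Write blocks as TSV (full ledgers, round-trips) or BED.

    The BED dialect emits one record per genome per block, named
    ``<block_id>|<genome_id>``, with 0-based half-open coordinates.
    """
    if format == "tsv":
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("\t".join(_BLOCK_COLUMNS) + "\n")
            for b in blocks:
                ia, ib = b.interval_a, b.interval_b
                row = [
                    b.block_id, b.genome_a_id, ia.chrom, ia.start_ord, ia.end_ord,
                    ia.start_bp, ia.end_bp, ia.n_genes, b.genome_b_id, ib.chrom,
                    ib.start_ord, ib.end_ord, ib.start_bp, ib.end_bp, ib.n_genes,
                    b.n_matched_a, b.n_matched_b,
                    ";".join(f"{x}|{y}" for x, y in b.matched_pairs),
                    _fmt_set(b.in_map_mismatches_a), _fmt_set(b.in_map_mismatches_b),
                    _fmt_set(b.out_map_mismatches_a), _fmt_set(b.out_map_mismatches_b),
                    b.orientation, b.strand_pattern,
                    int(b.nested), b.parent_id or ".", int(b.singleton),
                ]
                fh.write("\t".join(str(v) for v in row) + "\n")
    elif format == "bed":
        with open(path, "wt", encoding="utf-8") as fh:
            for b in blocks:
                for gid, iv in ((b.genome_a_id, b.interval_a), (b.genome_b_id, b.interval_b)):
                    fh.write(
                        f"{iv.chrom}\t{iv.start_bp - 1}\t{iv.end_bp}\t"
                        f"{b.block_id}|{gid}\t{b.size_genes}\t.\n"
                    )
    else:
        raise ValueError(f"unknown block format {format!r}")


def read_blocks(path) -> list[SyntenyBlock]:
    """Read a block TSV written by :func:`write_blocks` back into objects."""
    lines = _open_lines(path)
    if not lines:
        return []
    header = lines[0].rstrip("\n").split("\t")
    if header != _BLOCK_COLUMNS:
        raise ParseError(f"{path}: unrecognized block table header")
    blocks = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        f = dict(zip(_BLOCK_COLUMNS, line.rstrip("\n").split("\t")))
        pairs = (
            tuple(tuple(p.split("|")) for p in f["matched_pairs"].split(";"))
            if f["matched_pairs"]
            else ()
        )
        blocks.append(
            SyntenyBlock(
                block_id=f["block_id"],
                genome_a_id=f["genome_a"],
                genome_b_id=f["genome_b"],
                interval_a=BlockInterval(
                    f["chrom_a"], int(f["a_start_ord"]), int(f["a_end_ord"]),
                    int(f["a_start_bp"]), int(f["a_end_bp"]),
                ),
                interval_b=BlockInterval(
                    f["chrom_b"], int(f["b_start_ord"]), int(f["b_end_ord"]),
                    int(f["b_start_bp"]), int(f["b_end_bp"]),
                ),
                matched_pairs=pairs,
                in_map_mismatches_a=_parse_set(f["in_map_mismatches_a"]),
                in_map_mismatches_b=_parse_set(f["in_map_mismatches_b"]),
                out_map_mismatches_a=_parse_set(f["out_map_mismatches_a"]),
                out_map_mismatches_b=_parse_set(f["out_map_mismatches_b"]),
                orientation=f["orientation"],
                strand_pattern=f["strand_pattern"],
                nested=bool(int(f["nested"])),
                parent_id=None if f["parent_id"] == "." else f["parent_id"],
                singleton=bool(int(f["singleton"])),
            )
        )
    return blocks


def read_operons(path) -> list[tuple[str, str, tuple[str, ...]]]:
    """Read operons: TSV of (operon_id, chrom, comma-separated members)."""
    operons = []
    for lineno, line in enumerate(_open_lines(path), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns")
        operons.append((fields[0], fields[1], tuple(fields[2].split(","))))
    return operons


def write_operons(operons, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for op in operons:
            operon_id, chrom, members = op.operon_id, op.chrom, op.members
            fh.write(f"{operon_id}\t{chrom}\t{','.join(members)}\n")


def read_lengths(path) -> dict[str, int]:
    """Chromosome length table: TSV of (chrom, length_bp)."""
    lengths = {}
    for lineno, line in enumerate(_open_lines(path), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        lengths[fields[0]] = int(fields[1])
    return lengths


def read_regions(path) -> list[tuple[str, int, int, str]]:
    """Region definitions: TSV of (chrom, start, end, label).

    Labels are free-form; the chromosome-arm analysis uses ``arm`` and
    ``center``. Coordinates 1-based inclusive.
    """
    regions = []
    for lineno, line in enumerate(_open_lines(path), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns")
        regions.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
    return regions
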