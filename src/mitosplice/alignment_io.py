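"""Annotation and alignment parsing, read classification and union-mode counting.

GTF parsing is delegated to gffutils (in-memory database) and SAM/BAM parsing to
pysam.  Alignment blocks are re-derived from the CIGAR here rather than taken
from ``pysam.AlignedSegment.get_blocks`` because deletions must *not* split
blocks: only reference skips (``N``) — the splicing signal — create junctions.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
import pysam
from intervaltree import IntervalTree

from .model import (
    DEFAULT_MITO_NAMES,
    MITO,
    NUCLEAR,
    AlignedRead,
    Chromosome,
    GenomeModel,
    JunctionKey,
    SampleCounts,
    SampleTotals,
    Transcript,
)

logger = logging.getLogger(__name__)

# CIGAR operation codes (pysam numeric encoding)
_REF_BLOCK_OPS = {0, 7, 8, 2}  # M, =, X advance both; D advances reference in-block
_SKIP_OP = 3                   # N splits blocks
_QUERY_ONLY_OPS = {1, 4, 5, 6}  # I, S, H, P do not advance the reference


def read_annotation(
    path: str | Path,
    *,
    mito_names: frozenset[str] | set[str] = DEFAULT_MITO_NAMES,
    chrom_lengths: dict[str, int] | None = None,
) -> GenomeModel:
    """Parse a GTF into a GenomeModel (coordinates converted to 0-based half-open).

    Chromosome lengths are taken from ``chrom_lengths`` when given (e.g. from a
    SAM header or FASTA index), otherwise set to the furthest annotated end.
    Mitochondrial compartment is inferred from the chromosome name.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # surface parse failures with the offending file
        raise ValueError(f"malformed GTF {path}: {exc}") from exc

    exons_by_tx: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tx_ids = feat.attributes.get("transcript_id")
        if not tx_ids:
            raise ValueError(f"exon without transcript_id at {feat.seqid}:{feat.start}")
        tx_id = tx_ids[0]
        entry = exons_by_tx.setdefault(
            tx_id,
            {
                "gene_id": feat.attributes.get("gene_id", [tx_id])[0],
                "chromosome": feat.seqid,
                "strand": feat.strand if feat.strand in "+-" else "+",
                "biotype": feat.attributes.get("gene_biotype", ["protein_coding"])[0],
                "exons": [],
            },
        )
        entry["exons"].append((feat.start - 1, feat.end))  # GTF 1-based inclusive

    if not exons_by_tx:
        raise ValueError(f"no exon features in {path}")

    transcripts = [
        Transcript(
            transcript_id=tx_id,
            gene_id=e["gene_id"],
            chromosome=e["chromosome"],
            strand=e["strand"],
            exons=tuple(sorted(e["exons"])),
            biotype=e["biotype"],
        )
        for tx_id, e in exons_by_tx.items()
    ]

    chrom_names = sorted({t.chromosome for t in transcripts})
    chromosomes = []
    for name in chrom_names:
        is_mito = name in mito_names
        length = max(t.end for t in transcripts if t.chromosome == name)
        if chrom_lengths and name in chrom_lengths:
            length = chrom_lengths[name]
        chromosomes.append(
            Chromosome(
                name,
                length,
                circular=is_mito,
                compartment=MITO if is_mito else NUCLEAR,
            )
        )
    return GenomeModel(chromosomes=chromosomes, transcripts=transcripts)


def blocks_from_cigar(reference_start: int, cigartuples) -> tuple[tuple[int, int], ...]:
    """Genomic alignment blocks from a CIGAR; skips split, deletions do not."""
    blocks: list[tuple[int, int]] = []
    pos = reference_start
    block_start = None
    for op, length in cigartuples:
        if op in _REF_BLOCK_OPS:
            if block_start is None:
                block_start = pos
            pos += length
        elif op == _SKIP_OP:
            if block_start is not None:
                blocks.append((block_start, pos))
                block_start = None
            pos += length
        elif op in _QUERY_ONLY_OPS:
            continue
        else:
            raise ValueError(f"unsupported CIGAR op {op}")
    if block_start is not None:
        blocks.append((block_start, pos))
    return tuple(blocks)


def read_alignments(path: str | Path, sample_id: str = "") -> Iterator[AlignedRead]:
    """Stream primary mapped single-end alignments from a SAM/BAM file."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            yield AlignedRead(
                read_id=seg.query_name,
                chromosome=seg.reference_name,
                blocks=blocks_from_cigar(seg.reference_start, seg.cigartuples),
                strand="-" if seg.is_reverse else "+",
                sample_id=sample_id,
            )


def sam_chromosome_lengths(path: str | Path) -> dict[str, int]:
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        return {sq["SN"]: sq["LN"] for sq in fh.header.to_dict().get("SQ", [])}


def classify_read(read: AlignedRead) -> str:
    """'gapped' (spliced, >=2 blocks) or 'ungapped' (single contiguous block)."""
    return "gapped" if read.is_gapped else "ungapped"


def extract_junctions(read: AlignedRead) -> list[JunctionKey]:
    """One junction per adjacent block pair; empty for ungapped reads."""
    return [
        JunctionKey(read.chromosome, a_end, b_start, read.strand)
        for (_, a_end), (b_start, _) in zip(read.blocks, read.blocks[1:])
    ]


def _exon_trees(genome: GenomeModel) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree of exons -> gene_id (exons unioned per gene)."""
    trees: dict[str, IntervalTree] = {}
    for tx in genome.transcripts:
        tree = trees.setdefault(tx.chromosome, IntervalTree())
        for s, e in tx.exons:
            tree.addi(s, e, tx.gene_id)
    return trees


def count_gene_reads(
    reads: Iterable[AlignedRead],
    genome: GenomeModel,
    sample_id: str = "",
) -> SampleCounts:
    """Single pass over one sample's reads: union-mode gene counts, junction
    counts, gapped/ungapped/compartment totals.

    Union-mode rule: a read is assigned to a gene iff every one of its blocks
    overlaps that gene's exons and no block overlaps a different gene; reads
    hitting zero genes are ``no_feature``, reads hitting more than one are
    ``ambiguous``; neither contributes to gene counts.
    """
    trees = _exon_trees(genome)
    mito_chroms = {c.name for c in genome.mito_chromosomes()}

    totals = SampleTotals(sample_id=sample_id)
    junction_counts: dict[JunctionKey, int] = {}
    gene_counts: dict[str, int] = {}
    no_feature = 0
    ambiguous = 0

    for read in reads:
        totals.total_reads += 1
        gapped = read.is_gapped
        if gapped:
            totals.gapped_reads += 1
            for key in extract_junctions(read):
                junction_counts[key] = junction_counts.get(key, 0) + 1
        else:
            totals.ungapped_reads += 1
        if read.chromosome in mito_chroms:
            totals.mito_reads += 1
            if not gapped:
                totals.mito_ungapped_reads += 1

        tree = trees.get(read.chromosome)
        union: set[str] = set()
        all_blocks_hit = True
        for s, e in read.blocks:
            hits = {iv.data for iv in tree.overlap(s, e)} if tree is not None else set()
            if not hits:
                all_blocks_hit = False
            union |= hits
        if not union:
            no_feature += 1
        elif len(union) > 1:
            ambiguous += 1
        elif all_blocks_hit:
            gene = next(iter(union))
            gene_counts[gene] = gene_counts.get(gene, 0) + 1
        else:
            # one gene hit, but some block is entirely outside annotation
            no_feature += 1

    totals.validate()
    return SampleCounts(
        sample_id=sample_id,
        totals=totals,
        junction_counts=junction_counts,
        gene_counts=gene_counts,
        no_feature=no_feature,
        ambiguous=ambiguous,
    )


def sample_counts_from_sam(
    path: str | Path, genome: GenomeModel, sample_id: str = ""
) -> SampleCounts:
    return count_gene_reads(read_alignments(path, sample_id), genome, sample_id)


def write_junction_bed(counts: SampleCounts, path: str | Path) -> None:
    """One BED record per junction (0-based, donor_end..acceptor_start, count as score)."""
    items = sorted(
        counts.junction_counts.items(),
        key=lambda kv: (kv[0].chromosome, kv[0].donor_end, kv[0].acceptor_start),
    )
    with open(path, "w") as fh:
        for key, c in items:
            name = f"{key.chromosome}:{key.donor_end}-{key.acceptor_start}"
            fh.write(
                f"{key.chromosome}\t{key.donor_end}\t{key.acceptor_start}"
                f"\t{name}\t{c}\t{key.strand}\n"
            )


def write_gene_counts(counts: SampleCounts, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcount\n")
        for gene, c in sorted(counts.gene_counts.items()):
            fh.write(f"{gene}\t{c}\n")
        fh.write(f"__no_feature\t{counts.no_feature}\n")
        fh.write(f"__ambiguous\t{counts.ambiguous}\n")
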