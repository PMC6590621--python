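"""Shared data model for the junction-usage / mitochondrial transcriptome pipeline.

All genomic intervals are 0-based half-open ``[start, end)``.  GTF input/output is
converted at the boundary (GTF is 1-based inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

NUCLEAR = "nuclear"
MITO = "mito"

#: chromosome names treated as mitochondrial unless overridden
DEFAULT_MITO_NAMES = frozenset({"chrM", "MT", "chrMT"})


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    circular: bool = False
    compartment: str = NUCLEAR  # "nuclear" | "mito"


@dataclass(frozen=True)
class Transcript:
    """One transcript: ordered, non-overlapping exons on a single chromosome."""

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = -1
        for start, end in exons:
            if not (0 <= start < end):
                raise ValueError(
                    f"transcript {self.transcript_id}: bad exon [{start}, {end})"
                )
            if start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
            prev_end = end
        if not exons:
            raise ValueError(f"transcript {self.transcript_id}: zero exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def junctions(self) -> list["JunctionKey"]:
        """Exon-exon junctions implied by this transcript's exon chain."""
        return [
            JunctionKey(self.chromosome, a_end, b_start, self.strand)
            for (_, a_end), (b_start, _) in zip(self.exons, self.exons[1:])
        ]


@dataclass
class GenomeModel:
    """Chromosomes plus transcript annotation, split into nuclear/mito compartments."""

    chromosomes: list[Chromosome]
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        by_name = {c.name: c for c in self.chromosomes}
        if len(by_name) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for tx in self.transcripts:
            chrom = by_name.get(tx.chromosome)
            if chrom is None:
                raise ValueError(
                    f"transcript {tx.transcript_id} on unknown chromosome {tx.chromosome}"
                )
            if tx.end > chrom.length:
                raise ValueError(
                    f"transcript {tx.transcript_id} exceeds {chrom.name} length"
                )

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def transcripts_on(self, chromosome: str) -> list[Transcript]:
        return [t for t in self.transcripts if t.chromosome == chromosome]

    def mito_chromosomes(self) -> list[Chromosome]:
        return [c for c in self.chromosomes if c.compartment == MITO]

    def genes(self) -> dict[str, list[Transcript]]:
        out: dict[str, list[Transcript]] = {}
        for tx in self.transcripts:
            out.setdefault(tx.gene_id, []).append(tx)
        return out

    def gene_span(self, gene_id: str) -> tuple[str, int, int]:
        """(chromosome, start, end) covering all exons of the gene."""
        txs = [t for t in self.transcripts if t.gene_id == gene_id]
        if not txs:
            raise KeyError(gene_id)
        chroms = {t.chromosome for t in txs}
        if len(chroms) > 1:
            raise ValueError(f"gene {gene_id} spans multiple chromosomes")
        return txs[0].chromosome, min(t.start for t in txs), max(t.end for t in txs)


@dataclass(frozen=True)
class JunctionKey:
    """A splice junction: end of the donor block and start of the acceptor block."""

    chromosome: str
    donor_end: int       # 0-based exclusive end of the upstream aligned block
    acceptor_start: int  # 0-based start of the downstream aligned block
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.acceptor_start <= self.donor_end:
            raise ValueError("acceptor_start must exceed donor_end")


@dataclass(frozen=True)
class AlignedRead:
    """One single-end alignment as ordered genomic blocks; gapped iff >= 2 blocks."""

    read_id: str
    chromosome: str
    blocks: tuple[tuple[int, int], ...]
    strand: str = "+"
    sample_id: str = ""

    def __post_init__(self) -> None:
        blocks = tuple(tuple(b) for b in self.blocks)
        object.__setattr__(self, "blocks", blocks)
        prev_end = None
        for start, end in blocks:
            if end <= start:
                raise ValueError(f"read {self.read_id}: empty block")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"read {self.read_id}: unsorted/overlapping blocks")
            prev_end = end
        if not blocks:
            raise ValueError(f"read {self.read_id}: no blocks")

    @property
    def is_gapped(self) -> bool:
        return len(self.blocks) >= 2

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


@dataclass
class SampleTotals:
    """Per-sample read tallies used as normalizers throughout the pipeline."""

    sample_id: str
    total_reads: int = 0
    gapped_reads: int = 0
    ungapped_reads: int = 0
    mito_reads: int = 0
    mito_ungapped_reads: int = 0

    def validate(self) -> None:
        if self.gapped_reads + self.ungapped_reads != self.total_reads:
            raise ValueError("gapped + ungapped != total")
        if self.mito_ungapped_reads > self.ungapped_reads:
            raise ValueError("mito_ungapped exceeds ungapped")
        if min(
            self.total_reads,
            self.gapped_reads,
            self.ungapped_reads,
            self.mito_reads,
            self.mito_ungapped_reads,
        ) < 0:
            raise ValueError("negative tally")


@dataclass
class SampleCounts:
    """All per-sample count tables produced by one pass over the alignments."""

    sample_id: str
    totals: SampleTotals
    junction_counts: dict[JunctionKey, int] = field(default_factory=dict)
    gene_counts: dict[str, int] = field(default_factory=dict)
    no_feature: int = 0
    ambiguous: int = 0

    def gene_assigned(self) -> int:
        return sum(self.gene_counts.values())
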