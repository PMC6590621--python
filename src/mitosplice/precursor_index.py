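"""Mitochondrial precursor-transcript index from border-spanning reads.

The mitochondrial genome is transcribed as polycistronic precursors that RNase P
and RNase Z cleave into mature mt-mRNA/rRNA/tRNA units.  Reads whose single
contiguous alignment block covers the boundary between two neighboring units —
with at least ``min_overlap`` nucleotides on each side — can only stem from
uncleaved precursor RNA.  Per sample, the count for each adjacent border pair is
normalized to the total number of ungapped reads and to the fraction of ungapped
reads mapping to the mitochondrial reference; the mean over border pairs is the
precursor index, a proxy for the relative precursor abundance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .model import AlignedRead, GenomeModel, SampleTotals
from .stats import GroupComparison, t_test_unpaired

DEFAULT_MIN_OVERLAP = 6
DEFAULT_SCALE = 1e6


@dataclass(frozen=True)
class BorderPair:
    """Boundary between two transcripts adjacent on the mitochondrial genome."""

    upstream_transcript_id: str
    downstream_transcript_id: str
    upstream_end: int      # 0-based exclusive end of the upstream unit
    downstream_start: int  # 0-based start of the downstream unit
    chromosome: str

    def __post_init__(self) -> None:
        if self.downstream_start < self.upstream_end:
            raise ValueError("downstream unit starts before upstream unit ends")

    @property
    def label(self) -> str:
        return f"{self.upstream_transcript_id}|{self.downstream_transcript_id}"


def enumerate_border_pairs(
    genome: GenomeModel, include_origin: bool = False
) -> list[BorderPair]:
    """Adjacent transcript pairs on the mitochondrial chromosome, in genomic order.

    The circular-origin pair (last unit, first unit) is excluded unless
    ``include_origin`` is set, since linear alignments cannot span the origin.
    """
    mito = genome.mito_chromosomes()
    if not mito:
        raise ValueError("genome has no mitochondrial chromosome")
    pairs: list[BorderPair] = []
    for chrom in mito:
        units = sorted(genome.transcripts_on(chrom.name), key=lambda t: t.start)
        overlapping = [
            (a.transcript_id, b.transcript_id)
            for a, b in zip(units, units[1:])
            if b.start < a.end
        ]
        if overlapping:
            raise ValueError(f"overlapping mitochondrial transcripts: {overlapping}")
        pairs.extend(
            BorderPair(a.transcript_id, b.transcript_id, a.end, b.start, chrom.name)
            for a, b in zip(units, units[1:])
        )
        if include_origin and chrom.circular and len(units) >= 2:
            pairs.append(
                BorderPair(
                    units[-1].transcript_id,
                    units[0].transcript_id,
                    units[-1].end,
                    units[0].start + chrom.length,  # unwrapped coordinate
                    chrom.name,
                )
            )
    return pairs


def spans_border(
    block: tuple[int, int], pair: BorderPair, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> bool:
    """Does an ungapped block [a, b) overlap both sides of the border by >= min_overlap?

    For near-abutting neighbors each side is measured against its own boundary:
    the upstream unit's end and the downstream unit's start.
    """
    a, b = block
    return (pair.upstream_end - a) >= min_overlap and (
        b - pair.downstream_start
    ) >= min_overlap


def count_border_spanning(
    reads: Iterable[AlignedRead],
    pair: BorderPair,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> int:
    """Count ungapped reads spanning one border pair (gapped reads are skipped)."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    return sum(
        1
        for r in reads
        if not r.is_gapped
        and r.chromosome == pair.chromosome
        and spans_border(r.blocks[0], pair, min_overlap)
    )


def count_all_borders(
    reads: Iterable[AlignedRead],
    pairs: list[BorderPair],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> dict[str, int]:
    """Single pass over the reads counting every border pair.

    A read spanning more than one border (possible when a very short unit lies
    between two borders within the read length) counts for each pair it
    satisfies.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    out = {p.label: 0 for p in pairs}
    for r in reads:
        if r.is_gapped:
            continue
        for p in pairs:
            if r.chromosome == p.chromosome and spans_border(r.blocks[0], p, min_overlap):
                out[p.label] += 1
    return out


def normalize_border_coverage(
    raw: dict[str, int],
    totals: SampleTotals,
    scale: float = DEFAULT_SCALE,
) -> tuple[dict[str, float], float]:
    """Normalize raw border counts and average them into the precursor index.

    norm(pair) = scale * b(pair) / (U * m) with U the sample's ungapped reads and
    m the mitochondrial fraction of ungapped reads; the mean over pairs is the
    per-sample precursor index.
    """
    if totals.ungapped_reads <= 0:
        raise ValueError("no ungapped reads")
    U = totals.ungapped_reads
    m = totals.mito_ungapped_reads / U
    if m == 0:
        if any(raw.values()):
            raise ValueError(
                "border-spanning reads present but no mitochondrial ungapped reads"
            )
        norm = {label: 0.0 for label in raw}
        return norm, 0.0
    norm = {label: scale * b / (U * m) for label, b in raw.items()}
    mean_index = sum(norm.values()) / len(norm) if norm else 0.0
    return norm, mean_index


def precursor_report(
    reads: Iterable[AlignedRead],
    genome: GenomeModel,
    totals: SampleTotals,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    scale: float = DEFAULT_SCALE,
) -> pd.DataFrame:
    """Per-pair raw and normalized border coverage for one sample."""
    pairs = enumerate_border_pairs(genome)
    raw = count_all_borders(reads, pairs, min_overlap)
    norm, mean_index = normalize_border_coverage(raw, totals, scale)
    df = pd.DataFrame(
        {
            "sample_id": totals.sample_id,
            "pair": [p.label for p in pairs],
            "upstream_end": [p.upstream_end for p in pairs],
            "downstream_start": [p.downstream_start for p in pairs],
            "raw": [raw[p.label] for p in pairs],
            "normalized": [norm[p.label] for p in pairs],
        }
    )
    df.attrs["mean_index"] = mean_index
    return df


def compare_precursor(
    indices: dict[str, float],
    conditions: dict[str, str],
    order: tuple[str, str] | None = None,
) -> GroupComparison:
    """Unpaired t-test of per-sample precursor indices between two conditions."""
    labels = sorted(set(conditions.values())) if order is None else list(order)
    if len(labels) != 2:
        raise ValueError("exactly two condition labels required")
    x = [v for s, v in indices.items() if conditions[s] == labels[0]]
    y = [v for s, v in indices.items() if conditions[s] == labels[1]]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 samples per condition")
    return t_test_unpaired(x, y)
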