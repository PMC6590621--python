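"""End-to-end conveniences tying the simulator to the analysis stages.

Two equivalent routes feed the statistics: the in-memory route keeps each
simulated sample as column arrays (fast, used for calibration studies and the
worked examples) and the file route goes through SAM/GTF on disk via pysam and
gffutils.  Both produce identical count tables; a round-trip test enforces this.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import alignment_io, junction_usage, mito_expression, precursor_index
from .model import GenomeModel, SampleCounts
from .stats import GroupComparison
from .synthetic import NUCLEAR_GENE, SampleReads, SimConfig, anchor_coordinate, build_toy_genome, simulate_samples


@dataclass
class Experiment:
    """A simulated experiment held in memory."""

    genome: GenomeModel
    samples: list[SampleReads]
    counts: list[SampleCounts]
    conditions: dict[str, str]  # sample_id -> condition label


def simulate_in_memory(config: SimConfig) -> Experiment:
    genome, _ = build_toy_genome(config)
    samples = list(simulate_samples(config, genome))
    counts = [s.counts() for s in samples]
    conditions = {s.sample_id: s.condition for s in samples}
    return Experiment(genome, samples, counts, conditions)


def junction_shift_analysis(
    exp: Experiment,
    anchor: int | None = None,
    gene_id: str = NUCLEAR_GENE,
    order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Upstream/downstream junction-group GNSSR comparison for the anchor split."""
    if anchor is None:
        anchor = anchor_coordinate(exp.genome)
    records = {
        c.sample_id: junction_usage.compute_gnssr(c, exp.genome) for c in exp.counts
    }
    table = junction_usage.gnssr_table(records)
    groups = junction_usage.groups_from_anchor(exp.genome, gene_id, anchor)
    return junction_usage.compare_junction_groups(
        table, list(groups), exp.conditions, order=order
    )


def mito_profile(exp: Experiment, order: tuple[str, str] | None = None):
    """(compartment percentages per sample, mito gene change table)."""
    totals = [c.totals for c in exp.counts]
    profile = mito_expression.compartment_fractions(totals)
    matrix = mito_expression.gene_count_matrix(exp.counts)
    mito_genes = sorted(
        {
            t.gene_id
            for t in exp.genome.transcripts
            if exp.genome.chromosome(t.chromosome).compartment == "mito"
        }
    )
    cpm = mito_expression.normalize_counts(matrix.loc[matrix.index.isin(mito_genes)], totals)
    changes = mito_expression.gene_change(cpm, exp.conditions, order=order)
    return profile, changes


def precursor_indices(
    exp: Experiment,
    min_overlap: int = precursor_index.DEFAULT_MIN_OVERLAP,
    scale: float = precursor_index.DEFAULT_SCALE,
) -> dict[str, float]:
    """Per-sample precursor index via the vectorized border counter."""
    pairs = precursor_index.enumerate_border_pairs(exp.genome)
    out: dict[str, float] = {}
    for sr, counts in zip(exp.samples, exp.counts):
        by_idx = sr.border_span_counts(pairs, min_overlap)
        raw = {pairs[k].label: v for k, v in by_idx.items()}
        _, mean_index = precursor_index.normalize_border_coverage(
            raw, counts.totals, scale
        )
        out[sr.sample_id] = mean_index
    return out


def precursor_analysis(
    exp: Experiment,
    min_overlap: int = precursor_index.DEFAULT_MIN_OVERLAP,
    order: tuple[str, str] | None = None,
) -> tuple[dict[str, float], GroupComparison]:
    indices = precursor_indices(exp, min_overlap)
    return indices, precursor_index.compare_precursor(indices, exp.conditions, order=order)


def load_experiment(manifest_path: str | Path, gtf_path: str | Path):
    """Load a written experiment: returns (genome, counts list, conditions map).

    Manifest sample paths are resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    first_sam = manifest_path.parent / manifest.iloc[0]["path"]
    lengths = alignment_io.sam_chromosome_lengths(first_sam)
    genome = alignment_io.read_annotation(gtf_path, chrom_lengths=lengths)
    counts = []
    conditions = {}
    for row in manifest.itertuples():
        sam = manifest_path.parent / row.path
        counts.append(alignment_io.sample_counts_from_sam(sam, genome, row.sample_id))
        conditions[row.sample_id] = row.condition
    return genome, counts, conditions
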