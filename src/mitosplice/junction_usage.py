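"""Gene-normalized splice-site usage (GNSSR) and junction-group comparison.

For junction *j* in sample *s* the statistic is a ratio of ratios::

    GNSSR(j, s) = [ c(j, s) / G(s) ] / [ g(gene, s) / T(s) ]

with c = junction read count, G = total gapped (spliced) reads in the sample,
g = union-mode read count of the junction's host gene, and T = total mapped
reads.  The first ratio normalizes junction coverage to sequencing depth of the
spliced fraction; the second divides out the host gene's expression, so GNSSR
moves only when the *relative* use of a splice site changes.  Junctions are
grouped (e.g. upstream vs downstream of an anchor exon) and group means are
compared between conditions with an unpaired Student's t-test.

Absolute GNSSR magnitudes depend on an arbitrary output scale (default 1) and
are not comparable across normalization conventions; ratios, signs and
significance patterns are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GenomeModel, JunctionKey, SampleCounts
from .stats import GroupComparison, t_test_unpaired


@dataclass
class GnssrRecord:
    sample_id: str
    gene_id: str | None   # None when the junction maps to zero or >1 genes
    junction: JunctionKey
    raw_count: int
    gnssr: float | None   # None when the host gene has zero assigned reads


@dataclass(frozen=True)
class JunctionGroup:
    name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.name}: no member junctions")


def junction_gene(key: JunctionKey, genome: GenomeModel) -> str | None:
    """Host gene of a junction: both flanks inside exactly one gene's span."""
    hits = []
    for gene_id, txs in genome.genes().items():
        if txs[0].chromosome != key.chromosome:
            continue
        start = min(t.start for t in txs)
        end = max(t.end for t in txs)
        if start < key.donor_end <= end and start <= key.acceptor_start < end:
            hits.append(gene_id)
    return hits[0] if len(hits) == 1 else None


def compute_gnssr(
    counts: SampleCounts, genome: GenomeModel, *, scale: float = 1.0
) -> list[GnssrRecord]:
    """Per-junction GNSSR for one sample."""
    G = counts.totals.gapped_reads
    T = counts.totals.total_reads
    if G <= 0:
        raise ValueError(f"sample {counts.sample_id}: no gapped reads")
    records = []
    for key, c in counts.junction_counts.items():
        gene = junction_gene(key, genome)
        if gene is None:
            records.append(GnssrRecord(counts.sample_id, None, key, c, None))
            continue
        g = counts.gene_counts.get(gene, 0)
        if g == 0:
            records.append(GnssrRecord(counts.sample_id, gene, key, c, None))
            continue
        gnssr = scale * (c / G) / (g / T)
        records.append(GnssrRecord(counts.sample_id, gene, key, c, gnssr))
    return records


def _junction_label(key: JunctionKey) -> str:
    return f"{key.chromosome}:{key.donor_end}-{key.acceptor_start}:{key.strand}"


def gnssr_table(per_sample_records: dict[str, list[GnssrRecord]]) -> pd.DataFrame:
    """Samples x junctions GNSSR matrix over the observed junction universe.

    The universe is every junction observed (raw count > 0) with a defined GNSSR
    in at least one sample of the experiment; junctions unobserved in a given
    sample contribute 0 there, while undefined entries (host gene unassigned or
    unexpressed in that sample) stay NaN and are skipped by group averaging.
    """
    keys: dict[str, JunctionKey] = {}
    cells: dict[tuple[str, str], float] = {}
    undefined: set[tuple[str, str]] = set()
    for sample_id, records in per_sample_records.items():
        for rec in records:
            if rec.raw_count <= 0:
                continue
            label = _junction_label(rec.junction)
            if rec.gnssr is None:
                undefined.add((sample_id, label))
                continue
            keys[label] = rec.junction
            cells[(sample_id, label)] = rec.gnssr
    if not keys:
        raise ValueError("empty junction universe: no junction observed in any sample")
    table = pd.DataFrame(
        0.0, index=sorted(per_sample_records), columns=sorted(keys)
    )
    for (sample_id, label), value in cells.items():
        table.loc[sample_id, label] = value
    for sample_id, label in undefined:
        if label in table.columns:
            table.loc[sample_id, label] = np.nan
    table.attrs["junction_keys"] = keys
    return table


def _group_columns(table: pd.DataFrame, group: JunctionGroup) -> list[str]:
    keys: dict[str, JunctionKey] = table.attrs["junction_keys"]
    cols = [label for label, key in keys.items() if key in group.members]
    if not cols:
        raise ValueError(
            f"group {group.name}: no member junction observed in any sample"
        )
    return cols


def aggregate_group(
    table: pd.DataFrame, group: JunctionGroup, sample_id: str | None = None
):
    """Mean GNSSR over the group's observed members, per sample.

    Returns a Series over samples, or a float when ``sample_id`` is given.
    """
    means = table[_group_columns(table, group)].mean(axis=1, skipna=True)
    return float(means.loc[sample_id]) if sample_id is not None else means


def groups_from_anchor(
    genome: GenomeModel, gene_id: str, anchor: int
) -> tuple[JunctionGroup, JunctionGroup]:
    """Split a gene's annotated junctions at a genomic anchor coordinate.

    Junctions whose donor end lies before the anchor form the "upstream" group,
    the rest the "downstream" group (the exon-18-style split).
    """
    junctions: set[JunctionKey] = set()
    for tx in genome.transcripts:
        if tx.gene_id == gene_id:
            junctions.update(tx.junctions())
    upstream = frozenset(j for j in junctions if j.donor_end < anchor)
    downstream = frozenset(j for j in junctions if j.donor_end >= anchor)
    return JunctionGroup("upstream", upstream), JunctionGroup("downstream", downstream)


def compare_junction_groups(
    table: pd.DataFrame,
    groups: list[JunctionGroup],
    conditions: dict[str, str],
    order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Unpaired two-sided t-test of per-sample group means between two conditions.

    ``order`` fixes (control, treated); by default the two labels are taken in
    sorted order.  Returns one row per group with per-condition means, t, df, p.
    """
    labels = sorted(set(conditions.values())) if order is None else list(order)
    if len(labels) != 2:
        raise ValueError("exactly two condition labels required")
    rows = []
    for group in groups:
        means = aggregate_group(table, group)
        x = means[[s for s in means.index if conditions[s] == labels[0]]]
        y = means[[s for s in means.index if conditions[s] == labels[1]]]
        if len(x) < 2 or len(y) < 2:
            raise ValueError("need >= 2 samples per condition")
        cmp = t_test_unpaired(x.to_numpy(), y.to_numpy())
        rows.append(
            {
                "group": group.name,
                f"mean_{labels[0]}": cmp.mean_a,
                f"mean_{labels[1]}": cmp.mean_b,
                "t": cmp.t,
                "df": cmp.df,
                "p": cmp.p,
            }
        )
    return pd.DataFrame(rows)
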