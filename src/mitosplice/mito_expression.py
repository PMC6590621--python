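"""Nuclear/mitochondrial read partition and per-gene expression-change summary.

``compartment_fractions`` reproduces the mapped-read partition table (percent of
reads on the nuclear vs the mitochondrial reference).  ``gene_change`` is a
deliberately simple differential-expression surrogate — log2 fold change of
pseudocounted mean CPM with an unpaired t-test on log2(CPM + pseudocount) and
Benjamini-Hochberg adjustment across genes — not a negative-binomial Wald test;
output columns are labelled accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import SampleCounts, SampleTotals
from .stats import bh_adjust, t_test_unpaired


@dataclass
class CompartmentProfile:
    sample_id: str
    nuclear_pct: float
    mito_pct: float
    total_reads: int


def compartment_fractions(totals: list[SampleTotals]) -> pd.DataFrame:
    """Percent of mapped reads per compartment, one row per sample."""
    rows = []
    for t in totals:
        if t.total_reads <= 0:
            raise ValueError(f"sample {t.sample_id}: zero total reads")
        mito_pct = 100.0 * t.mito_reads / t.total_reads
        rows.append(
            {
                "sample_id": t.sample_id,
                "nuclear_pct": 100.0 - mito_pct,
                "mito_pct": mito_pct,
                "total_reads": t.total_reads,
            }
        )
    return pd.DataFrame(rows)


def gene_count_matrix(counts: list[SampleCounts]) -> pd.DataFrame:
    """Genes x samples raw count matrix (absent counts are 0)."""
    table = pd.DataFrame({c.sample_id: pd.Series(c.gene_counts) for c in counts})
    return table.fillna(0).astype(int).sort_index()


def normalize_counts(
    count_matrix: pd.DataFrame, totals: list[SampleTotals]
) -> pd.DataFrame:
    """Counts per million mapped reads (CPM), column-wise per sample."""
    denom = pd.Series({t.sample_id: t.total_reads for t in totals})
    missing = [s for s in count_matrix.columns if s not in denom.index]
    if missing:
        raise ValueError(f"totals missing for samples: {missing}")
    if (denom[count_matrix.columns] <= 0).any():
        raise ValueError("zero total mapped reads")
    return 1e6 * count_matrix / denom[count_matrix.columns]


def gene_change(
    cpm: pd.DataFrame,
    conditions: dict[str, str],
    pseudocount: float = 0.5,
    order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene log2 fold change (treated over control) with BH-adjusted t-test p.

    l2fc = log2[(mean CPM_treated + pc) / (mean CPM_control + pc)]; the t-test is
    computed on log2(CPM + pc) per sample.  ``order`` fixes (control, treated).
    """
    labels = sorted(set(conditions.values())) if order is None else list(order)
    if len(labels) != 2:
        raise ValueError("exactly two condition labels required")
    con_cols = [s for s in cpm.columns if conditions[s] == labels[0]]
    trt_cols = [s for s in cpm.columns if conditions[s] == labels[1]]
    if len(con_cols) < 2 or len(trt_cols) < 2:
        raise ValueError("need >= 2 samples per condition")

    mean_con = cpm[con_cols].mean(axis=1)
    mean_trt = cpm[trt_cols].mean(axis=1)
    l2fc = np.log2((mean_trt + pseudocount) / (mean_con + pseudocount))
    log_cpm = np.log2(cpm + pseudocount)
    pvals = np.array(
        [
            t_test_unpaired(log_cpm.loc[g, trt_cols], log_cpm.loc[g, con_cols]).p
            for g in cpm.index
        ]
    )
    return pd.DataFrame(
        {
            "gene_id": cpm.index,
            "l2fc": l2fc.to_numpy(),
            "p": pvals,
            "adjusted_p": bh_adjust(pvals),
            f"mean_cpm_{labels[0]}": mean_con.to_numpy(),
            f"mean_cpm_{labels[1]}": mean_trt.to_numpy(),
        }
    ).reset_index(drop=True)
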