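"""qPCR relative quantification by the 2^-dCt method.

Relative expression of a target against a reference amplicon measured in the
same sample is 2^-(Ct_target - Ct_reference), assuming perfect doubling per
cycle (no efficiency correction).  The same arithmetic with a mitochondrial
amplicon against a single-copy nuclear gene yields relative mtDNA content.
Technical replicates are averaged on the Ct scale (a geometric mean on the
quantity scale); no-RT mock controls, when present, flag possible genomic DNA
contamination if the mock Ct comes within 5 cycles of the RT Ct.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import t_test_unpaired

CT_MIN, CT_MAX = 0.0, 60.0
MOCK_CT_MARGIN = 5.0


@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    target: str
    ct: float
    condition: str = ""
    is_mock: bool = False

    def __post_init__(self) -> None:
        if not self.target:
            raise ValueError("empty target name")
        if not CT_MIN < self.ct < CT_MAX:
            raise ValueError(f"Ct {self.ct} outside ({CT_MIN}, {CT_MAX})")


def relative_quantity(ct_target: float, ct_reference: float) -> float:
    """2^-(Ct_target - Ct_reference); 1.0 means equal abundance."""
    for ct in (ct_target, ct_reference):
        if not CT_MIN < ct < CT_MAX:
            raise ValueError(f"Ct {ct} outside sanity bounds ({CT_MIN}, {CT_MAX})")
    return float(2.0 ** -(ct_target - ct_reference))


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns sample, condition, target, ct and optional is_mock."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "condition", "target", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if "is_mock" not in df.columns:
        df["is_mock"] = False
    df["is_mock"] = df["is_mock"].astype(bool)
    return df


def _mean_ct(df: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates per (sample, target) on the Ct scale."""
    for ct in df["ct"]:
        if not CT_MIN < ct < CT_MAX:
            raise ValueError(f"Ct {ct} outside sanity bounds")
    return (
        df.groupby(["sample", "condition", "target"], as_index=False)["ct"].mean()
    )


def per_sample_rq(records: pd.DataFrame, reference_target: str) -> pd.DataFrame:
    """Per-sample 2^-dCt of every non-reference target against the reference.

    Samples lacking a reference Ct are dropped (their count is reported in
    ``df.attrs['n_excluded_samples']``).  Mock (no-RT) rows never enter the
    quantification; targets whose mock Ct is within 5 cycles of the RT Ct in
    some sample are listed in ``df.attrs['contamination_flags']``.
    """
    rt = _mean_ct(records[~records["is_mock"]])
    ref = rt[rt["target"] == reference_target].set_index("sample")["ct"]
    targets = rt[rt["target"] != reference_target]
    have_ref = targets["sample"].isin(ref.index)
    excluded = sorted(targets.loc[~have_ref, "sample"].unique())
    targets = targets[have_ref].copy()
    targets["rq"] = 2.0 ** -(targets["ct"].to_numpy() - ref[targets["sample"]].to_numpy())

    flags: list[tuple[str, str]] = []
    mocks = records[records["is_mock"]]
    if len(mocks):
        mock_ct = _mean_ct(mocks.assign(is_mock=False)).set_index(["sample", "target"])["ct"]
        for row in targets.itertuples():
            key = (row.sample, row.target)
            if key in mock_ct.index and mock_ct[key] - row.ct < MOCK_CT_MARGIN:
                flags.append(key)

    out = targets.rename(columns={"sample": "sample_id"})[
        ["sample_id", "condition", "target", "ct", "rq"]
    ].reset_index(drop=True)
    out["reference"] = reference_target
    out.attrs["n_excluded_samples"] = len(excluded)
    out.attrs["excluded_samples"] = excluded
    out.attrs["contamination_flags"] = flags
    return out


def summarize_qpcr(
    records: pd.DataFrame,
    reference_target: str,
    order: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample rq plus per-target condition means +/- SEM and t-test p.

    Returns (per-sample rq table, per-target summary).  ``order`` fixes the
    (control, treated) labels; default is sorted label order.
    """
    rq = per_sample_rq(records, reference_target)
    labels = sorted(rq["condition"].unique()) if order is None else list(order)
    if len(labels) != 2:
        raise ValueError("exactly two condition labels required")
    rows = []
    for target, sub in rq.groupby("target"):
        x = sub.loc[sub["condition"] == labels[0], "rq"].to_numpy()
        y = sub.loc[sub["condition"] == labels[1], "rq"].to_numpy()
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"target {target}: need >= 2 samples per condition")
        cmp = t_test_unpaired(x, y)
        rows.append(
            {
                "target": target,
                f"mean_{labels[0]}": cmp.mean_a,
                f"sem_{labels[0]}": float(np.std(x, ddof=1) / np.sqrt(len(x))),
                f"mean_{labels[1]}": cmp.mean_b,
                f"sem_{labels[1]}": float(np.std(y, ddof=1) / np.sqrt(len(y))),
                "fold_change": cmp.mean_b / cmp.mean_a if cmp.mean_a else np.nan,
                "t": cmp.t,
                "df": cmp.df,
                "p": cmp.p,
                f"n_{labels[0]}": cmp.n_a,
                f"n_{labels[1]}": cmp.n_b,
            }
        )
    return rq, pd.DataFrame(rows)


def mtdna_content(
    records: pd.DataFrame,
    mito_target: str = "mtDNA",
    reference_target: str = "NXN",
    order: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative mtDNA copy number: 2^-dCt of a mito amplicon vs a single-copy
    nuclear gene, with the same group comparison as transcript qPCR."""
    sub = records[records["target"].isin({mito_target, reference_target})]
    rq, summary = summarize_qpcr(sub, reference_target, order=order)
    return rq, summary[summary["target"] == mito_target].reset_index(drop=True)


def simulate_ct_table(
    fold_changes: dict[str, float],
    n_per_group: int = 6,
    noise_sd: float = 0.2,
    reference_target: str = "RPL32",
    base_ct: float = 25.0,
    reference_ct: float = 20.0,
    conditions: tuple[str, str] = ("con", "ldl"),
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic Ct measurements with known per-target fold changes.

    Targets sit at ``base_ct`` in the control condition and are shifted by
    -log2(fold) cycles in the treated condition; every Ct gets independent
    Normal(0, noise_sd^2) measurement noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    con, trt = conditions
    for g, condition in enumerate(conditions):
        for i in range(n_per_group):
            sample = f"{condition}_{i + 1}"
            rows.append(
                {
                    "sample": sample,
                    "condition": condition,
                    "target": reference_target,
                    "ct": reference_ct + rng.normal(0, noise_sd),
                    "is_mock": False,
                }
            )
            for target, fold in fold_changes.items():
                shift = -np.log2(fold) if condition == trt else 0.0
                rows.append(
                    {
                        "sample": sample,
                        "condition": condition,
                        "target": target,
                        "ct": base_ct + shift + rng.normal(0, noise_sd),
                        "is_mock": False,
                    }
                )
    return pd.DataFrame(rows)
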