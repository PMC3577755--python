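"""Relative expression from qPCR threshold cycles (the ΔCt method).

Relative expression of a target against a reference gene is
RE = 2^-(mean Ct_target - mean Ct_reference), with replicate Ct values
averaged on the cycle scale before exponentiation.  Individual Ct values
outside the validity window [15, 30] cycles are unavailable (N/A) and
excluded.  Fold-change calls between time points are descriptive: a ratio
above the threshold (default 2) is "up", below its reciprocal "down".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

CT_MIN = 15.0
CT_MAX = 30.0

_CT_COLUMNS = ["gene", "condition", "timepoint", "replicate", "ct"]


@dataclass(frozen=True)
class CtTable:
    """Long-format Ct measurements plus the reference gene id."""

    data: pd.DataFrame
    reference: str

    def __post_init__(self):
        missing = set(_CT_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        if self.reference not in set(self.data["gene"]):
            raise ValueError(f"reference gene {self.reference!r} not in table")

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.data["gene"]) - {self.reference})

    def conditions(self) -> list[tuple]:
        sub = self.data[["condition", "timepoint"]].drop_duplicates()
        return [tuple(r) for r in sub.itertuples(index=False)]


def read_ct_table(path, reference: str) -> CtTable:
    """CSV with columns gene, condition, timepoint, replicate, ct."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    return CtTable(data=df[_CT_COLUMNS].copy(), reference=reference)


def validity_filter(ct: float) -> bool:
    """A Ct value is usable iff it lies in [15, 30] cycles."""
    return CT_MIN <= ct <= CT_MAX


def _mean_ct(table: CtTable, gene: str, condition, timepoint) -> Optional[float]:
    rows = table.data[
        (table.data["gene"] == gene)
        & (table.data["condition"] == condition)
        & (table.data["timepoint"] == timepoint)
    ]
    valid = rows["ct"][rows["ct"].apply(validity_filter)]
    if valid.empty:
        return None
    return float(valid.mean())


def relative_expression(table: CtTable, gene: str, condition,
                        timepoint) -> Optional[float]:
    """2^-ΔCt, or None (N/A) if target or reference has no valid replicate."""
    ct_gene = _mean_ct(table, gene, condition, timepoint)
    ct_ref = _mean_ct(table, table.reference, condition, timepoint)
    if ct_gene is None or ct_ref is None:
        return None
    return 2.0 ** (-(ct_gene - ct_ref))


def fold_change_call(re_t: float, re_0: float, threshold: float = 2.0) -> str:
    """"up" / "down" / "unchanged" comparison of two relative expressions."""
    if re_0 == 0:
        raise ValueError("baseline relative expression is zero")
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    ratio = re_t / re_0
    if ratio > threshold:
        return "up"
    if ratio < 1.0 / threshold:
        return "down"
    return "unchanged"


def expression_report(table: CtTable, baseline_timepoint,
                      threshold: float = 2.0) -> pd.DataFrame:
    """RE for every gene/condition/timepoint plus the fold-change call
    against the baseline timepoint of the same condition."""
    records = []
    for gene in table.genes:
        for condition, timepoint in table.conditions():
            re_t = relative_expression(table, gene, condition, timepoint)
            re_0 = relative_expression(table, gene, condition, baseline_timepoint)
            call = None
            if re_t is not None and re_0 not in (None, 0):
                call = fold_change_call(re_t, re_0, threshold)
            records.append({
                "gene": gene, "condition": condition, "timepoint": timepoint,
                "re": re_t, "call": call,
            })
    return pd.DataFrame.from_records(records)
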