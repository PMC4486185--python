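"""RQ-PCR reduction: triplicate Ct summaries and dCt relative quantities.

A Ct table holds one row per technical replicate with columns
``bag_id, day, target, replicate, ct``.  Replicates are reduced to a
mean Ct per (bag, day, target); each target is then quantified against
the endogenous control (mir-191, the most abundant platelet miRNA on
every storage day) by the dCt method:

    delta_ct = Ct(target) - Ct(reference)
    RQ       = 2 ** (-delta_ct)

Amplification efficiency is fixed at 2.0 (100%) and no inter-day
calibrator sample is applied, so log2(RQ) is exactly ``-delta_ct``.
Cross-bag summaries and paired t-tests between storage days complete
the validation-side pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference import REFERENCE_CONTROL

__all__ = [
    "CtSummary",
    "RQResult",
    "read_ct_table",
    "write_ct_table",
    "reduce_replicates",
    "relative_quantity",
    "compute_rq",
    "cohort_summary",
    "paired_t",
]

CT_COLUMNS = ["bag_id", "day", "target", "replicate", "ct"]

#: Default replicate-QC bound: triplicates wider than 0.5 cycles are flagged.
DEFAULT_MAX_SD = 0.5


@dataclass(frozen=True)
class CtSummary:
    mean_ct: float
    sd: float
    qc_pass: bool


@dataclass(frozen=True)
class RQResult:
    """Relative quantity of one target in one bag on one storage day."""

    bag_id: str
    day: int
    target: str
    delta_ct: float
    rq: float
    replicate_sd: float
    qc_pass: bool = True


def read_ct_table(path) -> pd.DataFrame:
    """Read a replicate-level Ct table (CSV, ``#`` comments allowed)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing Ct-table columns {missing}")
    return df


def write_ct_table(ct_table: pd.DataFrame, path, *, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        ct_table.to_csv(fh, index=False)


def reduce_replicates(cts: Sequence[float], max_sd: float = DEFAULT_MAX_SD) -> CtSummary:
    """Arithmetic mean and sample SD of the technical replicates.

    At least two replicates are required; the summary is QC-flagged
    (``qc_pass=False``) when the replicate SD exceeds ``max_sd`` cycles.
    """
    arr = np.asarray(cts, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need >= 2 replicates, got {arr.size}")
    sd = float(arr.std(ddof=1))
    return CtSummary(float(arr.mean()), sd, sd <= max_sd)


def relative_quantity(mean_ct_target: float, mean_ct_reference: float) -> tuple[float, float]:
    """(delta_ct, rq) of a target against the reference control.

    Monotone decreasing in the target Ct; rq == 1 exactly when the two
    Ct means coincide.
    """
    delta_ct = float(mean_ct_target) - float(mean_ct_reference)
    return delta_ct, 2.0 ** (-delta_ct)


def compute_rq(
    ct_table: pd.DataFrame,
    reference: str = REFERENCE_CONTROL,
    max_sd: float = DEFAULT_MAX_SD,
) -> pd.DataFrame:
    """Reduce a replicate-level Ct table to per-bag/day/target RQ values.

    Returns a DataFrame with columns ``bag_id, day, target, delta_ct,
    rq, replicate_sd, qc_pass`` containing every non-reference target;
    the reference rows are consumed as the per-bag/day denominator.
    A bag/day with no reference measurements is an error.
    """
    if reference not in set(ct_table["target"]):
        raise ValueError(f"reference target {reference!r} absent from Ct table")

    summaries: dict[tuple, CtSummary] = {}
    for (bag, day, target), grp in ct_table.groupby(["bag_id", "day", "target"], sort=True):
        summaries[(bag, day, target)] = reduce_replicates(grp["ct"].to_numpy(), max_sd)

    rows = []
    for (bag, day, target), summ in summaries.items():
        if target == reference:
            continue
        ref_summ = summaries.get((bag, day, reference))
        if ref_summ is None:
            raise ValueError(f"no reference ({reference}) Ct for bag {bag!r} day {day}")
        delta_ct, rq = relative_quantity(summ.mean_ct, ref_summ.mean_ct)
        rows.append(
            RQResult(bag, int(day), target, delta_ct, rq, summ.sd,
                     summ.qc_pass and ref_summ.qc_pass)
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def cohort_summary(rq_results: pd.DataFrame) -> pd.DataFrame:
    """Cross-bag mean, SD and n of RQ per (day, target).

    SD is the sample standard deviation (ddof=1); a single-bag cell
    reports SD 0.0.
    """
    if rq_results.empty:
        return pd.DataFrame(columns=["day", "target", "mean", "sd", "n"])
    grouped = rq_results.groupby(["day", "target"])["rq"]
    out = grouped.agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0,
                      n="count").reset_index()
    return out


def paired_t(values_i: Mapping, values_j: Mapping) -> tuple[float, float]:
    """Paired two-sided t-test on per-bag values from two storage days.

    ``values_i`` / ``values_j`` map bag id -> RQ; the bags must match
    exactly (pairing is by bag, the only entity repeated across days).
    Returns (t statistic, two-sided p).
    """
    keys_i, keys_j = set(values_i), set(values_j)
    if keys_i != keys_j:
        unpaired = sorted(keys_i ^ keys_j)
        raise ValueError(f"unpaired bags: {unpaired}")
    if len(keys_i) < 2:
        raise ValueError("need >= 2 paired bags")
    bags = sorted(keys_i)
    x = np.array([values_i[b] for b in bags], dtype=float)
    y = np.array([values_j[b] for b in bags], dtype=float)
    if np.allclose(x, y):
        return 0.0, 1.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)
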