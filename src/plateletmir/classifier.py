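"""Bag-validity decision rule on mir-127 vs mir-320a relative expression.

During cold-room storage the two biomarkers invert: mir-127 outranks
mir-320a during the first three days and falls below it from day 4, the
window in which platelet storage damage becomes measurable.  A bag is
therefore called VALID (physiologically normal platelets) when its
mir-127 expression is greater than or equal to its mir-320a expression,
and DAMAGED otherwise.  The rule is a ratio test — rq127/rq320a >= 1 —
so it is invariant to any common rescaling, in particular to the choice
of endogenous control.  It applies equally to RQ-PCR relative
quantities and to sequencing RPM values; label the input mode when
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .reference import MIR127, MIR320A

__all__ = ["Validity", "ValidityCall", "classify", "classify_cohort"]


class Validity(str, Enum):
    VALID = "VALID"
    DAMAGED = "DAMAGED"


@dataclass(frozen=True)
class ValidityCall:
    """One validity decision (per bag or per cohort-day summary)."""

    bag_id: str
    day: int | None
    rq127: float
    rq320a: float
    ratio: float
    label: Validity


def classify(rq127: float, rq320a: float, *, bag_id: str = "", day: int | None = None) -> ValidityCall:
    """VALID iff rq127 >= rq320a (inclusive boundary); DAMAGED otherwise."""
    if rq127 <= 0 or rq320a <= 0:
        raise ValueError(
            f"relative quantities must be positive, got rq127={rq127}, rq320a={rq320a}"
        )
    ratio = rq127 / rq320a
    label = Validity.VALID if rq127 >= rq320a else Validity.DAMAGED
    return ValidityCall(bag_id, day, float(rq127), float(rq320a), float(ratio), label)


def classify_cohort(
    rq_results: pd.DataFrame,
    target_127: str = MIR127,
    target_320a: str = MIR320A,
) -> tuple[list[ValidityCall], pd.DataFrame]:
    """Classify every (bag, day) unit of a per-bag RQ table.

    ``rq_results`` is the :func:`plateletmir.rqpcr.compute_rq` output
    (columns ``bag_id, day, target, rq``).  Units missing either target
    are skipped with a warning column in the summary.  Returns the
    per-unit calls (ordered by day then bag) and a per-day summary frame
    with columns ``day, n_valid, n_damaged, n_skipped``.
    """
    calls: list[ValidityCall] = []
    skipped: dict[int, int] = {}
    wide = rq_results.pivot_table(index=["bag_id", "day"], columns="target",
                                  values="rq", aggfunc="first")
    for (bag, day) in sorted(wide.index, key=lambda t: (t[1], str(t[0]))):
        row = wide.loc[(bag, day)]
        v127 = row.get(target_127)
        v320 = row.get(target_320a)
        if v127 is None or v320 is None or pd.isna(v127) or pd.isna(v320):
            skipped[day] = skipped.get(day, 0) + 1
            continue
        calls.append(classify(float(v127), float(v320), bag_id=str(bag), day=int(day)))

    days = sorted({c.day for c in calls} | set(skipped))
    summary = pd.DataFrame(
        {
            "day": days,
            "n_valid": [sum(1 for c in calls if c.day == d and c.label is Validity.VALID)
                        for d in days],
            "n_damaged": [sum(1 for c in calls if c.day == d and c.label is Validity.DAMAGED)
                          for d in days],
            "n_skipped": [skipped.get(d, 0) for d in days],
        }
    )
    return calls, summary


def calls_to_frame(calls: list[ValidityCall]) -> pd.DataFrame:
    """Validity calls as a flat DataFrame (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "bag_id": c.bag_id,
                "day": c.day,
                "rq127": c.rq127,
                "rq320a": c.rq320a,
                "ratio": c.ratio,
                "label": c.label.value,
            }
            for c in calls
        ]
    )
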