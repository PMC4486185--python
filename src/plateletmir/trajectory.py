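"""Top-k rankings per storage day and rank-trajectory analysis.

In anucleate platelets the most abundant miRNAs drift in rank as storage
damage accumulates; the objects here capture that drift: the per-day
top-k lists, their union, the per-miRNA rank paths, the day-to-day list
turnover, and value crossovers between designated miRNA pairs (the
mir-127 / mir-320a inversion is the damage signature of interest).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["TrajectoryTable", "top_k", "build_trajectory", "detect_crossover"]


def top_k(rpm_matrix: pd.DataFrame, sample, k: int = 10) -> list[str]:
    """The k most abundant miRNA ids in ``sample``, rank 1 first.

    Ties are broken lexicographically by id so the ranking is
    deterministic; the result is invariant to positive rescaling of the
    column (so raw counts, RPM or any per-sample scaling agree).
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if sample not in rpm_matrix.columns:
        raise KeyError(f"unknown sample {sample!r}")
    if k > len(rpm_matrix.index):
        raise ValueError(f"k={k} exceeds the {len(rpm_matrix.index)} miRNAs present")
    col = rpm_matrix[sample]
    order = sorted(col.index, key=lambda m: (-col[m], m))
    return order[:k]


@dataclass
class TrajectoryTable:
    """Per-day top-k lists plus derived turnover and rank paths.

    ``rank_paths`` maps miRNA id -> {day -> rank}; a day is absent when
    the miRNA fell outside that day's list.  ``entries``/``exits`` give
    the turnover relative to the previous sampled day.
    """

    days: list[int]
    k: int
    topk_lists: dict[int, list[str]]
    union_ids: set[str] = field(default_factory=set)
    rank_paths: dict[str, dict[int, int]] = field(default_factory=dict)
    entries: dict[int, set[str]] = field(default_factory=dict)
    exits: dict[int, set[str]] = field(default_factory=dict)

    def rank_path_frame(self) -> pd.DataFrame:
        """Rank paths as a DataFrame (rows miRNA, columns day, NA = absent)."""
        df = pd.DataFrame(
            {d: {m: self.rank_paths[m].get(d) for m in sorted(self.union_ids)}
             for d in self.days}
        )
        df.index.name = "mirna_id"
        return df.astype("Int64")

    def to_tsv(self, path) -> None:
        self.rank_path_frame().to_csv(path, sep="\t", na_rep="NA")

    def turnover_json(self, path) -> None:
        payload = {
            "days": self.days,
            "k": self.k,
            "union_size": len(self.union_ids),
            "entries": {str(d): sorted(v) for d, v in self.entries.items()},
            "exits": {str(d): sorted(v) for d, v in self.exits.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def build_trajectory(topk_lists: dict[int, list[str]]) -> TrajectoryTable:
    """Assemble a TrajectoryTable from per-day top-k lists."""
    if not topk_lists:
        raise ValueError("no per-day lists given")
    days = sorted(topk_lists)
    ks = {len(v) for v in topk_lists.values()}
    if len(ks) != 1:
        raise ValueError(f"inconsistent list lengths: {sorted(ks)}")
    (k,) = ks
    for d in days:
        if len(set(topk_lists[d])) != k:
            raise ValueError(f"day {d} list contains duplicate ids")

    table = TrajectoryTable(days=days, k=k,
                            topk_lists={d: list(topk_lists[d]) for d in days})
    table.union_ids = set().union(*(set(v) for v in topk_lists.values()))
    for m in table.union_ids:
        table.rank_paths[m] = {
            d: topk_lists[d].index(m) + 1 for d in days if m in topk_lists[d]
        }
    for prev, cur in zip(days, days[1:]):
        prev_set, cur_set = set(topk_lists[prev]), set(topk_lists[cur])
        table.entries[cur] = cur_set - prev_set
        table.exits[cur] = prev_set - cur_set
    return table


def detect_crossover(values, id_a: str, id_b: str) -> int | None:
    """Earliest day on which ``id_a`` drops strictly below ``id_b``.

    ``values`` is either an expression matrix (rows miRNA, columns days)
    or a :class:`TrajectoryTable`; with a table, ranks stand in for
    expression (a larger rank number means lower expression).  Ties are
    never a crossover — equality keeps ``id_a`` on top, mirroring the
    inclusive boundary of the validity rule.  Days on which either id is
    missing are flagged as incomparable and skipped.  Returns None when
    ``id_a`` never drops below ``id_b``.
    """
    if isinstance(values, TrajectoryTable):
        days = values.days
        path_a = values.rank_paths.get(id_a, {})
        path_b = values.rank_paths.get(id_b, {})
        # negate ranks: rank 1 is the highest expression
        get = lambda path, d: -path[d] if d in path else None
        series_a = {d: get(path_a, d) for d in days}
        series_b = {d: get(path_b, d) for d in days}
    else:
        for m in (id_a, id_b):
            if m not in values.index:
                raise KeyError(f"unknown miRNA {m!r}")
        days = list(values.columns)
        series_a = {d: values.at[id_a, d] for d in days}
        series_b = {d: values.at[id_b, d] for d in days}

    for d in days:
        va, vb = series_a[d], series_b[d]
        if va is None or vb is None or (isinstance(va, float) and math.isnan(va)) \
                or (isinstance(vb, float) and math.isnan(vb)):
            warnings.warn(f"day {d}: {id_a} vs {id_b} incomparable (missing value)")
            continue
        if va < vb:
            return d
    return None
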