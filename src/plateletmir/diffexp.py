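"""Two-library differential expression with the two-fold / p <= 0.05 rule.

Pooled sequencing gives one library per storage day, so the test is an
exact conditional binomial: under the null of equal relative abundance
in libraries *a* and *b*, the count in *a* given the pooled total
``count_a + count_b`` is Binomial(count_a + count_b, total_a / (total_a
+ total_b)).  The two-sided p-value sums the probabilities of all
outcomes no more likely than the observed one (minimum-likelihood
convention, ties included).  Fold changes are ratios of reads-per-million,
so they are invariant to library depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = ["DEResult", "de_test", "de_screen", "write_de_table"]


@dataclass(frozen=True)
class DEResult:
    """Differential-expression call for one miRNA between two libraries.

    ``log2fc`` is log2(RPM_b / RPM_a): positive when the miRNA is more
    abundant in library *b*.  ``fold_change`` is the larger/smaller RPM
    ratio (>= 1, +inf when one side is zero).  ``is_de`` applies the
    decision rule |fold change| >= min_fold AND p <= alpha.
    ``undefined_fc`` flags the zero/zero case (p = 1, no fold change).
    """

    mirna_id: str
    count_a: int
    count_b: int
    total_a: int
    total_b: int
    fold_change: float
    log2fc: float
    p_value: float
    is_de: bool
    undefined_fc: bool = False


def de_test(
    count_a: int,
    total_a: int,
    count_b: int,
    total_b: int,
    *,
    mirna_id: str = "",
    alpha: float = 0.05,
    min_fold: float = 2.0,
) -> DEResult:
    """Exact conditional binomial test for one miRNA across two libraries."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if count_a > total_a or count_b > total_b:
        raise ValueError("count exceeds its library total")

    n = count_a + count_b
    if n == 0:
        return DEResult(mirna_id, count_a, count_b, total_a, total_b,
                        math.nan, math.nan, 1.0, False, undefined_fc=True)

    p_null = total_a / (total_a + total_b)
    p_value = stats.binomtest(count_a, n=n, p=p_null, alternative="two-sided").pvalue
    # the exact p includes the observed outcome so it is strictly positive;
    # floor at the smallest denormal to undo floating-point underflow
    p_value = max(float(p_value), 5e-324)

    rpm_a = 1e6 * count_a / total_a
    rpm_b = 1e6 * count_b / total_b
    if rpm_a == 0:
        log2fc = math.inf
    elif rpm_b == 0:
        log2fc = -math.inf
    else:
        log2fc = math.log2(rpm_b / rpm_a)
    fold_change = 2.0 ** abs(log2fc) if math.isfinite(log2fc) else math.inf

    is_de = abs(log2fc) >= math.log2(min_fold) and p_value <= alpha
    return DEResult(mirna_id, count_a, count_b, total_a, total_b,
                    fold_change, log2fc, float(p_value), bool(is_de))


def de_screen(
    counts: pd.DataFrame,
    reference_sample,
    test_sample,
    *,
    alpha: float = 0.05,
    min_fold: float = 2.0,
) -> list[DEResult]:
    """Screen every miRNA of ``counts`` between two sample columns.

    ``reference_sample`` plays the role of library *a* (e.g. storage
    day 1) and ``test_sample`` library *b*; results are ordered by
    miRNA id.  Library sizes are the column totals.
    """
    for s in (reference_sample, test_sample):
        if s not in counts.columns:
            raise KeyError(f"unknown sample {s!r}")
    total_a = int(counts[reference_sample].sum())
    total_b = int(counts[test_sample].sum())
    results = []
    for mirna_id in sorted(counts.index):
        results.append(
            de_test(
                int(counts.at[mirna_id, reference_sample]), total_a,
                int(counts.at[mirna_id, test_sample]), total_b,
                mirna_id=mirna_id, alpha=alpha, min_fold=min_fold,
            )
        )
    return results


def write_de_table(results: list[DEResult], path, *, header_comment: str | None = None) -> None:
    """Write DE results as a TSV table."""
    df = pd.DataFrame([r.__dict__ for r in results])
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
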