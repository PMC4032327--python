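"""Pseudocount fold-change and two-tailed Fisher differential testing.

Per protein, abundance in tumor vs control is summarized by the
pseudocounted ratio of mean unique-peptide counts,

    FC = (mean_tumor + 1) / (mean_control + 1),

and significance by a two-tailed Fisher's exact test on the 2x2 table of
the protein's pooled group counts against the remainder of each group's
total.  Proteins with FC > 2 (or < 1/2) and p < 0.05 are selected as
differentially expressed — both inequalities strict.

The two-tailed p-value is the 'sum of small p' rule: the sum, over the
hypergeometric support fixed by the table margins, of point probabilities
not exceeding the observed table's probability (ties admitted within a
relative tolerance of 1e-7, matching the convention of the mainstream
statistical environments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .evidence import CountMatrix

__all__ = [
    "ContingencyTable",
    "DiffRecord",
    "fold_change",
    "fisher_two_tailed",
    "build_contingency",
    "test_all_proteins",
    "select_significant",
    "adjust_bh",
    "diff_table",
    "write_diff_table",
]

#: Relative tolerance used to admit ties at the observed point probability.
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: (a, b) = protein / rest counts in tumor, (c, d) in control."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"table entries must be non-negative integers, {name}={v}")


@dataclass(frozen=True)
class DiffRecord:
    """Per-protein differential-expression result."""

    accession: str
    avg_control: float
    avg_tumor: float
    fc: float
    p: float
    direction: str  # 'up' / 'down' / 'none'
    significant: bool


def fold_change(avg_t: float, avg_c: float) -> float:
    """Pseudocounted ratio of group means, (avg_t + 1) / (avg_c + 1).

    The +1 on both averages avoids division by zero when a protein has no
    unique peptides in one condition.
    """
    if avg_t < 0 or avg_c < 0:
        raise ValueError("averages must be non-negative")
    return (avg_t + 1.0) / (avg_c + 1.0)


def fisher_two_tailed(table: ContingencyTable | tuple[int, int, int, int]) -> float:
    """Two-tailed Fisher's exact p-value by the sum-of-small-p rule.

    Point probabilities are hypergeometric with the observed margins; the
    p-value sums those <= the observed table's probability (relative tie
    tolerance 1e-7).  A degenerate table (any zero margin) has a
    single-point support and returns 1 by convention.  The result is always
    in (0, 1].
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1 = a + b  # tumor margin
    k1 = a + c  # protein margin
    if n == 0 or r1 == 0 or r1 == n or k1 == 0 or k1 == n:
        return 1.0
    lo = max(0, k1 - (n - r1))
    hi = min(r1, k1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, k1, r1)
    p_obs = pmf[a - lo]
    mask = pmf <= p_obs * (1.0 + TIE_RTOL)
    if mask.all():
        return 1.0
    p = float(pmf[mask].sum())
    return min(1.0, max(p, math.ulp(0.0)))


def build_contingency(matrix: CountMatrix, accession: str) -> ContingencyTable:
    """Pooled 2x2 table for one protein.

    a = protein counts summed over tumor samples, b = all-protein tumor
    total minus a; c, d likewise for control.  Pooled integer sums are used
    because Fisher's test needs integers; the group means enter the
    fold-change only.
    """
    if accession not in matrix.counts.index:
        raise KeyError(f"accession {accession!r} not in count matrix")
    tumor = matrix.samples_in_group("tumor")
    control = matrix.samples_in_group("control")
    tot_t = int(matrix.counts[tumor].values.sum())
    tot_c = int(matrix.counts[control].values.sum())
    a = int(matrix.counts.loc[accession, tumor].sum())
    c = int(matrix.counts.loc[accession, control].sum())
    return ContingencyTable(a=a, b=tot_t - a, c=c, d=tot_c - c)


def test_all_proteins(
    matrix: CountMatrix,
    *,
    fc_cut: float = 2.0,
    alpha: float = 0.05,
    table_mode: str = "pooled",
) -> list[DiffRecord]:
    """FC + Fisher for every protein in the matrix.

    ``table_mode='pooled'`` (default) builds each 2x2 from pooled integer
    group sums; ``'rounded_average'`` uses rounded group means instead, as
    a sensitivity analysis.  Direction compares the raw group means;
    ``significant`` applies the strict FC/alpha cuts in either direction.
    """
    if table_mode not in ("pooled", "rounded_average"):
        raise ValueError(f"unknown table_mode {table_mode!r}")
    tumor = matrix.samples_in_group("tumor")
    control = matrix.samples_in_group("control")
    if not tumor or not control:
        raise ValueError("count matrix must contain both tumor and control samples")

    t_counts = matrix.counts[tumor].to_numpy()
    c_counts = matrix.counts[control].to_numpy()
    t_sum = t_counts.sum(axis=1)
    c_sum = c_counts.sum(axis=1)
    if table_mode == "pooled":
        a_col, c_col = t_sum, c_sum
    else:
        a_col = np.rint(t_sum / len(tumor)).astype(int)
        c_col = np.rint(c_sum / len(control)).astype(int)
    tot_t = int(a_col.sum())
    tot_c = int(c_col.sum())

    out: list[DiffRecord] = []
    for i, acc in enumerate(matrix.counts.index):
        avg_t = float(t_sum[i]) / len(tumor)
        avg_c = float(c_sum[i]) / len(control)
        fc = fold_change(avg_t, avg_c)
        a = int(a_col[i])
        c = int(c_col[i])
        p = fisher_two_tailed(ContingencyTable(a, tot_t - a, c, tot_c - c))
        if avg_t > avg_c:
            direction = "up"
        elif avg_t < avg_c:
            direction = "down"
        else:
            direction = "none"
        significant = p < alpha and (fc > fc_cut or fc < 1.0 / fc_cut)
        out.append(
            DiffRecord(
                accession=str(acc),
                avg_control=avg_c,
                avg_tumor=avg_t,
                fc=fc,
                p=p,
                direction=direction,
                significant=significant,
            )
        )
    return out


test_all_proteins.__test__ = False  # statistical routine, not a pytest case


def select_significant(
    records: Sequence[DiffRecord], fc_cut: float = 2.0, alpha: float = 0.05
) -> tuple[list[DiffRecord], list[DiffRecord]]:
    """Partition into (up, down) by strict FC and p cuts.

    up: fc > fc_cut and p < alpha; down: fc < 1/fc_cut and p < alpha.
    The down-regulation bound is the reciprocal of the up cut.
    """
    up = [r for r in records if r.fc > fc_cut and r.p < alpha]
    down = [r for r in records if r.fc < 1.0 / fc_cut and r.p < alpha]
    return up, down


def adjust_bh(records: Sequence[DiffRecord]) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values, indexed by accession.

    Offered as an option; the default selection applies no multiplicity
    correction.
    """
    from statsmodels.stats.multitest import multipletests

    pvals = [r.p for r in records]
    _, q, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.Series(q, index=[r.accession for r in records], name="q")


def diff_table(records: Sequence[DiffRecord]) -> pd.DataFrame:
    """Results as a DataFrame (accession, avg_control, avg_tumor, fc, p, ...)."""
    return pd.DataFrame(
        {
            "accession": [r.accession for r in records],
            "avg_control": [r.avg_control for r in records],
            "avg_tumor": [r.avg_tumor for r in records],
            "fc": [r.fc for r in records],
            "p": [r.p for r in records],
            "direction": [r.direction for r in records],
            "significant": [r.significant for r in records],
        }
    )


def write_diff_table(records: Sequence[DiffRecord], path: str | Path) -> None:
    diff_table(records).to_csv(path, sep="\t", index=False)
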