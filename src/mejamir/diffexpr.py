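"""Exact two-library differential expression test for count data.

For a tag observed x times in a library of N1 total clean tags, the
probability of observing it y times in a second library of N2 tags
(assuming equal underlying rates) is

    p(x|y) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

This is the classical digital-expression exact test: y | x follows a
negative-binomial mass with r = x+1 and success probability
q = (N2/N1)/(1+N2/N1).  Tails C = Σ_{y'<=y} p(y'|x) and
D = Σ_{y'>=y} p(y'|x) are summed directly; the two-sided p-value is
2·min(C, D) capped at 1.

A miRNA is a DEM (differentially expressed miRNA) in a pairwise
comparison when |log2 fold change| >= 1 on mean TPM (pseudocount 0.01)
and the exact-test p on replicate-summed counts is < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

TPM_PSEUDOCOUNT = 0.01


@dataclass
class DEResult:
    mirna: str
    comparison: str
    log2fc: float
    p_value: float
    direction: str  # 'up' or 'down' in B relative to A
    significant: bool


def _check_counts(x: int, y: int, n1: int, n2: int) -> None:
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")


def ac_log_probability(x: int, y, n1: int, n2: int):
    """log p(x|y); y may be a numpy array."""
    y = np.asarray(y, dtype=float)
    ratio = np.log(n2) - np.log(n1)
    log1p_ratio = np.log1p(np.exp(ratio)) if ratio < 50 else ratio
    return (
        y * ratio
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * log1p_ratio
    )


def ac_probability(x: int, y: int, n1: int, n2: int) -> float:
    """p(x|y), computed in log space."""
    _check_counts(x, y, n1, n2)
    return float(np.exp(ac_log_probability(x, y, n1, n2)))


def ac_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided exact p-value: 2·min(lower tail, upper tail), capped at 1.

    Lower tail C = Σ_{y'<=y} p(y'|x) and upper tail D = Σ_{y'>=y} p(y'|x),
    both summed directly in log space (D is never formed as 1 − C, which
    would lose all precision deep in the upper tail).  Values within
    10^-12 of 1 are reported as exactly 1.

    Note the statistic conditions on x, so swapping (x, N1) with (y, N2)
    does not in general give the identical p-value.
    """
    _check_counts(x, y, n1, n2)
    logs_low = ac_log_probability(x, np.arange(0, y + 1), n1, n2)
    c = float(np.exp(logsumexp(logs_low)))
    # upper tail: sum far enough past the distribution bulk
    mean = (x + 1) * n2 / n1
    sd = np.sqrt(mean * (1.0 + n2 / n1))
    hi = int(max(y, mean) + 20 * sd + 100)
    logs_up = ac_log_probability(x, np.arange(y, hi + 1), n1, n2)
    d = float(np.exp(logsumexp(logs_up)))
    p = min(1.0, 2.0 * min(min(c, 1.0), min(d, 1.0)))
    return 1.0 if p > 1.0 - 1e-12 else p


def call_dems(
    tpm: pd.DataFrame,
    counts: pd.DataFrame,
    totals: dict[str, int],
    group_a: list[str],
    group_b: list[str],
    label: str,
    fold_change: float = 2.0,
    alpha: float = 0.05,
) -> list[DEResult]:
    """DEM calls for one pairwise comparison.

    Counts and totals are summed over the replicate libraries of each
    group before the two-library statistic; fold change is the ratio of
    mean TPMs with a 0.01-TPM pseudocount on both sides.
    """
    for lib in list(group_a) + list(group_b):
        if lib not in counts.columns:
            raise ValueError(f"unknown library {lib!r} in comparison {label}")
    if not group_a or not group_b:
        raise ValueError("each comparison group needs >= 1 library")
    lfc_min = np.log2(fold_change)
    n1 = sum(totals[l] for l in group_a)
    n2 = sum(totals[l] for l in group_b)
    xs = counts[group_a].sum(axis=1)
    ys = counts[group_b].sum(axis=1)
    mean_a = tpm[group_a].mean(axis=1)
    mean_b = tpm[group_b].mean(axis=1)
    results = []
    for mirna in counts.index:
        lfc = float(np.log2((mean_b[mirna] + TPM_PSEUDOCOUNT)
                            / (mean_a[mirna] + TPM_PSEUDOCOUNT)))
        p = ac_pvalue(int(xs[mirna]), int(ys[mirna]), n1, n2)
        results.append(DEResult(
            mirna=mirna,
            comparison=label,
            log2fc=lfc,
            p_value=p,
            direction="up" if lfc >= 0 else "down",
            significant=bool(abs(lfc) >= lfc_min and p < alpha),
        ))
    return results


def dem_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"mirna": r.mirna, "log2fc": r.log2fc, "pvalue": r.p_value,
             "direction": r.direction, "significant": r.significant}
            for r in results
        ]
    )
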