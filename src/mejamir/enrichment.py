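"""Hypergeometric pathway/GO-term enrichment of DEM target genes.

For a universe of N annotated genes of which n are DEM targets, and a
term annotating M genes of which m are DEM targets, the enrichment
p-value is the hypergeometric upper tail

    P = 1 − Σ_{i=0}^{m−1} C(M, i) C(N−M, n−i) / C(N, n)

computed with log-space binomial coefficients.  Q-values are
Benjamini–Hochberg over all tested terms.  Report cells render as
"m (percentage%)" with percentage = 100·m/n, round-half-even to two
decimals with trailing zeros trimmed — and a bare "0" when m = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests
import pandas as pd

from .sequence_io import AnnotationTable


@dataclass
class EnrichmentInput:
    N: int  # all annotated genes (universe)
    n: int  # DEM-target genes in the universe
    M: int  # genes annotated to the term
    m: int  # DEM-target genes annotated to the term

    def __post_init__(self) -> None:
        if not (0 <= self.m <= min(self.n, self.M) and self.M <= self.N
                and self.n <= self.N):
            raise ValueError(f"inconsistent enrichment counts {self}")
        if self.N == 0:
            raise ValueError("empty annotation universe (N = 0)")


@dataclass
class EnrichmentResult:
    term: str
    name: str
    namespace: str
    inp: EnrichmentInput
    P: float
    Q: float

    @property
    def rich_factor(self) -> float:
        return self.inp.m / self.inp.M

    @property
    def percentage(self) -> float:
        return round(100.0 * self.inp.m / self.inp.n, 2)


def _log_binom(a: int, b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_p(inp: EnrichmentInput) -> float:
    """Upper-tail P = P(X >= m) for X ~ Hypergeom(N, M, n).

    Summed as Σ_{i=m}^{min(n,M)} of the mass, which is numerically the
    stable side of the printed 1 − Σ_{i<m} form and identical in exact
    arithmetic."""
    N, n, M, m = inp.N, inp.n, inp.M, inp.m
    if m == 0:
        return 1.0
    i = np.arange(m, min(n, M) + 1)
    log_terms = _log_binom(M, i) + _log_binom(N - M, n - i) - _log_binom(N, n)
    return float(min(1.0, np.exp(log_terms).sum()))


def enrich(
    dem_targets: set[str],
    annotation: AnnotationTable,
    namespace: str = "pathway",
) -> tuple[list[EnrichmentResult], int]:
    """Enrichment of every term with m >= 1 among the DEM-target genes.

    The universe N is the annotated-gene universe; DEM targets lacking
    annotation are excluded from n (their count is returned for
    logging).  Q is Benjamini–Hochberg over the tested terms."""
    universe = annotation.genes
    if not universe:
        raise ValueError("annotation table is empty (N = 0)")
    in_universe = dem_targets & universe
    n_dropped = len(dem_targets) - len(in_universe)
    N, n = len(universe), len(in_universe)
    results: list[EnrichmentResult] = []
    for term, genes in sorted(annotation.term_genes().items()):
        m = len(genes & in_universe)
        if m < 1:
            continue
        inp = EnrichmentInput(N=N, n=n, M=len(genes), m=m)
        results.append(EnrichmentResult(
            term=term, name=annotation.term_names.get(term, term),
            namespace=namespace, inp=inp, P=hypergeom_p(inp), Q=1.0,
        ))
    if results:
        _, q, _, _ = multipletests([r.P for r in results], method="fdr_bh")
        for r, qv in zip(results, q):
            r.Q = float(qv)
    return results, n_dropped


def format_percentage(m: int, n: int) -> str:
    """Round-half-even to 2 decimals, trim trailing zeros ('5.6', '0.63')."""
    pct = round(100.0 * m / n, 2)
    s = f"{pct:.2f}".rstrip("0").rstrip(".")
    return s or "0"


def format_cell(m: int, n: int) -> str:
    """Table cell 'm (percentage%)'; zero renders as plain '0'."""
    if m == 0:
        return "0"
    return f"{m} ({format_percentage(m, n)}%)"


def report_table(
    results_per_comparison: dict[str, list[EnrichmentResult]],
    pathway_rows: list[str],
    n_per_comparison: dict[str, int],
) -> pd.DataFrame:
    """Selected-pathway × comparison matrix of 'm (percentage%)' cells."""
    table = {}
    for comp, results in results_per_comparison.items():
        n = n_per_comparison[comp]
        by_name = {r.name: r for r in results}
        col = {}
        for pathway in pathway_rows:
            r = by_name.get(pathway)
            col[pathway] = format_cell(r.inp.m if r else 0, n)
        table[comp] = col
    return pd.DataFrame(table).reindex(pathway_rows)


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"term": r.term, "name": r.name, "namespace": r.namespace,
         "N": r.inp.N, "n": r.inp.n, "M": r.inp.M, "m": r.inp.m,
         "P": r.P, "Q": r.Q, "rich_factor": r.rich_factor,
         "percentage": r.percentage}
        for r in results
    ])
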