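"""Expression integration and gene-set over-representation.

Covers four small statistical steps of the pipeline: summarising the
expression of a target-gene set against backgrounds (median and
quartiles, as drawn in box-and-whisker plots), the mean-equalisation
("average") normalisation used to put two array populations on a common
scale, hypergeometric gene-set enrichment against a user-supplied GMT
collection, and the 2^ΔcT fold-enrichment formula for ChIP-qPCR
validation.

The over-representation test is the standard one-sided hypergeometric
upper tail, P(X >= k) for X ~ Hypergeom(N, K, n) — i.e. Fisher's exact
test with the greater alternative. No multiple-testing correction is
applied by default; Benjamini-Hochberg is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionSummary",
    "EnrichmentResult",
    "summarize_expression",
    "sample_random_background",
    "mean_equalize",
    "hypergeometric_enrichment",
    "qpcr_fold_enrichment",
]


@dataclass(frozen=True)
class ExpressionSummary:
    """Median and quartiles of a gene set's expression intensities.

    ``n_missing`` counts query genes absent from the expression table
    (dropped before summarising). Quartiles use linear interpolation
    between order statistics.
    """

    n: int
    median: float
    q1: float
    q3: float
    n_missing: int = 0

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("expected q1 <= median <= q3")


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation of one gene set in the query.

    k of the n query genes fall in a set of size K within a background
    of N genes; ``p`` is the hypergeometric upper tail P(X >= k).
    """

    set_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adjusted: float | None = None

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def summarize_expression(
    gene_set: Iterable[str], expression_table: dict[str, float]
) -> ExpressionSummary:
    """Median/quartile summary of the expression of a gene set.

    Genes missing from the table are dropped and counted in
    ``n_missing``. Order of the input is irrelevant. An empty
    intersection raises ValueError.
    """
    genes = set(gene_set)
    values = [expression_table[g] for g in genes if g in expression_table]
    n_missing = len(genes) - len(values)
    if not values:
        raise ValueError("no gene of the set is present in the expression table")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return ExpressionSummary(
        n=len(values), median=float(med), q1=float(q1), q3=float(q3), n_missing=n_missing
    )


def sample_random_background(
    expression_table: dict[str, float], n: int = 3000, seed: int | None = None
) -> set[str]:
    """Draw n genes uniformly without replacement from the table.

    A random background of this kind is the usual comparison set for
    target-gene expression; the draw is reproducible given ``seed``.
    """
    genes = sorted(expression_table)
    if n > len(genes):
        raise ValueError(f"cannot draw {n} genes from a table of {len(genes)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(genes), size=n, replace=False)
    return {genes[i] for i in idx}


def mean_equalize(
    values_a: Sequence[float], values_b: Sequence[float]
) -> np.ndarray:
    """Scale population b so its mean equals population a's mean.

    Multiplicative scaling by mean(a)/mean(b); dimensionless shape
    statistics of b (e.g. its coefficient of variation) are unchanged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both populations must be non-empty")
    mean_b = b.mean()
    if mean_b == 0:
        raise ValueError("population b has zero mean; cannot scale")
    return b * (a.mean() / mean_b)


def hypergeometric_enrichment(
    query_genes: Iterable[str],
    gene_sets: Sequence[tuple[str, str, set[str]]],
    background: Iterable[str],
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Test each gene set for over-representation in the query.

    The query must be a subset of the background; each set is intersected
    with the background before testing. Results are sorted by ascending
    p (ties by set name). With ``bh_correct`` the Benjamini-Hochberg
    adjusted p-values are attached (raw p still reported).
    """
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    query = set(query_genes)
    if not query <= bg:
        missing = sorted(query - bg)[:5]
        raise ValueError(f"query genes not in background, e.g. {missing}")
    N, n = len(bg), len(query)
    results: list[EnrichmentResult] = []
    for set_name, _desc, members in gene_sets:
        members_bg = members & bg
        K = len(members_bg)
        k = len(query & members_bg)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        results.append(EnrichmentResult(set_name=set_name, k=k, K=K, n=n, N=N, p=p))
    results.sort(key=lambda r: (r.p, r.set_name))
    if bh_correct and results:
        _, p_adj, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        results = [
            EnrichmentResult(
                set_name=r.set_name, k=r.k, K=r.K, n=r.n, N=r.N, p=r.p,
                p_adjusted=float(q),
            )
            for r, q in zip(results, p_adj)
        ]
    return results


def qpcr_fold_enrichment(
    ct_input: float, ct_chip: float, input_fraction_adjust: float = 1.0
) -> float:
    """ChIP-qPCR fold enrichment: 2^(cT_input - cT_chip).

    ``input_fraction_adjust`` multiplies the fold to correct for the
    dilution of the input DNA relative to the ChIP sample (e.g. 100.0
    when the input is 1% of the chromatin).
    """
    if input_fraction_adjust <= 0:
        raise ValueError("input_fraction_adjust must be positive")
    return float(2.0 ** (ct_input - ct_chip) * input_fraction_adjust)
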