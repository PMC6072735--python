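"""Term over-representation: one-sided hypergeometric test with
Benjamini-Hochberg FDR control.

For a query list of n genes from a background of N, a term with K members
in the background and k members in the query gets the upper-tail p-value
P(X >= k), X ~ Hypergeometric(N, K, n).  Terms overlapping the query in
fewer than ``min_overlap`` genes are excluded before testing, and BH is
applied across the tested family (filter-then-adjust; the choice is echoed
in the result metadata).  Only over-representation is tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


class EnrichmentError(ValueError):
    pass


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float
    significant: bool


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), via the survival function
    (numerically stable; exact well past 10 significant digits for the
    population sizes used here)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise EnrichmentError(
            f"inconsistent hypergeometric parameters k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise EnrichmentError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def run_enrichment(
    query: Iterable[str],
    background: Iterable[str],
    terms: Mapping[str, tuple[str, Iterable[str]]],
    *,
    min_overlap: int = 4,
    p_cutoff: float = 0.01,
    q_report: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every term for over-representation of the query in the
    background.

    Symbols are upper-cased for matching and term membership is intersected
    with the background before sizing, so genes absent from the experiment
    never inflate a term.  Terms with overlap below ``min_overlap`` are
    dropped before testing; results with p < ``p_cutoff`` are returned
    sorted by (p, term_id) and flagged significant when q < ``q_report``.
    """
    qset = {g.strip().upper() for g in query}
    bset = {g.strip().upper() for g in background}
    if not qset:
        raise EnrichmentError("query gene set is empty")
    if not bset:
        raise EnrichmentError("background gene set is empty")
    if not qset <= bset:
        missing = sorted(qset - bset)[:5]
        raise EnrichmentError(f"query genes missing from background, e.g. {missing}")

    N = len(bset)
    n = len(qset)
    tested: list[tuple[str, str, int, int]] = []
    for term_id in sorted(terms):
        name, members = terms[term_id]
        mset = {g.strip().upper() for g in members} & bset
        k = len(mset & qset)
        if k < min_overlap:
            continue
        tested.append((term_id, name, k, len(mset)))
    if not tested:
        return []

    pvals = [hypergeom_upper_tail(k, K, n, N) for _, _, k, K in tested]
    qvals = bh_fdr(pvals)
    results = [
        EnrichmentResult(
            term_id=term_id,
            name=name,
            k=k,
            K=K,
            n=n,
            N=N,
            p=p,
            q=q,
            significant=q < q_report,
        )
        for (term_id, name, k, K), p, q in zip(tested, pvals, qvals)
        if p < p_cutoff
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results
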