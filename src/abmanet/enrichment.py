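"""Hypergeometric term-set enrichment with fold enrichment and FDR.

For a query gene set of size n inside a universe of size N, a term with K
universe members and k query members is scored by the upper-tail
hypergeometric probability P(X >= k) and the fold enrichment
(k/n) / (K/N).  The EASE variant decrements k by one before taking the
tail, which is conservative for small overlaps; the classical tail is the
default.  Benjamini-Hochberg q-values are computed across the tested
terms (terms with no query member are skipped).
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .abma import bh_fdr

__all__ = ["fold_enrichment", "hypergeom_tail", "enrich"]


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(query hit rate) / (universe hit rate) = (k/n) / (K/N)."""
    if min(n, K, N) <= 0:
        raise ValueError("n, K and N must be positive")
    if k < 0 or k > min(n, K):
        raise ValueError(f"k={k} must lie in [0, min(n={n}, K={K})]")
    return (k / n) / (K / N)


def hypergeom_tail(k: int, n: int, K: int, N: int, ease: bool = False) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n); EASE uses max(k-1, 0)."""
    s = max(k - 1, 0) if ease else k
    if s == 0:
        return 1.0
    return float(stats.hypergeom.sf(s - 1, N, K, n))


def enrich(
    query,
    terms: dict[str, list[str]],
    universe,
    ease: bool = False,
) -> pd.DataFrame:
    """Score every term against a query set; one row per term with k >= 1.

    Term memberships are intersected with the universe first; the query
    must be contained in the universe.  Columns: ``term_id k n K N fold p q``,
    ordered by ascending p then term id.
    """
    uni = set(universe)
    qry = set(query)
    stray = qry - uni
    if stray:
        raise ValueError(
            "query genes absent from universe: " + ", ".join(sorted(stray)[:10])
        )
    n, N = len(qry), len(uni)
    rows = []
    for term_id in sorted(terms):
        members = set(terms[term_id]) & uni
        K = len(members)
        k = len(members & qry)
        if k == 0:
            continue
        rows.append(
            {
                "term_id": term_id,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold": fold_enrichment(k, n, K, N),
                "p": hypergeom_tail(k, n, K, N, ease=ease),
            }
        )
    out = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "fold", "p"])
    if not out.empty:
        out["q"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values(["p", "term_id"]).reset_index(drop=True)
    else:
        out["q"] = []
    return out
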