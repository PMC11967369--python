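"""Cross-disease gene-set comparison: Venn partitions, Fisher tests, odds ratios.

Two per-disease gene sets are compared against a fixed gene universe
(default: the 19,924-gene whole-genome screen).  The 2x2 contingency table
counts genes in both sets (a), each set alone (b, c), and the universe
remainder (d); overlap enrichment is the one-sided (greater) Fisher exact
tail and effect size is the cross-product odds ratio ad/bc, optionally
Haldane-Anscombe corrected so zero cells never yield infinity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_UNIVERSE_SIZE",
    "ContingencyTable",
    "venn_partition",
    "contingency",
    "fisher_enrichment",
    "odds_ratio",
    "compare_all",
]

DEFAULT_UNIVERSE_SIZE = 19_924


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 overlap table against a universe: a+b+c+d = universe size."""

    a: int  # in both sets
    b: int  # source only
    c: int  # target only
    d: int  # universe remainder

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


def venn_partition(set_a, set_b) -> tuple[int, int, int]:
    """Disjoint partition sizes (a_only, b_only, both) of two gene sets."""
    sa, sb = set(set_a), set(set_b)
    both = len(sa & sb)
    return len(sa) - both, len(sb) - both, both


def contingency(set_a, set_b, universe_size: int = DEFAULT_UNIVERSE_SIZE) -> ContingencyTable:
    sa, sb = set(set_a), set(set_b)
    union = len(sa | sb)
    if union > universe_size:
        raise ValueError(
            f"set union ({union}) exceeds universe size ({universe_size})"
        )
    a_only, b_only, both = venn_partition(sa, sb)
    return ContingencyTable(both, a_only, b_only, universe_size - union)


def fisher_enrichment(table: ContingencyTable, alternative: str = "greater") -> float:
    """Fisher exact tail probability of the overlap with margins fixed.

    One-sided ``greater`` by default: the probability of an overlap at
    least as large as observed under independent draws from the universe.
    """
    p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative=alternative
    ).pvalue
    return min(float(p), 1.0)


def odds_ratio(table: ContingencyTable, haldane: bool = False) -> float:
    """Cross-product odds ratio ad/bc; Haldane-Anscombe +0.5 on zero cells."""
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if haldane and min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0.0:
        # undefined without the correction; never return infinity
        return float("nan")
    return (a * d) / (b * c)


def compare_all(
    gene_sets: dict[str, list[str]],
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
    haldane: bool = True,
) -> pd.DataFrame:
    """Pairwise overlap statistics for every unordered disease pair.

    ``gene_sets`` maps disease id to its gene list.  Rows follow the
    insertion order of the mapping, one per pair, with columns
    ``source, target, n_source, n_target, overlap, odds_ratio, p_value``.
    """
    if len(gene_sets) < 2:
        raise ValueError("need at least two gene sets to compare")
    rows = []
    for src, tgt in combinations(gene_sets, 2):
        table = contingency(gene_sets[src], gene_sets[tgt], universe_size)
        rows.append(
            {
                "source": src,
                "target": tgt,
                "n_source": table.a + table.b,
                "n_target": table.a + table.c,
                "overlap": table.a,
                "odds_ratio": odds_ratio(table, haldane=haldane),
                "p_value": fisher_enrichment(table),
            }
        )
    return pd.DataFrame(rows)
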