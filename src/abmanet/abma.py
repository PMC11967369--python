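"""Adjusted binomial scoring of gene-disease literature evidence.

Each gene-disease pair carries three report counts: ``n_pos`` studies
reporting a positive association, ``n_neg`` reporting a negative one, and
``n_incon`` whose direction is inconclusive.  The adjusted binomial method
asks whether the *dominant* direction (the more frequent of positive vs
negative) is reported more often than a null proportion ``p0`` would
predict, after inflating the sample by a factor ``alpha`` of hypothesised
uncovered studies that the literature search missed.

Two limiting hypotheses about the uncovered studies give two tests:

* Case 1 — uncovered studies mirror the observed ones.  The total and the
  dominant count are both scaled by ``(1 + alpha)``; with equal counts of
  the three report types the dominant proportion approaches 1/3 from above,
  so the null proportion is the smallest two-decimal value above that bound
  (0.34 for any alpha).
* Case 2 — uncovered studies are all null.  The total is scaled by
  ``(1 + alpha)`` but the dominant count is not; the equal-count bound is
  ``1 / (3 * (1 + alpha))``, i.e. 0.17 at the default ``alpha = 1``.

The upper-tail binomial probability P(X >= s) for X ~ Binomial(N, p0) is
the per-case p-value; the two cases are combined (conservatively, by their
maximum) and Benjamini-Hochberg adjusted per disease.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AbmaParams",
    "dominant_direction",
    "case_null_proportion",
    "abma_pvalue",
    "combine_cases",
    "bh_fdr",
    "score_table",
    "significant_genes",
]

_CASE_RULES = ("case1", "case2", "max")


@dataclass(frozen=True)
class AbmaParams:
    """Parameters of the adjusted binomial test.

    alpha
        Uncovered-sample fraction: the assumed ratio of studies missed by
        the literature search to studies found.  The default 1 treats the
        search as covering half the relevant literature.
    p0_case1, p0_case2
        Null proportions for the two uncovered-sample hypotheses.  The
        defaults are the equal-count lower bounds derived by
        :func:`case_null_proportion` at ``alpha = 1``.
    case_rule
        How the two per-case p-values combine into the final one:
        ``"case1"``, ``"case2"``, or the conservative ``"max"``.
    q_threshold
        Benjamini-Hochberg FDR level below which a pair is called
        significant.
    """

    alpha: float = 1.0
    p0_case1: float = 0.34
    p0_case2: float = 0.17
    case_rule: str = "max"
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        for name in ("p0_case1", "p0_case2"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.case_rule not in _CASE_RULES:
            raise ValueError(
                f"case_rule must be one of {_CASE_RULES}, got {self.case_rule!r}"
            )
        if not 0.0 < self.q_threshold < 1.0:
            raise ValueError(f"q_threshold must lie in (0, 1), got {self.q_threshold}")


def _check_counts(n_pos: int, n_neg: int, n_incon: int) -> None:
    for name, v in (("n_pos", n_pos), ("n_neg", n_neg), ("n_incon", n_incon)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")


def dominant_direction(n_pos: int, n_neg: int, n_incon: int = 0) -> tuple[str, int]:
    """Return the dominant report direction and its count.

    ``positive`` if positive reports outnumber negative ones, ``negative``
    for the converse, ``tie`` when both are equal and nonzero, and ``none``
    when no directional report exists.  Inconclusive reports never count
    toward the dominant finding.
    """
    _check_counts(n_pos, n_neg, n_incon)
    if n_pos > n_neg:
        return "positive", n_pos
    if n_neg > n_pos:
        return "negative", n_neg
    if n_pos > 0:
        return "tie", n_pos
    return "none", 0


def case_null_proportion(case: int, alpha: float = 1.0) -> float:
    """Derive the null proportion ``p0`` for a case from the adjustment algebra.

    With equal counts ``n_pos = n_neg = n_incon = c`` the adjusted dominant
    proportion reaches its lower bound; any dominant direction must exceed
    it.  Case 1 scales both total and dominant count by ``(1 + alpha)``, so
    the bound is 1/3 independent of alpha and, being open, ``p0`` is the
    smallest value on a 0.01 grid strictly above it.  Case 2 leaves the
    dominant count unscaled, giving the bound ``1 / (3 * (1 + alpha))``,
    reported rounded to two decimals.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if case == 1:
        bound = (1.0 + alpha) / (3.0 * (1.0 + alpha))
        # Open bound: step up to the first 0.01-grid point strictly above it.
        return (math.floor(bound * 100.0) + 1) / 100.0
    if case == 2:
        bound = 1.0 / (3.0 * (1.0 + alpha))
        return round(bound, 2)
    raise ValueError(f"case must be 1 or 2, got {case}")


def _adjusted(n_dom: int, n_raw: int, alpha: float, case: int) -> tuple[int, int]:
    """Adjusted (successes, trials) for one case; totals rounded to integers."""
    n_adj = int(round((1.0 + alpha) * n_raw))
    if case == 1:
        s = int(round((1.0 + alpha) * n_dom))
    elif case == 2:
        s = n_dom
    else:
        raise ValueError(f"case must be 1 or 2, got {case}")
    return s, n_adj


def abma_pvalue(
    n_pos: int,
    n_neg: int,
    n_incon: int,
    params: AbmaParams = AbmaParams(),
    case: int = 1,
) -> float:
    """Upper-tail adjusted binomial p-value for one gene-disease pair.

    Computes P(X >= s) for X ~ Binomial(N, p0) with N the alpha-inflated
    total report count and s the (case-dependently adjusted) dominant
    count.  A tied pair has no dominant finding to test and returns 1.0;
    a pair with no reports at all is not testable and raises.
    """
    _check_counts(n_pos, n_neg, n_incon)
    n_raw = n_pos + n_neg + n_incon
    if n_raw == 0:
        raise ValueError("pair has no reports (n_raw = 0); not testable")
    direction, n_dom = dominant_direction(n_pos, n_neg, n_incon)
    if direction in ("tie", "none"):
        return 1.0
    s, n_adj = _adjusted(n_dom, n_raw, params.alpha, case)
    p0 = params.p0_case1 if case == 1 else params.p0_case2
    return float(stats.binom.sf(s - 1, n_adj, p0))


def combine_cases(p1: float, p2: float, rule: str = "max") -> float:
    """Combine the two per-case p-values according to ``rule``."""
    if rule == "case1":
        return p1
    if rule == "case2":
        return p2
    if rule == "max":
        return max(p1, p2)
    raise ValueError(f"case_rule must be one of {_CASE_RULES}, got {rule!r}")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _score_arrays(
    n_pos: np.ndarray, n_neg: np.ndarray, n_incon: np.ndarray, params: AbmaParams
) -> dict[str, np.ndarray]:
    """Vectorised per-pair scoring (no FDR); all inputs non-negative ints."""
    n_raw = n_pos + n_neg + n_incon
    if np.any(n_raw == 0):
        raise ValueError("all pairs must have n_raw >= 1")
    n_dom = np.maximum(n_pos, n_neg)
    direction = np.where(
        n_pos > n_neg,
        "positive",
        np.where(n_neg > n_pos, "negative", np.where(n_pos > 0, "tie", "none")),
    )
    tested = (n_pos != n_neg)
    n_adj = np.rint((1.0 + params.alpha) * n_raw).astype(np.int64)
    s1 = np.rint((1.0 + params.alpha) * n_dom).astype(np.int64)
    s2 = n_dom.astype(np.int64)
    p1 = np.ones_like(n_raw, dtype=float)
    p2 = np.ones_like(n_raw, dtype=float)
    p1[tested] = stats.binom.sf(s1[tested] - 1, n_adj[tested], params.p0_case1)
    p2[tested] = stats.binom.sf(s2[tested] - 1, n_adj[tested], params.p0_case2)
    if params.case_rule == "case1":
        p_final = p1
    elif params.case_rule == "case2":
        p_final = p2
    else:
        p_final = np.maximum(p1, p2)
    # observed dominant proportion under the Case-1 adjustment
    obs = s1 / n_adj
    return {
        "direction": direction,
        "n_raw": n_raw,
        "N_adj": n_adj,
        "n_dom_adj": s1,
        "obs_proportion": obs,
        "p_case1": p1,
        "p_case2": p2,
        "p_final": p_final,
    }


RESULT_COLUMNS = [
    "gene_id",
    "disease_id",
    "direction",
    "n_pos",
    "n_neg",
    "n_incon",
    "N_adj",
    "obs_proportion",
    "p_case1",
    "p_case2",
    "p_final",
    "q",
    "significant",
]


def score_table(evidence: pd.DataFrame, params: AbmaParams = AbmaParams()) -> pd.DataFrame:
    """Score an evidence table into per-pair adjusted binomial results.

    ``evidence`` needs columns ``gene_id, disease_id, n_pos, n_neg,
    n_incon``.  Pairs without any report are dropped before testing so the
    FDR family holds only pairs that actually carry evidence; the
    correction is applied separately within each disease.  Duplicate
    (gene, disease) rows are rejected.
    """
    required = {"gene_id", "disease_id", "n_pos", "n_neg", "n_incon"}
    missing = required - set(evidence.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    dup = evidence.duplicated(subset=["gene_id", "disease_id"], keep=False)
    if dup.any():
        offenders = (
            evidence.loc[dup, ["gene_id", "disease_id"]]
            .drop_duplicates()
            .itertuples(index=False)
        )
        raise ValueError(
            "duplicate (gene, disease) rows: "
            + ", ".join(f"({g}, {d})" for g, d in offenders)
        )
    counts = evidence[["n_pos", "n_neg", "n_incon"]].to_numpy()
    if np.any(counts < 0):
        raise ValueError("evidence counts must be non-negative")
    covered = evidence.loc[counts.sum(axis=1) >= 1].reset_index(drop=True)
    if covered.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)

    scored = _score_arrays(
        covered["n_pos"].to_numpy(np.int64),
        covered["n_neg"].to_numpy(np.int64),
        covered["n_incon"].to_numpy(np.int64),
        params,
    )
    out = covered[["gene_id", "disease_id", "n_pos", "n_neg", "n_incon"]].copy()
    for col in ("direction", "N_adj", "obs_proportion", "p_case1", "p_case2", "p_final"):
        out[col] = scored[col]
    out["q"] = np.nan
    for _, idx in out.groupby("disease_id", sort=False).groups.items():
        out.loc[idx, "q"] = bh_fdr(out.loc[idx, "p_final"].to_numpy())
    out["significant"] = (out["q"] <= params.q_threshold) & out["direction"].isin(
        ["positive", "negative"]
    )
    return out[RESULT_COLUMNS].sort_values(["disease_id", "gene_id"]).reset_index(drop=True)


def significant_genes(results: pd.DataFrame, disease_id: str) -> list[str]:
    """Lexicographically sorted significant genes for one disease."""
    if results.empty:
        raise ValueError(f"unknown disease_id: {disease_id!r}")
    if disease_id not in set(results["disease_id"]):
        raise ValueError(f"unknown disease_id: {disease_id!r}")
    mask = (results["disease_id"] == disease_id) & results["significant"]
    return sorted(set(results.loc[mask, "gene_id"]))
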