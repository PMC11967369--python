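"""Unit and property tests for the adjusted binomial scoring core."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abmanet import (
    AbmaParams,
    abma_pvalue,
    bh_fdr,
    case_null_proportion,
    combine_cases,
    dominant_direction,
    score_table,
    significant_genes,
)


def binom_tail_oracle(s: int, n: int, p: float) -> float:
    """Brute-force pmf summation of P(X >= s) for X ~ Binomial(n, p)."""
    return sum(
        math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(s, n + 1)
    )


def bh_oracle(pvals):
    """Naive quadratic Benjamini-Hochberg step-up."""
    m = len(pvals)
    q = []
    for i, p in enumerate(pvals):
        # rank of p among all values (1-based, ties share the higher rank set)
        candidates = []
        order = sorted(range(m), key=lambda j: pvals[j])
        ranks = {j: r + 1 for r, j in enumerate(order)}
        for j in range(m):
            if pvals[j] >= p or j == i:
                candidates.append(m * pvals[j] / ranks[j])
        q.append(min(1.0, min(candidates)))
    return q


@pytest.mark.parametrize(
    "counts, expected",
    [
        ((5, 1, 1), ("positive", 5)),
        ((1, 4, 0), ("negative", 4)),
        ((3, 3, 0), ("tie", 3)),
        ((0, 0, 4), ("none", 0)),
        ((0, 0, 0), ("none", 0)),
    ],
)
def test_dominant_direction(counts, expected):
    assert dominant_direction(*counts) == expected


def test_dominant_direction_rejects_negative_counts():
    with pytest.raises(ValueError, match="non-negative"):
        dominant_direction(-1, 0, 0)


class TestCaseNullProportions:
    """The p0 constants follow from the equal-count limiting proportion."""

    def test_case1_bound_is_034(self):
        assert case_null_proportion(1) == 0.34

    def test_case2_bound_is_017(self):
        assert case_null_proportion(2) == 0.17

    def test_case1_bound_independent_of_alpha(self):
        for alpha in (0.0, 0.5, 1.0, 2.0):
            assert case_null_proportion(1, alpha=alpha) == 0.34

    def test_case2_bound_tracks_alpha(self):
        # no uncovered inflation: bound is 1/3, rounded
        assert case_null_proportion(2, alpha=0.0) == 0.33

    def test_invalid_case(self):
        with pytest.raises(ValueError):
            case_null_proportion(3)


class TestAbmaPvalue:
    def test_case1_matches_pmf_summation(self):
        # np=5, nn=1, n0=1: N = 14, dominant doubled to 10
        expected = binom_tail_oracle(10, 14, 0.34)
        assert abma_pvalue(5, 1, 1, case=1) == pytest.approx(expected, rel=1e-12)

    def test_case2_matches_pmf_summation(self):
        expected = binom_tail_oracle(5, 14, 0.17)
        assert abma_pvalue(5, 1, 1, case=2) == pytest.approx(expected, rel=1e-12)

    def test_single_report_closed_form(self):
        # one positive report: N=2, s=1, P(X>=1) = 1 - 0.83^2
        assert abma_pvalue(1, 0, 0, case=2) == pytest.approx(1 - 0.83**2, rel=1e-12)

    def test_tie_returns_one(self):
        assert abma_pvalue(3, 3, 2, case=1) == 1.0

    def test_no_reports_raises(self):
        with pytest.raises(ValueError, match="not testable"):
            abma_pvalue(0, 0, 0, case=1)

    def test_oracle_equivalence_small_grid(self):
        """Both cases match brute-force summation over all triples n_raw <= 20."""
        params = AbmaParams()
        for n_raw in range(1, 21):
            for n_pos in range(n_raw + 1):
                for n_neg in range(n_raw - n_pos + 1):
                    n_incon = n_raw - n_pos - n_neg
                    if n_pos == n_neg:
                        continue
                    n_dom = max(n_pos, n_neg)
                    p1 = abma_pvalue(n_pos, n_neg, n_incon, params, case=1)
                    p2 = abma_pvalue(n_pos, n_neg, n_incon, params, case=2)
                    assert p1 == pytest.approx(
                        binom_tail_oracle(2 * n_dom, 2 * n_raw, 0.34), rel=1e-10
                    )
                    assert p2 == pytest.approx(
                        binom_tail_oracle(n_dom, 2 * n_raw, 0.17), rel=1e-10
                    )

    @settings(max_examples=100, derandomize=True)
    @given(
        n_neg=st.integers(0, 10),
        n_incon=st.integers(0, 10),
        n_pos=st.integers(1, 40),
        case=st.sampled_from([1, 2]),
    )
    def test_monotone_in_dominant_count(self, n_neg, n_incon, n_pos, case):
        """More dominant-direction reports never weaken the evidence."""
        n_pos = n_pos + n_neg  # ensure positive direction
        p_lo = abma_pvalue(n_pos, n_neg, n_incon, case=case)
        p_hi = abma_pvalue(n_pos + 1, n_neg, n_incon, case=case)
        assert p_hi <= p_lo + 1e-15


@pytest.mark.parametrize(
    "p1, p2, rule, expected",
    [(0.01, 0.04, "max", 0.04), (0.01, 0.04, "case1", 0.01),
     (0.01, 0.04, "case2", 0.04), (0.3, 0.3, "max", 0.3)],
)
def test_combine_cases(p1, p2, rule, expected):
    assert combine_cases(p1, p2, rule) == expected


def test_combine_cases_invalid_rule():
    with pytest.raises(ValueError):
        combine_cases(0.1, 0.2, "mean")


class TestBhFdr:
    def test_uniform_spacing_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_identity(self):
        assert bh_fdr([0.5]) == pytest.approx([0.5])

    def test_empty(self):
        assert len(bh_fdr([])) == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            p = rng.random(rng.integers(1, 30)).tolist()
            assert bh_fdr(p) == pytest.approx(bh_oracle(p), rel=1e-12)

    def test_monotone_when_sorted(self):
        rng = np.random.default_rng(7)
        p = np.sort(rng.random(100))
        q = bh_fdr(p)
        assert np.all(np.diff(q) >= -1e-15)


class TestScoreTable:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "disease_id", "n_pos", "n_neg", "n_incon"]
        )

    def test_strong_gene_among_nulls_is_significant(self):
        rows = [(f"G{i:03d}", "D1", 1, 1, 0) for i in range(100)]
        rows.append(("G100", "D1", 50, 0, 0))
        res = score_table(self._table(rows))
        hit = res.loc[res.gene_id == "G100"].iloc[0]
        assert hit.significant and hit.q <= 0.05 and hit.direction == "positive"
        assert significant_genes(res, "D1") == ["G100"]

    def test_empty_table(self):
        assert score_table(self._table([])).empty

    def test_all_zero_counts_excluded(self):
        res = score_table(self._table([("G1", "D1", 0, 0, 0)]))
        assert res.empty

    def test_duplicate_pairs_rejected_with_offenders(self):
        t = self._table([("G1", "D1", 1, 0, 0), ("G1", "D1", 2, 0, 0)])
        with pytest.raises(ValueError, match=r"\(G1, D1\)"):
            score_table(t)

    def test_fdr_applied_per_disease(self):
        # identical counts in two diseases of different family sizes get
        # different q-values
        rows = [("G0", "D1", 6, 0, 0)]
        rows += [(f"G{i}", "D2", 6, 0, 0) for i in range(20)]
        rows += [(f"H{i}", "D2", 1, 1, 0) for i in range(20)]
        res = score_table(self._table(rows))
        q_d1 = res.loc[res.disease_id == "D1", "q"].iloc[0]
        q_d2 = res.loc[(res.disease_id == "D2") & (res.gene_id == "G0"), "q"].iloc[0]
        assert q_d1 != q_d2

    def test_tie_never_significant(self):
        res = score_table(self._table([("G1", "D1", 7, 7, 0)]))
        assert res.iloc[0].direction == "tie"
        assert res.iloc[0].p_final == 1.0
        assert not res.iloc[0].significant

    def test_planted_recall(self):
        """Recall of planted genes on the standard planted-truth fixture."""
        from abmanet.simulate import SimConfig, generate_evidence_table

        cfg = SimConfig(
            n_genes=2000, diseases=("D1",), planted_fraction=0.1,
            coverage_fraction=0.5, lambda_signal=20, lambda_noise=1,
            seed=20250320,
        )
        ev, truth = generate_evidence_table(cfg)
        res = score_table(ev)
        called = set(significant_genes(res, "D1"))
        planted = set(truth.loc[truth.associated, "gene_id"])
        recall = len(called & planted) / len(planted)
        assert recall >= 0.9

    def test_unknown_disease_rejected(self):
        res = score_table(self._table([("G1", "D1", 5, 0, 0)]))
        with pytest.raises(ValueError, match="unknown disease"):
            significant_genes(res, "D9")
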