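"""Seed-reproducible synthetic literature corpora with known ground truth.

The generator emulates the shape of a mined literature corpus: for every
gene-disease pair, counts of positive / negative / inconclusive reports.
Most pairs have no literature at all; covered null pairs draw small
symmetric Poisson counts; a planted fraction of truly associated pairs
draws a large count in its true direction.  Alongside the evidence table a
truth table records which pairs were planted and with which polarity, so
recall and calibration of every downstream stage can be measured.

A companion sampler produces weighted directed interaction edge lists
(edge weights playing the role of supporting-reference counts) and random
term sets in GMT form, so the whole pipeline runs without any download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "generate_evidence_table",
    "generate_ppi_edges",
    "generate_term_sets",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the synthetic corpus.

    n_genes
        Size of the gene universe (default: the 19,924-gene whole-genome
        screen the corpus emulates).
    diseases
        Disease identifiers; one evidence column block per disease.
    planted_fraction
        Fraction of genes per disease that are truly associated.
    shared_planted_fraction
        Fraction of genes planted jointly in *every* disease (subset of
        ``planted_fraction``); controls cross-disease overlap structure.
    coverage_fraction
        Fraction of gene-disease pairs with any literature at all.  Planted
        pairs are always covered (an association with no reports would be
        undetectable by construction), so it must be >= planted_fraction.
    lambda_signal, lambda_noise, lambda_incon
        Poisson means for, respectively, the dominant-direction count of a
        planted pair, the directional counts of null pairs (and the
        minority direction of planted pairs), and inconclusive counts.
    positive_polarity_prob
        Probability that a planted association is positive-direction.
    ppi_edge_prob, weight_lambda
        Directed-edge density and mean extra weight (weights are
        ``1 + Poisson(weight_lambda)`` supporting references).
    n_terms, term_size_range
        Number of random term sets and the inclusive size range.
    seed
        RNG seed; identical configs give byte-identical outputs.
    """

    n_genes: int = 19_924
    diseases: tuple[str, ...] = ("AD", "ADHD", "HNC")
    planted_fraction: float = 0.02
    shared_planted_fraction: float = 0.0
    coverage_fraction: float = 0.25
    lambda_signal: float = 5.0
    lambda_noise: float = 0.8
    lambda_incon: float = 0.5
    positive_polarity_prob: float = 0.8
    ppi_edge_prob: float = 0.4
    weight_lambda: float = 2.5
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 100)
    seed: int = 20_250_320

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError(f"n_genes must be positive, got {self.n_genes}")
        if len(self.diseases) == 0:
            raise ValueError("diseases must be non-empty")
        if len(set(self.diseases)) != len(self.diseases):
            raise ValueError("disease identifiers must be unique")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must lie in [0, 1]")
        if not 0.0 <= self.shared_planted_fraction <= self.planted_fraction:
            raise ValueError(
                "shared_planted_fraction must lie in [0, planted_fraction]"
            )
        if not 0.0 < self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must lie in (0, 1]")
        if self.coverage_fraction < self.planted_fraction:
            raise ValueError(
                "coverage_fraction must be >= planted_fraction "
                "(planted pairs always carry literature)"
            )
        for name in ("lambda_signal", "lambda_noise", "lambda_incon", "weight_lambda"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.positive_polarity_prob <= 1.0:
            raise ValueError("positive_polarity_prob must lie in [0, 1]")
        if not 0.0 <= self.ppi_edge_prob <= 1.0:
            raise ValueError("ppi_edge_prob must lie in [0, 1]")
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ValueError(
                f"term_size_range must satisfy 1 <= lo <= hi <= n_genes, "
                f"got {self.term_size_range}"
            )
        if self.n_terms < 0:
            raise ValueError("n_terms must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]


def _nonzero_poisson_triplets(
    rng: np.random.Generator, n: int, lams: tuple[float, float, float]
) -> np.ndarray:
    """Draw (k1, k2, k3) Poisson triplets conditioned on a nonzero sum.

    Covered pairs have, by definition, at least one report; all-zero draws
    are resampled, truncating the joint distribution at zero.
    """
    out = np.column_stack([rng.poisson(lam, size=n) for lam in lams]).astype(np.int64)
    while True:
        zero = out.sum(axis=1) == 0
        n_zero = int(zero.sum())
        if n_zero == 0:
            return out
        out[zero] = np.column_stack(
            [rng.poisson(lam, size=n_zero) for lam in lams]
        )


def generate_evidence_table(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one evidence table and its ground-truth table.

    Returns ``(evidence, truth)``.  ``evidence`` has one row per
    gene-disease pair with columns ``gene_id, disease_id, n_pos, n_neg,
    n_incon`` (uncovered pairs are all-zero rows).  ``truth`` mirrors the
    pairs with ``associated`` flags and the true ``polarity`` of planted
    pairs (``.`` for nulls).
    """
    rng = np.random.default_rng(config.seed)
    genes = np.array(config.gene_ids)
    n_genes = config.n_genes
    diseases = list(config.diseases)
    n_dis = len(diseases)

    n_planted = int(round(config.planted_fraction * n_genes))
    n_shared = int(round(config.shared_planted_fraction * n_genes))
    shared_idx = rng.choice(n_genes, size=n_shared, replace=False)

    planted = np.zeros((n_genes, n_dis), dtype=bool)
    polarity_pos = np.zeros((n_genes, n_dis), dtype=bool)
    for j in range(n_dis):
        planted[shared_idx, j] = True
        extra = n_planted - n_shared
        if extra > 0:
            pool = np.setdiff1d(np.arange(n_genes), shared_idx, assume_unique=False)
            planted[rng.choice(pool, size=extra, replace=False), j] = True
        polarity_pos[:, j] = rng.random(n_genes) < config.positive_polarity_prob

    # coverage: planted pairs first, then random null pairs up to the target
    n_pairs = n_genes * n_dis
    target_covered = int(round(config.coverage_fraction * n_pairs))
    covered = planted.copy()
    deficit = target_covered - int(covered.sum())
    if deficit > 0:
        null_flat = np.flatnonzero(~covered.ravel())
        fill = rng.choice(null_flat, size=min(deficit, null_flat.size), replace=False)
        covered.ravel()[fill] = True

    n_pos = np.zeros((n_genes, n_dis), dtype=np.int64)
    n_neg = np.zeros((n_genes, n_dis), dtype=np.int64)
    n_incon = np.zeros((n_genes, n_dis), dtype=np.int64)

    null_cov = covered & ~planted
    k = int(null_cov.sum())
    trip = _nonzero_poisson_triplets(
        rng, k, (config.lambda_noise, config.lambda_noise, config.lambda_incon)
    )
    n_pos[null_cov], n_neg[null_cov], n_incon[null_cov] = trip[:, 0], trip[:, 1], trip[:, 2]

    k = int(planted.sum())
    trip = _nonzero_poisson_triplets(
        rng, k, (config.lambda_signal, config.lambda_noise, config.lambda_incon)
    )
    pos_pol = polarity_pos[planted]
    n_pos[planted] = np.where(pos_pol, trip[:, 0], trip[:, 1])
    n_neg[planted] = np.where(pos_pol, trip[:, 1], trip[:, 0])
    n_incon[planted] = trip[:, 2]

    gene_col = np.repeat(genes, n_dis)
    dis_col = np.tile(np.array(diseases), n_genes)
    evidence = pd.DataFrame(
        {
            "gene_id": gene_col,
            "disease_id": dis_col,
            "n_pos": n_pos.ravel(),
            "n_neg": n_neg.ravel(),
            "n_incon": n_incon.ravel(),
        }
    )
    polarity = np.where(
        planted, np.where(polarity_pos, "positive", "negative"), "."
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_col,
            "disease_id": dis_col,
            "associated": planted.ravel(),
            "polarity": polarity.ravel(),
        }
    )
    return evidence, truth


def generate_ppi_edges(genes, config: SimConfig) -> pd.DataFrame:
    """Sample a weighted signed directed edge list over ``genes``.

    Each ordered pair (no self-loops) carries an edge independently with
    probability ``ppi_edge_prob``; weights are ``1 + Poisson(weight_lambda)``
    supporting-reference counts and signs are drawn uniformly from
    ``{+, -, ?}``.
    """
    genes = list(genes)
    if len(genes) == 0:
        raise ValueError("gene list must be non-empty")
    rng = np.random.default_rng(config.seed + 1)
    n = len(genes)
    mask = rng.random((n, n)) < config.ppi_edge_prob
    np.fill_diagonal(mask, False)
    src_i, tgt_i = np.nonzero(mask)
    weights = 1 + rng.poisson(config.weight_lambda, size=src_i.size)
    signs = rng.choice(np.array(["+", "-", "?"]), size=src_i.size)
    garr = np.array(genes)
    return pd.DataFrame(
        {
            "source": garr[src_i],
            "target": garr[tgt_i],
            "weight": weights,
            "sign": signs,
        }
    )


def generate_term_sets(genes, config: SimConfig) -> dict[str, list[str]]:
    """Sample ``n_terms`` random gene sets (GMT-serialisable).

    Term sizes are uniform over ``term_size_range`` and members are drawn
    without replacement from ``genes``.
    """
    genes = list(genes)
    lo, hi = config.term_size_range
    if hi > len(genes):
        raise ValueError(
            f"term size upper bound {hi} exceeds gene count {len(genes)}"
        )
    rng = np.random.default_rng(config.seed + 2)
    garr = np.array(genes)
    width = max(1, len(str(max(config.n_terms - 1, 0))))
    terms: dict[str, list[str]] = {}
    for t in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = garr[rng.choice(len(garr), size=size, replace=False)]
        terms[f"TERM{t:0{width}d}"] = sorted(members.tolist())
    return terms
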