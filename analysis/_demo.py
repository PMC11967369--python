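"""Shared demo-study conditions for the numbered analysis scripts.

A 2,000-gene, three-disease synthetic corpus with strong planted signal
(dominant-direction reports at Poisson mean 20 vs background 1), a 5%
cross-disease shared planted structure, and 40% literature coverage.
Every script reads from / writes under results/.
"""

from pathlib import Path

from abmanet.simulate import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
CORPUS = RESULTS / "corpus"

DEMO = SimConfig(
    n_genes=2000,
    diseases=("AD", "ADHD", "HNC"),
    planted_fraction=0.1,
    shared_planted_fraction=0.05,
    coverage_fraction=0.4,
    lambda_signal=20,
    lambda_noise=1,
    ppi_edge_prob=0.05,
    n_terms=40,
    term_size_range=(10, 60),
    seed=20_250_320,
)
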