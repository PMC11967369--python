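"""Assemble the signed disease-gene-disease pathway graph.

Significant associations become polarity edges (orientation assigned
reproducibly from the run seed, standing in for the literature-derived
orientation); intermediary genes between each ordered disease pair are
listed with their composed sign.  Writes results/pathway/.
"""

from itertools import permutations

import numpy as np
from _demo import DEMO, RESULTS

from abmanet import io
from abmanet.pathway import build_pathway, intermediary_genes, to_dot, to_edge_table


def main() -> None:
    results = io.read_tsv(RESULTS / "associations.tsv")
    rng = np.random.default_rng(DEMO.seed + 3)
    sig = results.loc[results["significant"]]
    direction_map = {
        (r.gene_id, r.disease_id): ("disease->gene" if rng.random() < 0.5
                                    else "gene->disease")
        for r in sig.itertuples(index=False)
    }
    graph = build_pathway(results, direction_map, diseases=DEMO.diseases)
    outdir = RESULTS / "pathway"
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_tsv(to_edge_table(graph), outdir / "edges.tsv")
    (outdir / "pathway.dot").write_text(to_dot(graph))
    print(f"pathway graph: {graph.number_of_edges()} signed edges")
    for a, b in permutations(DEMO.diseases, 2):
        inter = intermediary_genes(graph, a, b)
        if inter:
            head = ", ".join(f"{g}({s[0]})" for g, s in inter[:5])
            print(f"  {a} -> {b}: {len(inter)} intermediary genes, e.g. {head}")
    print(f"wrote edge table and DOT export to {outdir}")


if __name__ == "__main__":
    main()
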