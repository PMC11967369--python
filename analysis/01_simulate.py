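"""Generate the demo literature corpus with known ground truth.

Writes the evidence table, truth table, PPI edge list and term sets under
results/corpus/ and prints what was planted.
"""

from _demo import CORPUS, DEMO

from abmanet import io
from abmanet.simulate import generate_evidence_table, generate_ppi_edges, generate_term_sets


def main() -> None:
    print(f"simulating corpus: {DEMO.n_genes} genes x {DEMO.diseases}, "
          f"seed {DEMO.seed}")
    evidence, truth = generate_evidence_table(DEMO)
    io.write_tsv(evidence, CORPUS / "evidence.tsv")
    io.write_tsv(truth, CORPUS / "truth.tsv")
    io.write_tsv(generate_ppi_edges(DEMO.gene_ids, DEMO), CORPUS / "ppi_edges.tsv")
    io.write_gmt(generate_term_sets(DEMO.gene_ids, DEMO), CORPUS / "terms.gmt")

    per_disease = truth.groupby("disease_id")["associated"].sum()
    covered = (evidence[["n_pos", "n_neg", "n_incon"]].sum(axis=1) > 0).mean()
    print(f"planted associations per disease: {per_disease.to_dict()}")
    print(f"fraction of pairs with literature: {covered:.3f}")
    print(f"wrote corpus to {CORPUS}")


if __name__ == "__main__":
    main()
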