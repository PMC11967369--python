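"""Readers and writers for the pipeline's plain-text file contracts.

All tables are UTF-8 tab-separated with a header row and ``\n`` line
endings, so identical inputs yield byte-identical files.  Term sets use
the standard GMT layout: term id, description, then members, one term per
line.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_tsv",
    "write_tsv",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
]

EVIDENCE_COLUMNS = ["gene_id", "disease_id", "n_pos", "n_neg", "n_incon"]
EDGE_COLUMNS = ["source", "target", "weight", "sign"]
TRUTH_COLUMNS = ["gene_id", "disease_id", "associated", "polarity"]


def read_tsv(path, required=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "disease_id": str})
    if required:
        missing = set(required) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.6g")


def read_gmt(path) -> dict[str, list[str]]:
    terms: dict[str, list[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{i + 1}: GMT line needs term, description, members")
        terms[fields[0]] = [g for g in fields[2:] if g]
    return terms


def write_gmt(terms: dict[str, list[str]], path, description: str = "synthetic") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for term_id in terms:
            fh.write("\t".join([term_id, description, *terms[term_id]]) + "\n")


def read_gene_list(path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    return df.iloc[:, 0].astype(str).tolist()


def write_gene_list(genes, path, column: str = "gene_id") -> None:
    write_tsv(pd.DataFrame({column: list(genes)}), path)
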