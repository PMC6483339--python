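#!/usr/bin/env python
"""Refine each class's top-200 signature to its unique genes.

A gene is unique to a class when expressed (log2(TPM+1) > 2) in more than
half of the class's cells and in at most 10% of every other class's
cells.  Writes per-class unique-gene tables to results/unique/.
"""

import json
from pathlib import Path

import pandas as pd

import itersig as ig
from itersig.unique import write_unique_genes

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA, CLUST, SIG, OUT = (
    ROOT / "data", ROOT / "clustering", ROOT / "signatures", ROOT / "unique"
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sc = ig.read_tpm_matrix(DATA / "sc_matrix.tsv", DATA / "sc_metadata.tsv")
    labels = pd.read_csv(CLUST / "labels.tsv", sep="\t")
    sigs = pd.read_csv(SIG / "signatures.tsv", sep="\t")
    truth = json.loads((DATA / "truth.json").read_text())

    kept = labels["final_class"] != 0
    sub = sc.subset_columns(list(labels.loc[kept, "cell_id"]))
    names = labels.loc[kept, "class_name"].to_numpy()

    pool = {c: list(g["gene"]) for c, g in sigs.groupby("class")}
    uniq = ig.unique_genes(sub, names, ig.UniqueGeneFilter(candidate_pool=pool))
    write_unique_genes(uniq, OUT / "unique_genes.tsv")

    print("unique genes per class (planted markers in parentheses):")
    for cls, n in sorted(uniq.counts().items()):
        planted = set(truth["class_markers"].get(cls, []))
        hit = len(planted & set(uniq.genes(cls)))
        print(f"  {cls}: {n} ({hit}/{len(planted)} planted)")


if __name__ == "__main__":
    main()
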