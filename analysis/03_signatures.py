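#!/usr/bin/env python
"""Rank Product signatures of the recovered major classes.

For each retained class, genes are ranked by one-sided Wilcoxon rank-sum
and fold change against all other cells and integrated with the Rank
Product; the top-200 lists, their pooled union, per-class plain gene-list
exports, planted-marker recovery, and a 2-D t-SNE on the pooled genes go
to results/signatures/.
"""

import json
from pathlib import Path

import pandas as pd

import itersig as ig
from itersig.ranking import write_signatures

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA, CLUST, OUT = ROOT / "data", ROOT / "clustering", ROOT / "signatures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sc = ig.read_tpm_matrix(DATA / "sc_matrix.tsv", DATA / "sc_metadata.tsv")
    labels = pd.read_csv(CLUST / "labels.tsv", sep="\t")
    truth = json.loads((DATA / "truth.json").read_text())

    kept = labels["final_class"] != 0
    sub = sc.subset_columns(list(labels.loc[kept, "cell_id"]))
    names = labels.loc[kept, "class_name"].to_numpy()

    sigs = ig.signatures_for_all_classes(sub, names, None, 200)
    write_signatures(sigs, OUT / "signatures.tsv")
    pooled = ig.pool_training_set(sigs)

    for cls in sigs.class_ids():
        (OUT / f"genes_{cls}.txt").write_text("\n".join(sigs.genes(cls)) + "\n")

    emb = ig.tsne_embed(sub, pooled, seed=7)
    emb["class_name"] = names
    emb.to_csv(OUT / "tsne.tsv", sep="\t", index=False)

    print(f"signatures for {len(sigs.class_ids())} classes; "
          f"pooled training set: {len(pooled)} genes")
    for cls in sigs.class_ids():
        planted = set(truth["class_markers"].get(cls, []))
        if planted:
            hit = len(planted & set(sigs.genes(cls)))
            print(f"  {cls}: {hit}/{len(planted)} planted markers in top-200")


if __name__ == "__main__":
    main()
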