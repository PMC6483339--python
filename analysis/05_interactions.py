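#!/usr/bin/env python
"""Receptor-ligand interactions among the bile-duct cell classes.

Restricts the unique-gene sets to the classes present in the 4d-IL33
bile-duct group, predicts directed ligand->receptor edges against the
pair table, and exports the edge list, the class x class adjacency
matrix for chord plotting, and the per-class degree summary to
results/interactions/.
"""

import json
from pathlib import Path

import pandas as pd

import itersig as ig
from itersig.interactions import edge_summary, export_chord
from itersig.unique import read_unique_genes, UniqueGeneSet

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA, CLUST, UNIQ, OUT = (
    ROOT / "data", ROOT / "clustering", ROOT / "unique", ROOT / "interactions"
)

DUCT_GROUP = "EHBD-4d-IL33"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    uniq = read_unique_genes(UNIQ / "unique_genes.tsv")
    labels = pd.read_csv(CLUST / "labels.tsv", sep="\t")
    meta = pd.read_csv(DATA / "sc_metadata.tsv", sep="\t")
    truth = json.loads((DATA / "truth.json").read_text())
    table = ig.load_rl_table(DATA / "rl_pairs.tsv")

    # classes with at least 2 cells in the bile-duct group
    duct_cells = set(meta.loc[meta["group"] == DUCT_GROUP, "column_id"])
    in_duct = labels[labels["cell_id"].isin(duct_cells)]
    duct_classes = [
        c for c, n in in_duct["class_name"].value_counts().items()
        if c != "excluded" and n >= 2
    ]
    duct_sets = UniqueGeneSet(
        {c: uniq.per_class[c] for c in duct_classes if c in uniq.per_class}
    )

    edges = ig.predict_interactions(duct_sets, table)
    export_chord(edges, duct_sets.class_ids(), OUT)
    summary = edge_summary(edges, duct_sets.class_ids())
    summary.to_csv(OUT / "degree_summary.tsv", sep="\t", index=False)

    planted = {(s, l, t, r) for l, r, s, t in map(tuple, truth["planted_pairs"])}
    got = {(e.source, e.ligand, e.target, e.receptor) for e in edges}
    print(f"bile-duct classes: {duct_sets.class_ids()}")
    print(f"predicted edges: {len(edges)} "
          f"({len(got & planted)}/{len(planted)} planted pairs recovered; "
          f"{len(got - planted)} spurious)")
    at_bim = summary[summary["class"] == "BIM"]
    if len(at_bim):
        deg = at_bim["degree"].iloc[0]
        share = at_bim.set_index("partner")["frac_shared"].get("cILC2", 0.0)
        print(f"edges at BIM: {deg}; share with cILC2: {100 * share:.0f}%")


if __name__ == "__main__":
    main()
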