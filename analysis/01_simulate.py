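#!/usr/bin/env python
"""Generate the study-shaped synthetic dataset.

Writes the single-cell TPM matrix (four treatment groups, 17 latent cell
classes of which 11 have fewer than 5 cells), the bulk tissue matrix
(3 replicates for each of PBS liver, 4d-IL33 liver and 4d-IL33 bile
duct), the ligand-receptor pair table (15 planted pairs among the three
bile-duct classes plus 30 decoys), and the ground truth, under
results/data/.
"""

import json
from pathlib import Path

import itersig as ig
from itersig.matrix import write_group_metadata, write_matrix

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = ig.study_spec(seed=SEED)
    sc, truth = ig.simulate_single_cell_matrix(spec)
    bulk = ig.simulate_bulk_matrix(
        sc, truth, ig.simulate.default_bulk_frequencies(truth),
        n_replicates=3, noise_sd=0.2, seed=SEED + 1,
    )
    rl = ig.simulate_rl_table(truth, n_decoys=30, seed=SEED + 2,
                              n_genes_hint=spec.n_genes)

    write_matrix(sc, OUT / "sc_matrix.tsv")
    write_group_metadata(sc.column_groups, OUT / "sc_metadata.tsv")
    write_matrix(bulk, OUT / "bulk_matrix.tsv")
    write_group_metadata(bulk.column_groups, OUT / "bulk_metadata.tsv")
    rl.to_csv(OUT / "rl_pairs.tsv", sep="\t", index=False)
    (OUT / "truth.json").write_text(
        json.dumps(
            {
                "cell_to_class": dict(truth.cell_to_class),
                "class_markers": {c: list(g) for c, g in truth.class_markers.items()},
                "planted_pairs": [list(p) for p in truth.planted_pairs],
                "seed": SEED,
            },
            indent=1, sort_keys=True,
        )
    )

    sizes = sc.group_design().sizes()
    print(f"single-cell matrix: {sc.n_genes} genes x {sc.n_columns} cells")
    print(f"cells per group (yield range 39-82 in the sorted data): {sizes}")
    print(f"latent classes: {len(spec.classes)} "
          f"({sum(1 for c in spec.classes if c.total_cells < 5)} below 5 cells)")
    print(f"bulk matrix: {bulk.n_columns} samples; "
          f"RL table: {len(rl)} pairs ({len(truth.planted_pairs)} planted)")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
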