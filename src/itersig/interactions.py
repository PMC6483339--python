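"""Receptor-ligand cell-cell interaction inference from unique-gene sets.

Given the per-class unique genes and a curated two-column ligand-receptor
pair table, an interaction edge A -> B is predicted whenever a table pair
(L, R) has L unique to class A and R unique to class B.  Edges are
directed (ligand source to receptor target); the per-class degree summary
counts a class's incident edges regardless of direction, matching how a
chord diagram is read.  Exports are the long-format edge list and a
class x class adjacency count matrix directly consumable by chord-diagram
tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .unique import UniqueGeneSet


@dataclass(frozen=True)
class InteractionEdge:
    source: object   # class providing the ligand
    ligand: str
    target: object   # class providing the receptor
    receptor: str


def load_rl_table(path) -> pd.DataFrame:
    """Two-column [ligand, receptor] TSV, deduplicated, order preserved."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["ligand", "receptor"]:
        raise ValueError(
            f"{path}: expected header [ligand, receptor], got {list(df.columns)}"
        )
    for i, row in df.iterrows():
        if pd.isna(row["ligand"]) or pd.isna(row["receptor"]):
            raise ValueError(f"{path}: malformed row at line {i + 2}")
    return df.drop_duplicates(ignore_index=True)


def write_rl_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def predict_interactions(
    u: UniqueGeneSet,
    table: pd.DataFrame,
    include_self: bool = False,
) -> list[InteractionEdge]:
    """All edges A->B with ligand unique to A and receptor unique to B.

    Sorted by (source, target, ligand, receptor).  Self-edges (autocrine)
    are off by default.
    """
    classes = u.class_ids()
    if len(classes) < (1 if include_self else 2):
        raise ValueError("need at least 2 classes (or 1 with include_self)")
    membership = {c: set(u.genes(c)) for c in classes}
    pairs = list(zip(table["ligand"], table["receptor"]))
    edges = []
    for a in classes:
        for b in classes:
            if a == b and not include_self:
                continue
            for lig, rec in pairs:
                if lig in membership[a] and rec in membership[b]:
                    edges.append(InteractionEdge(a, lig, b, rec))
    edges.sort(key=lambda e: (str(e.source), str(e.target), e.ligand, e.receptor))
    return edges


def edge_summary(edges: Sequence[InteractionEdge], classes: Sequence) -> pd.DataFrame:
    """Per-class degree (direction-blind) and partner-sharing fractions."""
    rows = []
    for c in classes:
        incident = [e for e in edges if e.source == c or e.target == c]
        partners: dict = {}
        for e in incident:
            other = e.target if e.source == c else e.source
            partners[other] = partners.get(other, 0) + 1
        for other in classes:
            if other == c:
                continue
            n = partners.get(other, 0)
            rows.append(
                (c, len(incident), other, n,
                 n / len(incident) if incident else 0.0)
            )
    return pd.DataFrame(
        rows, columns=["class", "degree", "partner", "n_shared", "frac_shared"]
    )


def edges_frame(edges: Sequence[InteractionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.source, e.ligand, e.target, e.receptor) for e in edges],
        columns=["source_class", "ligand", "target_class", "receptor"],
    )


def adjacency_matrix(
    edges: Sequence[InteractionEdge], classes: Sequence
) -> pd.DataFrame:
    """Square class x class matrix of directed edge counts."""
    classes = list(classes)
    mat = pd.DataFrame(0, index=classes, columns=classes)
    for e in edges:
        mat.loc[e.source, e.target] += 1
    return mat


def export_chord(
    edges: Sequence[InteractionEdge],
    classes: Sequence,
    out_dir,
    prefix: str = "interactions",
) -> tuple[Path, Path]:
    """Write the edge list TSV and the adjacency CSV for chord plotting."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edge_path = out_dir / f"{prefix}_edges.tsv"
    adj_path = out_dir / f"{prefix}_adjacency.csv"
    edges_frame(edges).to_csv(edge_path, sep="\t", index=False)
    adjacency_matrix(edges, classes).to_csv(adj_path)
    return edge_path, adj_path
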