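"""Class-specific "unique genes".

A gene is unique to a cell class when it is expressed — log2(TPM+1)
strictly above a threshold (default 2, i.e. TPM > 3) — in more than half
of that class's cells and effectively not expressed in any other class.
"Not expressed" is operationalised as an expressing fraction at or below a
small ceiling (default 0.1) rather than strictly zero, which would be
fragile to single-cell noise; setting the ceiling to 0 restores the
strict reading.  Candidates are drawn from each class's top-200 signature
by default, matching the workflow in which the signature list is refined
rather than the whole transcriptome rescanned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, as_log
from .clustering import UNASSIGNED


@dataclass(frozen=True)
class UniqueGeneFilter:
    expr_threshold: float = 2.0  # log2(TPM+1) cut; > 2 means TPM > 3
    frac_in: float = 0.5         # strict >: expressed in more than half the class
    frac_out: float = 0.1        # ceiling in every other class
    candidate_pool: Mapping[object, Sequence[str]] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.frac_out < self.frac_in <= 1:
            raise ValueError("need 0 <= frac_out < frac_in <= 1")
        if self.expr_threshold < 0:
            raise ValueError("expr_threshold must be >= 0")


@dataclass(frozen=True)
class UniqueGeneSet:
    """class id -> frame [gene, frac_in_class, max_frac_other, mean_log_expr]."""

    per_class: Mapping[object, pd.DataFrame]

    def genes(self, class_id) -> list[str]:
        return list(self.per_class[class_id]["gene"])

    def class_ids(self) -> list:
        return sorted(self.per_class, key=str)

    def counts(self) -> dict:
        return {c: len(df) for c, df in self.per_class.items()}


def expressing_fraction(
    m: ExpressionMatrix,
    labels: Sequence,
    gene: str,
    class_id,
    threshold: float = 2.0,
) -> float:
    """Fraction of the class's cells with log2(TPM+1) strictly above threshold."""
    labels = np.asarray(labels)
    mask = labels == class_id
    if not mask.any():
        raise KeyError(f"unknown or empty class {class_id!r}")
    row = as_log(m).values[m.gene_index(gene)]
    return float((row[mask] > threshold).mean())


def unique_genes(
    m: ExpressionMatrix,
    labels: Sequence,
    filt: UniqueGeneFilter = UniqueGeneFilter(),
) -> UniqueGeneSet:
    """Per-class unique-gene sets; disjoint across classes by construction.

    Cells labelled UNASSIGNED (excluded minor classes) take part in no
    fraction computation.  Raising ``expr_threshold`` or ``frac_in`` can
    only shrink the sets.
    """
    labels = np.asarray(labels)
    keep = labels != UNASSIGNED
    classes = sorted(set(labels[keep]), key=str)
    if len(classes) < 2:
        raise ValueError("unique genes need at least 2 classes")
    logv = as_log(m).values
    expressed = logv > filt.expr_threshold

    frac = {}
    for c in classes:
        mask = labels == c
        frac[c] = expressed[:, mask].mean(axis=1)

    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
    out: dict = {}
    for c in classes:
        pool = (
            list(filt.candidate_pool.get(c, []))
            if filt.candidate_pool is not None
            else list(m.gene_ids)
        )
        rows = []
        for g in pool:
            i = gene_pos.get(g)
            if i is None:
                continue
            fin = frac[c][i]
            others = [frac[c2][i] for c2 in classes if c2 != c]
            fmax = max(others) if others else 0.0
            if fin > filt.frac_in and fmax <= filt.frac_out:
                mean_expr = float(logv[i, labels == c].mean())
                rows.append((g, float(fin), float(fmax), mean_expr))
        out[c] = pd.DataFrame(
            rows, columns=["gene", "frac_in_class", "max_frac_other", "mean_log_expr"]
        )
    return UniqueGeneSet(out)


def apply_whitelist(u: UniqueGeneSet, whitelist: Sequence[str]) -> UniqueGeneSet:
    """Restrict every class's set to a user-supplied gene whitelist.

    Stand-in for manual curation toward surface and secreted proteins;
    applied after the fraction filter.
    """
    allowed = set(whitelist)
    return UniqueGeneSet(
        {c: df[df["gene"].isin(allowed)].reset_index(drop=True)
         for c, df in u.per_class.items()}
    )


def write_unique_genes(u: UniqueGeneSet, path) -> None:
    frames = []
    for c in u.class_ids():
        df = u.per_class[c].copy()
        df.insert(0, "class", c)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_unique_genes(path) -> UniqueGeneSet:
    df = pd.read_csv(path, sep="\t")
    return UniqueGeneSet(
        {c: sub.drop(columns="class").reset_index(drop=True)
         for c, sub in df.groupby("class", sort=True)}
    )
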