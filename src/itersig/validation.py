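"""Tissue-level validation of class signatures in bulk RNA-seq.

Each class's unique genes are checked in bulk tissue TPM data in two
steps: a detection ("signal") filter — the gene's mean linear TPM reaches
a floor in at least one group — and a one-tailed two-sample Student's
t-test (pooled variance, on log2(TPM+1)) of the focal tissue group against
each reference group, significant only when every reference comparison
falls below alpha.  The report mirrors the published three-count table:
number of unique genes, number with signal, number significantly enriched.
No multiple-testing correction is applied by default, matching the raw
p < 0.05 / p < 0.005 reporting of the source analysis; Benjamini-Hochberg
is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, align_genes, as_linear
from .unique import UniqueGeneSet


@dataclass(frozen=True)
class ValidationConfig:
    detection_tpm: float = 1.0   # mean linear TPM floor in >= 1 group
    alpha: float = 0.05
    reference_groups: tuple[str, ...] | None = None  # None = all non-focal
    require_all_references: bool = True
    bh_correction: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.detection_tpm < 0:
            raise ValueError("detection_tpm must be >= 0")


@dataclass(frozen=True)
class ValidationReport:
    summary: pd.DataFrame   # class, n_genes, n_signal, n_significant
    detail: pd.DataFrame    # class, gene, group means, per-reference p-values


def _group_masks(bulk: ExpressionMatrix) -> dict[str, np.ndarray]:
    cols = np.array([bulk.column_groups[c] for c in bulk.column_ids])
    return {g: cols == g for g in dict.fromkeys(cols)}


def signal_filter(
    bulk: ExpressionMatrix, genes: Sequence[str], cfg: ValidationConfig = ValidationConfig()
) -> list[str]:
    """Genes whose mean linear TPM reaches the detection floor in >= 1 group.

    Genes absent from the bulk matrix count as no-signal.
    """
    linear = as_linear(align_genes(bulk, [g for g in genes if g in set(bulk.gene_ids)]))
    masks = _group_masks(bulk)
    kept = []
    pos = {g: i for i, g in enumerate(linear.gene_ids)}
    for g in genes:
        i = pos.get(g)
        if i is None:
            continue
        means = [linear.values[i, m].mean() for m in masks.values()]
        if max(means) >= cfg.detection_tpm:
            kept.append(g)
    return kept


def pooled_t_one_tailed(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Student's pooled-variance t and one-tailed p for mean(x) > mean(y).

    Zero pooled variance is degenerate rather than an error: identical
    groups give p = 0.5 (no evidence either way), a strictly larger or
    smaller focal mean gives p = 0 or 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    delta = x.mean() - y.mean()
    if sp2 == 0:
        if delta == 0:
            return 0.0, 0.5
        return float(np.sign(delta) * np.inf), 0.0 if delta > 0 else 1.0
    t = delta / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), float(stats.t.sf(t, df))


def enrichment_test(
    bulk: ExpressionMatrix,
    gene: str,
    focal_group: str,
    cfg: ValidationConfig = ValidationConfig(),
) -> pd.DataFrame:
    """One-tailed t-test of the focal group against each reference group.

    Returns a frame [reference, t, p]; the gene is significant when p <
    alpha for every reference (or any single one, if configured).
    Performed on log2(TPM+1) values.
    """
    masks = _group_masks(bulk)
    if focal_group not in masks:
        raise KeyError(f"unknown focal group {focal_group!r}")
    refs = (
        list(cfg.reference_groups)
        if cfg.reference_groups is not None
        else [g for g in masks if g != focal_group]
    )
    row = np.log2(as_linear(bulk).values[bulk.gene_index(gene)] + 1.0)
    x = row[masks[focal_group]]
    if len(x) < 2:
        raise ValueError(f"focal group {focal_group!r} has fewer than 2 replicates")
    rows = []
    for ref in refs:
        y = row[masks[ref]]
        if len(y) < 2:
            raise ValueError(f"reference group {ref!r} has fewer than 2 replicates")
        t, p = pooled_t_one_tailed(x, y)
        rows.append((ref, t, p))
    return pd.DataFrame(rows, columns=["reference", "t", "p"])


def _is_significant(pvals: np.ndarray, cfg: ValidationConfig) -> bool:
    if cfg.require_all_references:
        return bool(np.all(pvals < cfg.alpha))
    return bool(np.any(pvals < cfg.alpha))


def validation_report(
    bulk: ExpressionMatrix,
    unique: UniqueGeneSet,
    focal_group: str,
    cfg: ValidationConfig = ValidationConfig(),
) -> ValidationReport:
    """Per class: gene count, signal count, significant count, plus detail.

    n_significant <= n_signal <= n_genes holds by construction: only genes
    passing the signal filter are tested.
    """
    summary_rows = []
    detail_rows = []
    masks = _group_masks(bulk)
    present = set(bulk.gene_ids)
    linear = as_linear(bulk)
    for cls in unique.class_ids():
        genes = unique.genes(cls)
        with_signal = signal_filter(bulk, genes, cfg)
        pvals_per_gene = {}
        for g in with_signal:
            tests = enrichment_test(bulk, g, focal_group, cfg)
            pvals_per_gene[g] = tests
        if cfg.bh_correction and pvals_per_gene:
            _apply_bh(pvals_per_gene)
        n_sig = 0
        for g in genes:
            if g in pvals_per_gene:
                tests = pvals_per_gene[g]
                sig = _is_significant(tests["p"].to_numpy(), cfg)
                n_sig += sig
            else:
                tests, sig = None, False
            means = {
                grp: float(linear.values[bulk.gene_index(g), m].mean())
                for grp, m in masks.items()
            } if g in present else {grp: float("nan") for grp in masks}
            detail_rows.append(
                {
                    "class": cls,
                    "gene": g,
                    "signal": g in pvals_per_gene,
                    "significant": bool(sig),
                    **{f"mean_tpm[{grp}]": v for grp, v in means.items()},
                    **(
                        {f"p[{r.reference}]": r.p for r in tests.itertuples()}
                        if tests is not None
                        else {}
                    ),
                }
            )
        summary_rows.append((cls, len(genes), len(with_signal), n_sig))
    summary = pd.DataFrame(
        summary_rows, columns=["class", "n_genes", "n_signal", "n_significant"]
    )
    return ValidationReport(summary, pd.DataFrame(detail_rows))


def _apply_bh(pvals_per_gene: dict) -> None:
    """Benjamini-Hochberg over all (gene, reference) p-values, in place."""
    from statsmodels.stats.multitest import multipletests

    flat = []
    for g, frame in pvals_per_gene.items():
        for i in range(len(frame)):
            flat.append((g, i, frame["p"].iloc[i]))
    if not flat:
        return
    _, adj, _, _ = multipletests([p for _, _, p in flat], method="fdr_bh")
    for (g, i, _), q in zip(flat, adj):
        pvals_per_gene[g].loc[pvals_per_gene[g].index[i], "p"] = q
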