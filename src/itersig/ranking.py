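"""Per-class signature genes via Rank Product over Wilcoxon and fold-change rankings.

For a target cell class, genes are ranked by (i) a one-sided Wilcoxon
rank-sum test of the class's cells against all other cells (alternative:
greater, i.e. up-regulation) and (ii) fold change of mean linear TPM with a
pseudocount.  When the class has subclusters, the same two rankings are
additionally computed for its focal (largest) subcluster against the rest,
giving up to four rankings.  The Rank Product — the geometric mean of a
gene's ranks across the supplied rankings — integrates them; small values
mean consistently top-ranked, and the top-n genes form the class signature.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, as_linear, as_log


class Criterion(str, enum.Enum):
    WILCOXON_CLUSTER = "wilcoxon_cluster"
    FC_CLUSTER = "fc_cluster"
    WILCOXON_SUBCLUSTER = "wilcoxon_subcluster"
    FC_SUBCLUSTER = "fc_subcluster"


@dataclass(frozen=True)
class GeneRanking:
    """Ranks 1..n_genes (smaller = stronger up-regulation evidence).

    ``statistic`` holds the raw per-gene quantity the ranking is built
    from: the one-sided p-value for Wilcoxon criteria, the fold change for
    fold-change criteria.
    """

    criterion: Criterion
    gene_ids: tuple[str, ...]
    ranks: np.ndarray
    statistic: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        total = n * (n + 1) / 2
        if abs(self.ranks.sum() - total) > 1e-6:
            raise ValueError("ranks do not cover 1..n_genes")

    def rank_of(self, gene: str) -> float:
        return float(self.ranks[self.gene_ids.index(gene)])


@dataclass(frozen=True)
class SignatureSet:
    """Per-class ordered signature gene lists with Rank Product scores."""

    top_n: int
    signatures: Mapping[str, pd.DataFrame]
    # each frame: columns [gene, rp] sorted ascending by rp

    def genes(self, class_id: str) -> list[str]:
        return list(self.signatures[class_id]["gene"])

    def class_ids(self) -> list[str]:
        return sorted(self.signatures)


# -- component rankings ---------------------------------------------------


def _one_sided_rank_sum_p(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 10
) -> np.ndarray:
    """Vectorised one-sided (x greater) Wilcoxon rank-sum p per gene row.

    Uses the exact null distribution when both sides are small and a row
    has no ties; otherwise the tie-corrected normal approximation without
    continuity correction, so that identical samples give exactly p = 0.5.
    """
    n1, n2 = x.shape[1], y.shape[1]
    data = np.hstack([x, y])
    ranks = stats.rankdata(data, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction on the rank variance
    n = n1 + n2
    tie_term = np.zeros(data.shape[0])
    for i in range(data.shape[0]):
        _, counts = np.unique(data[i], return_counts=True)
        tie_term[i] = np.sum(counts**3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u - mu) / sigma
    p = stats.norm.sf(z)
    degenerate = sigma == 0
    p[degenerate] = np.where(u[degenerate] > mu, 0.0, np.where(u[degenerate] < mu, 1.0, 0.5))

    if max(n1, n2) <= exact_max_n:
        # exact p where a row is tie-free
        for i in range(data.shape[0]):
            if len(np.unique(data[i])) == n:
                p[i] = stats.mannwhitneyu(
                    x[i], y[i], alternative="greater", method="exact"
                ).pvalue
    return p


def _fold_changes(
    linear_values: np.ndarray, in_mask: np.ndarray, pseudocount: float
) -> np.ndarray:
    mean_in = linear_values[:, in_mask].mean(axis=1)
    mean_out = linear_values[:, ~in_mask].mean(axis=1)
    return (mean_in + pseudocount) / (mean_out + pseudocount)


def _strict_ranks(primary: np.ndarray, *tiebreak: np.ndarray) -> np.ndarray:
    """Ranks 1..n from lexicographic order (primary ascending, then tiebreaks)."""
    order = np.lexsort(tuple(reversed(tiebreak)) + (primary,))
    ranks = np.empty(len(primary))
    ranks[order] = np.arange(1, len(primary) + 1)
    return ranks


def wilcoxon_ranking(
    m: ExpressionMatrix,
    labels: Sequence,
    target_class,
    criterion: Criterion = Criterion.WILCOXON_CLUSTER,
    pseudocount: float = 1.0,
) -> GeneRanking:
    """Rank genes by one-sided rank-sum p (target cells vs all others).

    Ties in p are broken by larger fold change, then gene id.
    """
    labels = np.asarray(labels)
    in_mask = labels == target_class
    if in_mask.sum() < 2 or (~in_mask).sum() < 2:
        raise ValueError(
            f"target class {target_class!r} and its complement each need >= 2 cells"
        )
    logm = as_log(m)
    p = _one_sided_rank_sum_p(logm.values[:, in_mask], logm.values[:, ~in_mask])
    fc = _fold_changes(as_linear(m).values, in_mask, pseudocount)
    gene_order = np.arange(len(m.gene_ids))
    lex = np.argsort(np.array(m.gene_ids))
    gene_rank = np.empty(len(m.gene_ids))
    gene_rank[lex] = gene_order
    ranks = _strict_ranks(p, -fc, gene_rank)
    return GeneRanking(criterion, m.gene_ids, ranks, p)


def fold_change_ranking(
    m: ExpressionMatrix,
    labels: Sequence,
    target_class,
    pseudocount: float = 1.0,
    criterion: Criterion = Criterion.FC_CLUSTER,
) -> GeneRanking:
    """Rank genes descending by (mean TPM in target + c)/(mean TPM in rest + c)."""
    labels = np.asarray(labels)
    in_mask = labels == target_class
    if in_mask.sum() < 2 or (~in_mask).sum() < 2:
        raise ValueError(
            f"target class {target_class!r} and its complement each need >= 2 cells"
        )
    fc = _fold_changes(as_linear(m).values, in_mask, pseudocount)
    lex = np.argsort(np.array(m.gene_ids))
    gene_rank = np.empty(len(m.gene_ids))
    gene_rank[lex] = np.arange(len(m.gene_ids))
    ranks = _strict_ranks(-fc, gene_rank)
    return GeneRanking(criterion, m.gene_ids, ranks, fc)


def rank_product(rankings: Sequence[GeneRanking]) -> pd.Series:
    """Geometric mean of each gene's ranks across 1-4 rankings, ascending.

    Invariant to the order the rankings are supplied in; improving a
    gene's rank in any single ranking never worsens its score.
    """
    if not 1 <= len(rankings) <= 4:
        raise ValueError("rank_product takes 1 to 4 rankings")
    universe = rankings[0].gene_ids
    for r in rankings[1:]:
        if r.gene_ids != universe:
            raise ValueError("rankings are over different gene universes")
    mat = np.vstack([r.ranks for r in rankings])
    rp = np.exp(np.log(mat).mean(axis=0))
    s = pd.Series(rp, index=list(universe), name="rp")
    return s.sort_values(kind="stable")


def class_signature(
    m: ExpressionMatrix,
    labels: Sequence,
    target_class,
    sublabels: Sequence | None = None,
    top_n: int = 200,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Top-n signature of one class by Rank Product.

    Two rankings (cluster-level Wilcoxon and fold change) when the class
    has no subclusters; four when it does, adding the same pair for the
    focal subcluster — the class's largest — against all other cells.
    Returns a frame [gene, rp] sorted ascending by Rank Product score.
    """
    labels = np.asarray(labels)
    if (labels == target_class).sum() < 2:
        raise ValueError(f"class {target_class!r} has fewer than 2 cells")
    rankings = [
        wilcoxon_ranking(m, labels, target_class, Criterion.WILCOXON_CLUSTER,
                         pseudocount),
        fold_change_ranking(m, labels, target_class, pseudocount),
    ]
    focal = _focal_subcluster(labels, sublabels, target_class)
    if focal is not None:
        sub = np.asarray(sublabels)
        rankings.append(
            wilcoxon_ranking(m, sub, focal, Criterion.WILCOXON_SUBCLUSTER,
                             pseudocount)
        )
        rankings.append(
            fold_change_ranking(m, sub, focal, pseudocount,
                                Criterion.FC_SUBCLUSTER)
        )
    rp = rank_product(rankings).iloc[:top_n]
    return pd.DataFrame({"gene": rp.index, "rp": rp.values})


def _focal_subcluster(labels, sublabels, target_class):
    """Largest subcluster of the target class, if it is genuinely split."""
    if sublabels is None:
        return None
    labels = np.asarray(labels)
    sub = np.asarray(sublabels)
    in_class = sub[labels == target_class]
    uniq, counts = np.unique(in_class, return_counts=True)
    if len(uniq) < 2:
        return None
    best = uniq[np.lexsort((uniq, -counts))][0]
    if (sub == best).sum() < 2 or (sub != best).sum() < 2:
        return None
    return best


def signatures_for_all_classes(
    m: ExpressionMatrix,
    labels: Sequence,
    sublabels: Sequence | None = None,
    top_n: int = 200,
) -> SignatureSet:
    """Signatures for every class with at least 2 cells.

    Singleton clusters cannot be ranked (the rank-sum test needs two
    target cells) and contribute no signature; they are skipped rather
    than aborting the surrounding iteration.
    """
    labels = np.asarray(labels)
    out: dict = {}
    for cls in sorted(set(labels), key=str):
        if (labels == cls).sum() < 2 or (labels != cls).sum() < 2:
            continue
        out[cls] = class_signature(m, labels, cls, sublabels, top_n)
    if not out:
        raise ValueError("no class has enough cells to rank")
    return SignatureSet(top_n, out)


def pool_training_set(signatures: SignatureSet) -> list[str]:
    """Deduplicated union of all class signatures, first-seen order by class id."""
    pooled: list[str] = []
    seen: set[str] = set()
    for cls in signatures.class_ids():
        for g in signatures.genes(cls):
            if g not in seen:
                seen.add(g)
                pooled.append(g)
    if not pooled:
        raise ValueError("pooled training set is empty")
    return pooled


def write_signatures(signatures: SignatureSet, path) -> None:
    rows = []
    for cls in signatures.class_ids():
        frame = signatures.signatures[cls]
        for i, row in enumerate(frame.itertuples(index=False), start=1):
            rows.append((cls, i, row.gene, row.rp))
    pd.DataFrame(rows, columns=["class", "rank", "gene", "rp"]).to_csv(
        path, sep="\t", index=False
    )
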