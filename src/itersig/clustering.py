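"""Iterative feature-selection clustering of single-cell TPM profiles.

The pipeline runs three steps per iteration: (1) feature selection —
principal components capturing a fixed fraction of variance at the first
iteration, the pooled per-class top-ranked signature genes afterwards;
(2) agglomerative average-linkage (UPGMA) clustering on Pearson-correlation
distance between cells, the flat cut chosen by mean silhouette width over a
candidate k range, optionally followed by one level of subclustering inside
each sufficiently large cluster; (3) per-class signature ranking (supplied
as a callback so the ranking stage stays swappable).  Iteration stops when
two consecutive clusterings agree exactly (adjusted Rand index 1) or at the
iteration cap.

After convergence, classes below a minimum size are excluded from all
downstream analysis and the per-group class-frequency table is computed
over retained classes, with excluded cells still counted in the group
denominators (the convention under which the per-group "total percentage
accounted for" can fall below 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .matrix import ExpressionMatrix, GroupDesign, as_log
from . import ranking as _ranking

UNASSIGNED = 0  # label for cells of excluded minor classes

# mean-silhouette floor below which a proposed subcluster split of a major
# cluster is rejected as 'no substantial structure' (rule-of-thumb cutoff)
SUBCLUSTER_SILHOUETTE_MIN = 0.25


@dataclass(frozen=True)
class ClusteringConfig:
    """Knobs of the iterative pipeline.

    ``variance_fraction``: cumulative explained-variance target of the
    first-iteration PCA (the study used 0.8).  ``min_class_size``: classes
    with fewer cells are excluded after convergence (study threshold: 5).
    ``top_n_signature``: per-class signature length pooled into the next
    iteration's feature set (study: 200).
    """

    variance_fraction: float = 0.8
    k_range: tuple[int, int] = (2, 20)
    subcluster: bool = True
    subcluster_k_range: tuple[int, int] = (2, 4)
    min_class_size: int = 5
    top_n_signature: int = 200
    max_iterations: int = 20
    min_cells_expressing: int = 2

    def __post_init__(self) -> None:
        if self.k_range[0] < 2:
            raise ValueError("k_range lower bound must be >= 2")
        if self.min_class_size < 1:
            raise ValueError("min_class_size must be >= 1")
        if not 0 < self.variance_fraction <= 1:
            raise ValueError("variance_fraction must be in (0, 1]")


@dataclass
class IterationRecord:
    feature_genes: list[str] | None  # None at iteration 1 (PCA features)
    labels: np.ndarray
    sublabels: np.ndarray


@dataclass
class ClusterResult:
    """Labels per iteration, final labels, dendrogram, convergence state."""

    iterations: list[IterationRecord]
    final_labels: np.ndarray
    final_sublabels: np.ndarray
    linkage: np.ndarray
    converged: bool
    n_iterations: int
    column_ids: tuple[str, ...]

    def n_terminal_classes(self) -> int:
        """Clusters plus accepted subclusters (a split cluster contributes
        its subclusters, an unsplit one contributes itself)."""
        return len(set(map(str, self.final_sublabels)))


# -- building blocks ------------------------------------------------------


def pca_reduce(m: ExpressionMatrix, variance_fraction: float = 0.8) -> np.ndarray:
    """Cells x components scores: the fewest leading principal components
    whose cumulative explained variance reaches ``variance_fraction``.

    Cells are observations and genes features; each gene is mean-centered.
    """
    if m.n_columns < 2:
        raise ValueError("PCA needs at least 2 cells")
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must be in (0, 1]")
    x = as_log(m).values.T  # cells x genes
    if np.allclose(x, x.mean(axis=0), atol=1e-12):
        # no variance at all: a single constant component
        return np.zeros((x.shape[0], 1))
    pca = PCA(svd_solver="full", random_state=0)
    scores = pca.fit_transform(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_fraction - 1e-9) + 1)
    n_comp = min(n_comp, scores.shape[1])
    return scores[:, :n_comp]


def pearson_distance(features: np.ndarray, ids: Sequence[str] | None = None) -> np.ndarray:
    """1 - Pearson correlation between every pair of cell feature vectors.

    Symmetric, zero diagonal, values in [0, 2].  A cell whose feature
    vector has zero variance has undefined correlation and is rejected by
    name.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 features per cell")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        i = int(np.flatnonzero(sd == 0)[0])
        name = ids[i] if ids is not None else f"index {i}"
        raise ValueError(f"cell {name} has a zero-variance profile")
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    # quantize away float residue so exact ties (identical profiles) stay
    # exact regardless of feature order, keeping linkage deterministic
    return np.round(np.clip(d, 0.0, 2.0), 12)


def _linkage_from_dist(dist: np.ndarray) -> np.ndarray:
    return hierarchy.linkage(squareform(dist, checks=False), method="average")


def hcluster(dist: np.ndarray, k: int, linkage: np.ndarray | None = None) -> np.ndarray:
    """Average-linkage tree cut into exactly k flat clusters.

    Labels are 1..k ordered by decreasing cluster size, ties broken by the
    smallest member index.
    """
    n = dist.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    if linkage is None:
        linkage = _linkage_from_dist(dist)
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return relabel_by_size(raw)


def relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """Renumber cluster ids 1.. by decreasing size, ties by first member."""
    raw = np.asarray(raw)
    uniq = np.unique(raw)
    first = {u: int(np.flatnonzero(raw == u)[0]) for u in uniq}
    order = sorted(uniq, key=lambda u: (-(raw == u).sum(), first[u]))
    mapping = {u: i + 1 for i, u in enumerate(order)}
    return np.array([mapping[u] for u in raw])


def choose_k(
    dist: np.ndarray,
    k_range: tuple[int, int],
    linkage: np.ndarray | None = None,
    return_score: bool = False,
):
    """The k in [k_range] maximising mean silhouette width on ``dist``.

    Deterministic; ties go to the smaller k.  If every candidate cut is
    degenerate (e.g. all distances equal), returns the lower bound with a
    warning and a score of -inf.
    """
    n = dist.shape[0]
    lo, hi = k_range
    lo = max(lo, 2)
    hi = min(hi, n - 1)
    if hi < lo:
        hi = lo = min(max(lo, 2), n)
    if linkage is None:
        linkage = _linkage_from_dist(dist)
    off_diag = dist[~np.eye(n, dtype=bool)]
    if off_diag.size and np.allclose(off_diag, off_diag[0]):
        warnings.warn("all pairwise distances equal; returning smallest k")
        return (lo, -np.inf) if return_score else lo
    best_k, best_s = lo, -np.inf
    for k in range(lo, hi + 1):
        labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
        n_lab = len(np.unique(labels))
        if n_lab < 2 or n_lab > n - 1:
            continue
        s = float(silhouette_score(dist, labels, metric="precomputed"))
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if not np.isfinite(best_s):
        warnings.warn("degenerate distance matrix; returning smallest k")
    return (best_k, best_s) if return_score else best_k


# -- the iterative pipeline -----------------------------------------------

RankFn = Callable[[ExpressionMatrix, np.ndarray, np.ndarray | None, int], list[str]]


def default_rank_fn(
    m: ExpressionMatrix,
    labels: np.ndarray,
    sublabels: np.ndarray | None,
    top_n: int,
) -> list[str]:
    """Pool per-class Rank Product top-n signatures into a training set.

    If no class can be ranked (e.g. the cut produced a single cluster, so
    there is no complement to test against), feature selection is
    impossible and the full gene set is returned unchanged.
    """
    try:
        sigs = _ranking.signatures_for_all_classes(m, labels, sublabels, top_n)
    except ValueError:
        return list(m.gene_ids)
    return _ranking.pool_training_set(sigs)


def prefilter_genes(m: ExpressionMatrix, min_cells_expressing: int) -> ExpressionMatrix:
    """Drop genes detected (value > 0) in fewer than ``min_cells_expressing`` cells."""
    keep = (m.values > 0).sum(axis=1) >= min_cells_expressing
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    return m.subset_genes(genes)


def _subcluster(
    logm: ExpressionMatrix, labels: np.ndarray, cfg: ClusteringConfig
) -> np.ndarray:
    """One level of subclustering inside each large-enough major cluster.

    A split is kept only if its best silhouette clears
    ``SUBCLUSTER_SILHOUETTE_MIN``; otherwise the cluster stays whole.
    Sublabels are globally unique strings "<cluster>" or "<cluster>.<sub>".
    """
    sub = np.array([str(c) for c in labels], dtype=object)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2 * cfg.min_class_size:
            continue
        x = logm.values[:, idx].T
        sd = x.std(axis=1)
        if np.any(sd == 0):
            continue
        dist = pearson_distance(x)
        k, score = choose_k(dist, cfg.subcluster_k_range, return_score=True)
        if not np.isfinite(score) or score < SUBCLUSTER_SILHOUETTE_MIN:
            continue
        sl = hcluster(dist, k)
        for j, s in zip(idx, sl):
            sub[j] = f"{c}.{s}"
    return sub


def iterate(
    m: ExpressionMatrix,
    cfg: ClusteringConfig = ClusteringConfig(),
    rank_fn: RankFn = default_rank_fn,
) -> ClusterResult:
    """Run the full iterative pipeline on a TPM matrix.

    Iteration 1 clusters cells on PCA scores; every later iteration
    clusters on the pooled top-ranked genes from the previous labels.
    Convergence is label identity (ARI = 1) between consecutive iterations.
    """
    logm = as_log(prefilter_genes(m, cfg.min_cells_expressing))
    if logm.n_genes == 0:
        raise ValueError("no genes left after expression prefilter")

    records: list[IterationRecord] = []
    prev_labels: np.ndarray | None = None
    labels = sublabels = None
    linkage = None
    converged = False
    feature_genes: list[str] | None = None

    for _it in range(cfg.max_iterations):
        if feature_genes is None:
            coords = pca_reduce(logm, cfg.variance_fraction)
            if coords.shape[1] < 2 or np.allclose(coords.std(axis=0), 0):
                # correlation needs >= 2 informative features; fall back
                # to the genes themselves on (near-)degenerate data
                full = pca_reduce(logm, 1.0)
                coords = full[:, :2] if full.shape[1] >= 2 else logm.values.T
            feats = coords
        else:
            sel = logm.subset_genes(feature_genes)
            feats = sel.values.T
        dist = pearson_distance(feats, logm.column_ids)
        linkage = _linkage_from_dist(dist)
        k = choose_k(dist, cfg.k_range, linkage=linkage)
        labels = hcluster(dist, k, linkage=linkage)
        sublabels = (
            _subcluster(logm, labels, cfg)
            if cfg.subcluster
            else np.array([str(c) for c in labels], dtype=object)
        )
        records.append(IterationRecord(feature_genes, labels, sublabels))

        if prev_labels is not None and adjusted_rand_score(prev_labels, labels) == 1.0:
            converged = True
            break
        prev_labels = labels
        feature_genes = rank_fn(logm, labels, sublabels, cfg.top_n_signature)
        if not feature_genes:
            raise ValueError("pooled feature set is empty")

    return ClusterResult(
        iterations=records,
        final_labels=labels,
        final_sublabels=sublabels,
        linkage=linkage,
        converged=converged,
        n_iterations=len(records),
        column_ids=logm.column_ids,
    )


# -- post-processing ------------------------------------------------------


def filter_minor_classes(
    labels: np.ndarray, min_class_size: int = 5
) -> tuple[np.ndarray, list]:
    """Exclude classes with fewer than ``min_class_size`` cells.

    Excluded cells get the UNASSIGNED label (0); retained classes are
    renumbered 1.. by decreasing size.  Retained cells keep their
    co-membership exactly.
    """
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    excluded = [u for u, c in zip(uniq, counts) if c < min_class_size]
    if len(excluded) == len(uniq):
        raise ValueError("all classes fall below the minimum size")
    out = labels.copy()
    mask = np.isin(labels, excluded)
    kept = labels[~mask]
    renumbered = relabel_by_size(kept)
    result = np.zeros(len(labels), dtype=int)
    result[~mask] = renumbered
    return result, excluded


def class_frequency_table(
    labels: np.ndarray,
    groups: GroupDesign,
    column_ids: Sequence[str],
    class_names: Sequence | None = None,
) -> pd.DataFrame:
    """Per-group percentage of cells in each major class, plus the total
    percentage accounted for.

    Excluded (UNASSIGNED) cells stay in the denominator but in no class
    column, so "Total %" < 100 exactly when minor classes were excluded.
    Percentages are rounded half-up to integers; the total is the sum of
    the rounded class percentages.
    """
    labels = np.asarray(labels)
    pos = {c: i for i, c in enumerate(column_ids)}
    classes = [c for c in np.unique(labels) if c != UNASSIGNED]
    names = list(class_names) if class_names is not None else [str(c) for c in classes]
    rows = {}
    for g in groups.groups:
        cols = groups.columns_per_group[g]
        if not cols:
            raise ValueError(f"group {g!r} is empty")
        glab = labels[[pos[c] for c in cols]]
        pcts = [
            int(np.floor(100.0 * (glab == cls).sum() / len(cols) + 0.5))
            for cls in classes
        ]
        rows[g] = pcts + [sum(pcts)]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=names + ["Total %"]
    )


def tsne_embed(
    m: ExpressionMatrix, feature_genes: Sequence[str], seed: int = 0
) -> pd.DataFrame:
    """2-D t-SNE of cells restricted to the pooled signature genes.

    Deterministic for a fixed seed.  Returns a frame [cell, x, y].
    """
    feats = [g for g in feature_genes if g in set(m.gene_ids)]
    if len(feats) < 2:
        raise ValueError("need at least 2 feature genes present in the matrix")
    x = as_log(m.subset_genes(feats)).values.T
    n = x.shape[0]
    perplexity = min(30.0, max(1.0, (n - 1) / 3.0))
    tsne = TSNE(
        n_components=2,
        random_state=seed,
        init="pca",
        perplexity=perplexity,
        method="exact" if n < 16 else "barnes_hut",
    )
    coords = tsne.fit_transform(x)
    return pd.DataFrame(
        {"cell": list(m.column_ids), "x": coords[:, 0], "y": coords[:, 1]}
    )
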