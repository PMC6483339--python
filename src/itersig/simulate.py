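"""Synthetic single-cell and bulk TPM data with planted ground truth.

The generator emulates the statistical structure of sorted CD45+ lineage-
negative hepatobiliary mononuclear cells profiled on a microfluidic
single-cell platform: a few hundred cells across four treatment groups
(PBS liver, 1d and 4d IL-33 liver, 4d IL-33 extrahepatic bile duct), a
handful of latent cell classes each with a block of class-specific marker
genes expressed high on the log2(TPM+1) scale, heavy dropout, and bulk
tissue samples that are noisy class-frequency-weighted mixtures of the
single-cell class profiles.

Two fixed designs are provided:

``default_spec``
    The parameter-recovery benchmark: 6 classes, 30 markers each, 50 cells
    per class distributed over the four groups with the tissue-restriction
    pattern of the study (one class dominant in the PBS group, shared
    classes, two classes exclusive to the bile duct).

``study_spec``
    The study-shape emulation: group sizes 70/72/77/64 (within the 39-82
    cells-per-group yield of the sorted data), the six major classes at
    cell counts whose rounded percentages reproduce the published
    frequency table exactly, plus 11 minor classes of fewer than 5 cells
    each — 17 latent subpopulations in total — to exercise the minor-class
    exclusion rule.

Expression model: log2(TPM+1) values are drawn Normal(mu, sigma) and
clipped at zero, with mu = ``mu_marker`` for a marker gene in its own
class's cells and ``mu_background`` everywhere else; independent per-entry
dropout then zeroes each value with fixed probability; values are finally
converted to linear TPM.  The model is deliberately log-normal rather than
count-based because every downstream stage operates on TPM, not UMIs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, Scale

GROUPS = ("PBS-Liver", "Liver-1d-IL33", "Liver-4d-IL33", "EHBD-4d-IL33")


class SimulationError(ValueError):
    """Raised for an invalid simulation specification."""


@dataclass(frozen=True)
class ClassSpec:
    """One latent cell class: its per-group cell counts and marker budget."""

    class_id: str
    n_cells: Mapping[str, int]
    n_markers: int

    @property
    def total_cells(self) -> int:
        return sum(self.n_cells.values())


@dataclass(frozen=True)
class SimulationSpec:
    """Full design of a synthetic single-cell experiment.

    ``mu_marker`` / ``mu_background`` are means of log2(TPM+1); ``sigma``
    is the normal noise s.d. on the same scale; ``dropout`` is the
    independent per-entry zeroing probability.
    """

    n_genes: int
    classes: tuple[ClassSpec, ...]
    mu_marker: float = 6.0
    mu_background: float = 0.5
    sigma: float = 1.0
    dropout: float = 0.3
    seed: int = 0
    planted_pairs: tuple[tuple[str, str], ...] = ()  # (source_class, target_class)

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise SimulationError("n_genes must be positive")
        if not 0.0 <= self.dropout <= 1.0:
            raise SimulationError("dropout must be in [0, 1]")
        ids = [c.class_id for c in self.classes]
        if len(set(ids)) != len(ids):
            raise SimulationError("duplicate class ids")
        for c in self.classes:
            if any(n < 0 for n in c.n_cells.values()):
                raise SimulationError(f"negative cell count in class {c.class_id}")
        if sum(c.n_markers for c in self.classes) > self.n_genes:
            raise SimulationError(
                "total marker genes exceed n_genes; marker sets must be disjoint"
            )
        known = {c.class_id for c in self.classes}
        for s, t in self.planted_pairs:
            if s not in known or t not in known:
                raise SimulationError(f"planted pair ({s}, {t}) names unknown class")


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth: cell labels, marker sets, and receptor-ligand pairs."""

    cell_to_class: Mapping[str, str]
    class_markers: Mapping[str, tuple[str, ...]]
    planted_pairs: tuple[tuple[str, str, str, str], ...] = ()
    # rows: (ligand gene, receptor gene, source class, target class)

    def labels_for(self, column_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.cell_to_class[c] for c in column_ids])

    @property
    def all_marker_genes(self) -> set[str]:
        return {g for ms in self.class_markers.values() for g in ms}


# -- designs --------------------------------------------------------------


def default_spec(seed: int = 0) -> SimulationSpec:
    """Six classes, 30 markers each, 50 cells per class (300 cells)."""
    g = GROUPS
    classes = (
        ClassSpec("ProB", {g[0]: 38, g[1]: 10, g[2]: 1, g[3]: 1}, 30),
        ClassSpec("gdT", {g[0]: 5, g[1]: 30, g[2]: 9, g[3]: 6}, 30),
        ClassSpec("cILC2", {g[1]: 1, g[2]: 27, g[3]: 22}, 30),
        ClassSpec("L-ILC2", {g[2]: 50}, 30),
        ClassSpec("BD-ILC1", {g[3]: 50}, 30),
        ClassSpec("BIM", {g[3]: 50}, 30),
    )
    return SimulationSpec(
        n_genes=2000, classes=classes, seed=seed, planted_pairs=default_rl_design()
    )


def study_spec(seed: int = 0) -> SimulationSpec:
    """Seventeen latent subpopulations shaped like the published study.

    Major-class counts are chosen so each group's rounded class
    percentages reproduce the published frequency table (Pro-B 76% of the
    PBS liver, γδ-T 25% of the 1d liver, totals 83/83/90/89), and the 11
    minor classes all fall under the 5-cell exclusion threshold.
    """
    g = GROUPS
    majors = (
        ClassSpec("ProB", {g[0]: 53, g[1]: 40, g[2]: 14, g[3]: 2}, 30),
        ClassSpec("gdT", {g[0]: 5, g[1]: 18, g[2]: 2, g[3]: 2}, 30),
        ClassSpec("cILC2", {g[1]: 1, g[2]: 41, g[3]: 36}, 30),
        ClassSpec("BIM", {g[1]: 1, g[3]: 7}, 30),
        ClassSpec("BD-ILC1", {g[3]: 10}, 30),
        ClassSpec("L-ILC2", {g[2]: 12}, 30),
    )
    minor_sizes = {
        g[0]: (4, 4, 4),
        g[1]: (4, 4, 4),
        g[2]: (3, 3, 2),
        g[3]: (4, 3),
    }
    minors = tuple(
        ClassSpec(f"minor{i + 1:02d}", {grp: n}, 10)
        for i, (grp, n) in enumerate(
            (grp, n) for grp in g for n in minor_sizes[grp]
        )
    )
    return SimulationSpec(
        n_genes=2000,
        classes=majors + minors,
        seed=seed,
        planted_pairs=default_rl_design(),
    )


def default_rl_design() -> tuple[tuple[str, str], ...]:
    """Planted ligand->receptor class pairs among the bile-duct classes.

    Fifteen pairs among the three classes present in the bile duct, six of
    them incident to the immature-myeloid class (four of those six with
    canonical ILC2), mirroring the interaction topology the analysis is
    meant to surface.
    """
    return (
        ("BIM", "cILC2"),
        ("BIM", "cILC2"),
        ("cILC2", "BIM"),
        ("cILC2", "BIM"),
        ("BIM", "BD-ILC1"),
        ("BD-ILC1", "BIM"),
        ("cILC2", "BD-ILC1"),
        ("cILC2", "BD-ILC1"),
        ("cILC2", "BD-ILC1"),
        ("cILC2", "BD-ILC1"),
        ("cILC2", "BD-ILC1"),
        ("BD-ILC1", "cILC2"),
        ("BD-ILC1", "cILC2"),
        ("BD-ILC1", "cILC2"),
        ("BD-ILC1", "cILC2"),
    )


# -- generators -----------------------------------------------------------


def simulate_single_cell_matrix(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw a single-cell TPM matrix and its ground truth.

    Deterministic given ``spec.seed``; identical specs give byte-identical
    matrices.
    """
    rng = np.random.default_rng(spec.seed)
    genes = tuple(f"g{i + 1:04d}" for i in range(spec.n_genes))

    # contiguous disjoint marker blocks, in class order
    class_markers: dict[str, tuple[str, ...]] = {}
    off = 0
    for c in spec.classes:
        class_markers[c.class_id] = genes[off : off + c.n_markers]
        off += c.n_markers

    cell_ids: list[str] = []
    cell_class: list[str] = []
    groups: dict[str, str] = {}
    for grp in _group_order(spec):
        i = 0
        for c in spec.classes:
            for _ in range(c.n_cells.get(grp, 0)):
                i += 1
                cid = f"{grp}.c{i:03d}"
                cell_ids.append(cid)
                cell_class.append(c.class_id)
                groups[cid] = grp

    n_cells = len(cell_ids)
    mu = np.full((spec.n_genes, n_cells), spec.mu_background)
    gene_pos = {g: i for i, g in enumerate(genes)}
    class_arr = np.array(cell_class)
    for c in spec.classes:
        cols = np.flatnonzero(class_arr == c.class_id)
        rows = [gene_pos[g] for g in class_markers[c.class_id]]
        mu[np.ix_(rows, cols)] = spec.mu_marker

    logvals = np.clip(rng.normal(mu, spec.sigma), 0.0, None)
    keep = rng.random(logvals.shape) >= spec.dropout
    logvals *= keep
    tpm = np.exp2(logvals) - 1.0
    tpm[tpm < 0] = 0.0

    matrix = ExpressionMatrix(genes, tuple(cell_ids), tpm, Scale.LINEAR_TPM, groups)

    planted = _assign_pair_genes(spec, class_markers, rng)
    truth = GroundTruth(
        cell_to_class=dict(zip(cell_ids, cell_class)),
        class_markers=class_markers,
        planted_pairs=planted,
    )
    return matrix, truth


def _group_order(spec: SimulationSpec) -> list[str]:
    order: list[str] = []
    for c in spec.classes:
        for grp in c.n_cells:
            if grp not in order:
                order.append(grp)
    return order


def _assign_pair_genes(
    spec: SimulationSpec,
    class_markers: Mapping[str, tuple[str, ...]],
    rng: np.random.Generator,
) -> tuple[tuple[str, str, str, str], ...]:
    """Pick a distinct ligand/receptor marker gene for each planted pair."""
    used: set[str] = set()
    rows: list[tuple[str, str, str, str]] = []
    for src, tgt in spec.planted_pairs:
        lig = next(g for g in class_markers[src] if g not in used)
        used.add(lig)
        rec = next(g for g in class_markers[tgt] if g not in used)
        used.add(rec)
        rows.append((lig, rec, src, tgt))
    return tuple(rows)


def simulate_bulk_matrix(
    sc: ExpressionMatrix,
    truth: GroundTruth,
    frequencies: Mapping[str, Mapping[str, float]],
    n_replicates: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> ExpressionMatrix:
    """Bulk tissue samples as noisy mixtures of single-cell class profiles.

    Each bulk sample's linear TPM profile is the class-frequency-weighted
    sum of the mean class profiles, multiplied per entry by
    exp(Normal(0, noise_sd)).  ``n_replicates`` samples per group (three
    per group in the study).
    """
    if n_replicates < 2:
        raise SimulationError("need at least 2 replicates per group")
    labels = truth.labels_for(sc.column_ids)
    profiles: dict[str, np.ndarray] = {}
    for cls in set(labels):
        profiles[cls] = sc.values[:, labels == cls].mean(axis=1)

    rng = np.random.default_rng(seed)
    cols: list[str] = []
    groups: dict[str, str] = {}
    vals = []
    for grp, weights in frequencies.items():
        total = sum(weights.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"weights for group {grp!r} sum to {total}, not 1")
        base = np.zeros(sc.n_genes)
        for cls, w in weights.items():
            if cls not in profiles:
                raise SimulationError(f"class {cls!r} not present in ground truth")
            base += w * profiles[cls]
        for r in range(n_replicates):
            cid = f"{grp}.bulk{r + 1}"
            noise = np.exp(rng.normal(0.0, noise_sd, size=sc.n_genes))
            vals.append(base * noise)
            cols.append(cid)
            groups[cid] = grp
    return ExpressionMatrix(
        sc.gene_ids, tuple(cols), np.column_stack(vals), Scale.LINEAR_TPM, groups
    )


def default_bulk_frequencies(truth: GroundTruth) -> dict[str, dict[str, float]]:
    """Tissue mixtures for the three bulk groups of the validation assay.

    The bile-duct group contains the two duct-restricted classes; the
    liver groups do not.  A large non-immune 'tissue' share is spread over
    the liver-resident classes so signature genes stay detectable but
    minor on the bulk scale.
    """
    has = lambda c: c in truth.class_markers
    pbs = {"ProB": 0.8, "gdT": 0.2}
    liver4d = {"ProB": 0.2, "gdT": 0.05, "cILC2": 0.55}
    if has("L-ILC2"):
        liver4d["L-ILC2"] = 0.2
    else:
        liver4d["cILC2"] += 0.2
    ehbd = {"ProB": 0.05, "gdT": 0.05, "cILC2": 0.55, "BIM": 0.15, "BD-ILC1": 0.2}
    return {"PBS-Liver": pbs, "Liver-4d-IL33": liver4d, "EHBD-4d-IL33": ehbd}


def simulate_rl_table(
    truth: GroundTruth, n_decoys: int = 30, seed: int = 0, n_genes_hint: int = 0
) -> pd.DataFrame:
    """Ligand-receptor pair table: all planted pairs plus decoy pairs.

    Decoys are drawn among genes that are markers of no class, so they can
    never satisfy the unique-gene membership test; the table is what a
    curated protein-interaction compilation would look like restricted to
    the measured gene universe.
    """
    if not truth.planted_pairs and n_decoys == 0:
        return pd.DataFrame(columns=["ligand", "receptor"])
    rng = np.random.default_rng(seed)
    rows = [(lig, rec) for lig, rec, _, _ in truth.planted_pairs]
    marker_genes = sorted(truth.all_marker_genes)
    n_total = max(n_genes_hint, _max_gene_index(marker_genes))
    background = [
        f"g{i + 1:04d}"
        for i in range(n_total)
        if f"g{i + 1:04d}" not in truth.all_marker_genes
    ]
    seen = set(rows)
    while len(rows) < len(truth.planted_pairs) + n_decoys:
        lig, rec = rng.choice(background, size=2, replace=False)
        if (lig, rec) in seen or lig == rec:
            continue
        seen.add((lig, rec))
        rows.append((lig, rec))
    return pd.DataFrame(rows, columns=["ligand", "receptor"])


def _max_gene_index(genes: list[str]) -> int:
    idx = [int(g[1:]) for g in genes if g.startswith("g") and g[1:].isdigit()]
    return (max(idx) + 50) if idx else 100


def table1_expected() -> pd.DataFrame:
    """The published frequency table the study design reproduces.

    Rows are treatment groups, columns the six major classes plus the
    total percentage of cells accounted for; entries are integer percent.
    """
    data = {
        "ProB": [76, 56, 18, 3],
        "gdT": [7, 25, 3, 3],
        "cILC2": [0, 1, 53, 56],
        "BIM": [0, 1, 0, 11],
        "BD-ILC1": [0, 0, 0, 16],
        "L-ILC2": [0, 0, 16, 0],
        "Total %": [83, 83, 90, 89],
    }
    return pd.DataFrame(data, index=list(GROUPS))
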