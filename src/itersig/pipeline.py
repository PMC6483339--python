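"""End-to-end orchestration with a reproducibility manifest.

``run_all`` chains the stages in analysis order — simulate (optional) →
cluster → signatures → unique genes → interactions → tissue validation —
writing each stage's tables under one output directory plus a manifest
recording the configuration snapshot, input digests, seeds, per-stage
shapes and wall-clock.  All randomness flows from a single top-level seed,
expanded per stage, so a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .matrix import (
    read_tpm_matrix,
    write_matrix,
    write_group_metadata,
)
from .simulate import (
    GroundTruth,
    default_bulk_frequencies,
    default_spec,
    simulate_bulk_matrix,
    simulate_rl_table,
    simulate_single_cell_matrix,
    study_spec,
)
from .clustering import (
    ClusteringConfig,
    class_frequency_table,
    filter_minor_classes,
    iterate,
    tsne_embed,
)
from .ranking import signatures_for_all_classes, pool_training_set, write_signatures
from .unique import UniqueGeneFilter, unique_genes, write_unique_genes
from .interactions import (
    edge_summary,
    export_chord,
    load_rl_table,
    predict_interactions,
)
from .validation import ValidationConfig, validation_report


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: Mapping[str, Any] | str | Path, out_dir: str | Path) -> Path:
    """Run every enabled stage; returns the output directory.

    ``config`` is a mapping (or path to a YAML file) with optional keys
    ``simulate`` (design: default|study, plus generator overrides),
    ``input`` (matrix/metadata/rl_table paths when not simulating),
    ``cluster``, ``unique``, ``validation`` (per-stage parameter
    overrides), and ``seed``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "config": _jsonable(cfg),
        "stages": {},
        "inputs": {},
    }

    # -- stage: data ------------------------------------------------------
    t0 = time.perf_counter()
    truth: GroundTruth | None = None
    if "input" in cfg:
        paths = cfg["input"]
        for key in ("matrix", "metadata"):
            if key not in paths or not Path(paths[key]).exists():
                raise StageError(f"input: missing required file for {key!r}")
        if cfg.get("interactions", {}).get("enabled", True):
            if "rl_table" not in paths or not Path(paths["rl_table"]).exists():
                raise StageError("input: interactions enabled but rl_table missing")
        sc = read_tpm_matrix(paths["matrix"], paths["metadata"])
        rl_path = Path(paths["rl_table"]) if "rl_table" in paths else None
        bulk = (
            read_tpm_matrix(paths["bulk_matrix"], paths["bulk_metadata"])
            if "bulk_matrix" in paths
            else None
        )
        for k, p in paths.items():
            manifest["inputs"][k] = _digest(Path(p))
    else:
        sim = cfg.get("simulate", {})
        design = sim.get("design", "default")
        spec = {"default": default_spec, "study": study_spec}[design](seed=seed)
        overrides = {
            k: sim[k]
            for k in ("mu_marker", "mu_background", "sigma", "dropout")
            if k in sim
        }
        if overrides:
            from dataclasses import replace

            spec = replace(spec, **overrides)
        sc, truth = simulate_single_cell_matrix(spec)
        bulk = simulate_bulk_matrix(
            sc,
            truth,
            default_bulk_frequencies(truth),
            n_replicates=int(sim.get("n_replicates", 3)),
            noise_sd=float(sim.get("noise_sd", 0.2)),
            seed=seed + 1,
        )
        rl = simulate_rl_table(
            truth, n_decoys=int(sim.get("n_decoys", 30)), seed=seed + 2,
            n_genes_hint=spec.n_genes,
        )
        write_matrix(sc, out / "sc_matrix.tsv")
        write_group_metadata(sc.column_groups, out / "sc_metadata.tsv")
        write_matrix(bulk, out / "bulk_matrix.tsv")
        write_group_metadata(bulk.column_groups, out / "bulk_metadata.tsv")
        rl_path = out / "rl_pairs.tsv"
        rl.to_csv(rl_path, sep="\t", index=False)
        (out / "truth.json").write_text(
            json.dumps(
                {
                    "cell_to_class": dict(truth.cell_to_class),
                    "class_markers": {
                        c: list(g) for c, g in truth.class_markers.items()
                    },
                    "planted_pairs": [list(p) for p in truth.planted_pairs],
                },
                indent=1,
                sort_keys=True,
            )
        )
    manifest["stages"]["data"] = {
        "n_genes": sc.n_genes,
        "n_cells": sc.n_columns,
        "wall_s": round(time.perf_counter() - t0, 3),
    }

    # -- stage: cluster ---------------------------------------------------
    t0 = time.perf_counter()
    ccfg = ClusteringConfig(**cfg.get("cluster", {}))
    try:
        result = iterate(sc, ccfg)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"cluster: {e}") from e
    major, excluded = filter_minor_classes(result.final_labels, ccfg.min_class_size)
    labels_df = pd.DataFrame(
        {
            "cell_id": result.column_ids,
            "cluster": result.final_labels,
            "subcluster": result.final_sublabels,
            "final_class": major,
        }
    )
    labels_df.to_csv(out / "labels.tsv", sep="\t", index=False)
    design = sc.group_design()
    freq = class_frequency_table(major, design, result.column_ids)
    freq.to_csv(out / "class_frequencies.tsv", sep="\t")
    manifest["stages"]["cluster"] = {
        "n_iterations": result.n_iterations,
        "converged": result.converged,
        "n_terminal_classes": result.n_terminal_classes(),
        "n_major_classes": int(len(set(major[major != 0]))),
        "n_excluded_classes": len(excluded),
        "wall_s": round(time.perf_counter() - t0, 3),
    }

    # -- stage: signatures ------------------------------------------------
    t0 = time.perf_counter()
    keep = major != 0
    sc_major = sc.subset_columns([c for c, k in zip(result.column_ids, keep) if k])
    sigs = signatures_for_all_classes(
        sc_major, major[keep], None, ccfg.top_n_signature
    )
    write_signatures(sigs, out / "signatures.tsv")
    pooled = pool_training_set(sigs)
    emb = tsne_embed(sc_major, pooled, seed=seed + 3)
    emb["final_class"] = major[keep]
    emb.to_csv(out / "tsne.tsv", sep="\t", index=False)
    manifest["stages"]["signatures"] = {
        "n_classes": len(sigs.class_ids()),
        "n_pooled_genes": len(pooled),
        "wall_s": round(time.perf_counter() - t0, 3),
    }

    # -- stage: unique genes ----------------------------------------------
    t0 = time.perf_counter()
    ufilt = UniqueGeneFilter(
        **{k: v for k, v in cfg.get("unique", {}).items()},
        candidate_pool={c: sigs.genes(c) for c in sigs.class_ids()},
    )
    uniq = unique_genes(sc_major, major[keep], ufilt)
    write_unique_genes(uniq, out / "unique_genes.tsv")
    manifest["stages"]["unique"] = {
        "counts": {str(c): n for c, n in sorted(uniq.counts().items())},
        "wall_s": round(time.perf_counter() - t0, 3),
    }

    # -- stage: interactions ----------------------------------------------
    if rl_path is not None:
        t0 = time.perf_counter()
        table = load_rl_table(rl_path)
        edges = predict_interactions(uniq, table)
        export_chord(edges, uniq.class_ids(), out)
        edge_summary(edges, uniq.class_ids()).to_csv(
            out / "interactions_summary.tsv", sep="\t", index=False
        )
        manifest["stages"]["interactions"] = {
            "n_edges": len(edges),
            "wall_s": round(time.perf_counter() - t0, 3),
        }

    # -- stage: tissue validation -----------------------------------------
    if bulk is not None:
        t0 = time.perf_counter()
        vcfg = ValidationConfig(**cfg.get("validation", {}))
        focal = cfg.get("focal_group", "EHBD-4d-IL33")
        report = validation_report(bulk, uniq, focal, vcfg)
        report.summary.to_csv(out / "validation_summary.tsv", sep="\t", index=False)
        report.detail.to_csv(out / "validation_detail.tsv", sep="\t", index=False)
        manifest["stages"]["validation"] = {
            "focal_group": focal,
            "wall_s": round(time.perf_counter() - t0, 3),
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
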