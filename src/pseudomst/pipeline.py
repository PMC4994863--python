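"""End-to-end orchestration: load -> transform -> reduce -> cluster -> tree ->
order -> differential expression -> (optional) evaluation.

`run_pipeline` works on an in-memory matrix and returns all intermediate
objects; `run_end_to_end` wraps it with file I/O and writes every artifact plus a
manifest recording the resolved configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cell_clustering import CellClusterModel, cluster_cells
from .diffexpr import DEResult, detect_differential
from .evaluation import EvaluationReport, TimeLabels, pos_score
from .io import ExpressionMatrix, load_collection_time, load_expression, log_transform
from .preprocess import (
    ReducedMatrix,
    aggregate_gene_clusters,
    cluster_genes,
    filter_zero_genes,
    reduce_dimension,
)
from .tree_ordering import (
    ClusterTree,
    OrderedPath,
    build_mst,
    enumerate_paths,
    find_main_path,
    marker_means_per_cluster,
    order_cells_along_path,
    order_cells_by_pc1,
    orient_path,
    validate_manual_path,
)

_TRIM_RE = re.compile(r"^\s*(\S+?)\s*([<>])\s*([-+0-9.eE]+)\s*$")


def parse_trim_rule(rule: str) -> tuple[str, str, float]:
    """Parse a trimming criterion like ``"SPHK1 > 1"`` into (gene, op, thr)."""
    match = _TRIM_RE.match(rule)
    if not match:
        raise ValueError(f"cannot parse trimming rule: {rule!r} (expect 'GENE>VALUE')")
    gene, op, thr = match.groups()
    return gene, op, float(thr)


@dataclass
class RunConfig:
    """Complete, serializable record of one pipeline run."""

    input_path: str | None = None
    input_format: str | None = None
    time_path: str | None = None
    apply_log: bool = False
    pseudocount: float = 1.0
    log_base: float = 2.0
    gene_cluster_fraction: float = 0.05
    max_pcs_for_fit: int = 20
    k_override: int | None = None
    cluster_method: str = "gmm"
    n_clusters: int | None = None
    candidate_min: int = 2
    candidate_max: int = 9
    origin: int | None = None
    manual_path: list[int] | None = None
    marker_gene: str | None = None
    direction: str = "increasing"
    trim_rules: list[str] = field(default_factory=list)
    edf: int = 3
    fdr_threshold: float = 0.05
    use_raw_times: bool = False
    seed: int = 0
    outdir: str | None = None


@dataclass
class PipelineResult:
    matrix: ExpressionMatrix  # working (transformed, trimmed, filtered) matrix
    reduced: ReducedMatrix
    model: CellClusterModel
    tree: ClusterTree | None
    paths: list[OrderedPath]
    main_path: OrderedPath
    de: DEResult
    report: EvaluationReport | None
    config: RunConfig


def trim_cells(m: ExpressionMatrix, rules: list[str]) -> ExpressionMatrix:
    """Drop cells satisfying *every* active trimming criterion (conjunction)."""
    if not rules:
        return m
    mask = np.ones(m.n_cells, dtype=bool)
    for rule in rules:
        gene, op, thr = parse_trim_rule(rule)
        row = m.values[m.gene_index(gene)]
        mask &= (row > thr) if op == ">" else (row < thr)
    keep = np.flatnonzero(~mask)
    if keep.size == 0:
        raise ValueError("trimming rules removed every cell")
    return m.subset_cells(keep) if keep.size < m.n_cells else m


def run_pipeline(m: ExpressionMatrix, cfg: RunConfig) -> PipelineResult:
    """Execute the full ordering method on an in-memory matrix."""
    stage_seeds = np.random.SeedSequence(cfg.seed).generate_state(4) % (2**31)

    work = log_transform(m, cfg.pseudocount, cfg.log_base) if cfg.apply_log else m
    work = trim_cells(work, cfg.trim_rules)
    work = filter_zero_genes(work)

    gc = cluster_genes(work, fraction=cfg.gene_cluster_fraction)
    agg = aggregate_gene_clusters(work, gc)
    reduced = reduce_dimension(
        agg, max_pcs_for_fit=cfg.max_pcs_for_fit, k_override=cfg.k_override
    )
    model = cluster_cells(
        reduced,
        method=cfg.cluster_method,
        n_clusters=cfg.n_clusters,
        candidate_range=range(cfg.candidate_min, cfg.candidate_max + 1),
        seed=int(stage_seeds[0]),
    )

    if model.n_clusters < 2:
        main = order_cells_by_pc1(reduced)
        tree = None
        paths = [main]
    else:
        tree = build_mst(model)
        if cfg.manual_path is not None:
            main_seq = validate_manual_path(tree, cfg.manual_path)
        else:
            main_seq = find_main_path(tree)
            if cfg.marker_gene is not None:
                means = marker_means_per_cluster(work, model, cfg.marker_gene)
                main_seq = orient_path(main_seq, means, cfg.direction)
        origin = cfg.origin if cfg.origin is not None else main_seq[0]
        if origin == main_seq[-1]:
            main_seq = main_seq[::-1]
        paths = []
        main = None
        for seq in enumerate_paths(tree, origin):
            is_main = seq == main_seq
            op = order_cells_along_path(seq, model, reduced, is_main=is_main)
            paths.append(op)
            if is_main:
                main = op
        if main is None:  # origin not an end of the main path: order it explicitly
            main = order_cells_along_path(main_seq, model, reduced, is_main=True)
            paths.insert(0, main)

    de = detect_differential(work, main, edf=cfg.edf, threshold=cfg.fdr_threshold)

    report = None
    if work.collection_time is not None:
        labels = TimeLabels.from_matrix(work)
        report = EvaluationReport(
            pos=pos_score(main.cell_order, labels, use_raw_times=cfg.use_raw_times),
            configs={"n_cells": main.n_cells, "n_timepoints": labels.v},
        )
    return PipelineResult(
        matrix=work,
        reduced=reduced,
        model=model,
        tree=tree,
        paths=paths,
        main_path=main,
        de=de,
        report=report,
        config=cfg,
    )


def ordering_table(path: OrderedPath, model: CellClusterModel, path_id: str) -> pd.DataFrame:
    """Flat (cell_id, path_id, cluster, edge, projection, pseudotime) table."""
    label_of = dict(zip(model.cell_ids, model.labels))
    rows = []
    for i, cell in enumerate(path.cell_order):
        edge = path.edge_assignment[i] if path.edge_assignment else None
        rows.append(
            {
                "cell_id": cell,
                "path_id": path_id,
                "cluster": int(label_of.get(cell, 0)),
                "edge": "" if edge is None else f"{edge[0]}-{edge[1]}",
                "projection": float(path.projection_value[i])
                if path.projection_value is not None
                else float("nan"),
                "pseudotime": int(path.pseudotime[i]),
            }
        )
    return pd.DataFrame(rows)


def tree_to_json(tree: ClusterTree, main_path: list[int]) -> dict:
    return {
        "nodes": [
            {
                "id": int(c),
                "center": [float(x) for x in tree.nodes[c]],
                "n_cells": int(tree.cell_counts[c]),
            }
            for c in sorted(tree.nodes)
        ],
        "edges": [
            {"a": int(a), "b": int(b), "length": float(d)} for a, b, d in tree.edges
        ],
        "total_length": tree.total_length,
        "main_path": [int(c) for c in main_path],
    }


def run_end_to_end(cfg: RunConfig) -> PipelineResult:
    """File-based entry point: load inputs, run the pipeline, write artifacts."""
    if cfg.input_path is None:
        raise ValueError("RunConfig.input_path is required")
    m = load_expression(cfg.input_path, format=cfg.input_format)
    if cfg.time_path is not None:
        m = load_collection_time(cfg.time_path, m)
    result = run_pipeline(m, cfg)

    if cfg.outdir is not None:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        for i, p in enumerate(result.paths):
            pid = "main" if p.is_main else f"branch{i}"
            ordering_table(p, result.model, pid).to_csv(
                out / f"ordering_{pid}.tsv", sep="\t", index=False
            )
        if result.tree is not None:
            (out / "tree.json").write_text(
                json.dumps(
                    tree_to_json(result.tree, result.main_path.cluster_sequence),
                    indent=1,
                )
            )
        result.de.table.to_csv(out / "de.tsv", sep="\t")
        scree = result.reduced.scree
        pd.DataFrame(
            {
                "pc": np.arange(1, len(scree.v) + 1),
                "lambda": scree.v**2,
                "v": scree.v,
            }
        ).to_csv(out / "scree.tsv", sep="\t", index=False)
        if result.report is not None:
            (out / "report.json").write_text(json.dumps(result.report.to_dict(), indent=1))
        cfg_dict = asdict(cfg)
        manifest = {
            "package": "pseudomst",
            "version": __version__,
            "seed": cfg.seed,
            "config": cfg_dict,
            "config_hash": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True).encode()
            ).hexdigest(),
            "n_cells": result.matrix.n_cells,
            "n_genes": result.matrix.n_genes,
            "n_clusters": result.model.n_clusters,
            "chosen_k": result.reduced.k,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result
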