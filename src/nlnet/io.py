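"""Matrix I/O, single-cell preprocessing, and the end-to-end pipeline.

Expression matrices are plain TSV/CSV files with gene ids in the first
column and sample ids in the header row.  Preprocessing follows the usual
treatment of sparse count data: keep genes with non-zero values in more
than a given fraction of samples (default 2/3), then take log(x+1).

`run_pipeline` chains the whole method: filter -> transform -> DCOL matrix
-> permutation null -> p-values -> lfdr -> dynamic cutoff -> network ->
communities, and writes an edge list, a membership table and a JSON run
summary.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dcol import ExpressionMatrix, dcol_matrix
from .inference import dcol_pvalues, lfdr_matrix, permutation_null
from .network import (GeneNetwork, Partition, build_network,
                      communities_label_propagation, communities_multilevel,
                      select_cutoff)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "read_expression",
    "write_expression",
    "filter_genes",
    "log_transform",
    "run_pipeline",
]

logger = logging.getLogger("nlnet")


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the full reconstruction run.

    n_perm: permutation replicates for the null (500 by default).
    target_degree: requested average node degree; the lfdr cutoff that
        achieves it is clamped to [0.05, 0.2].
    min_community_size: communities below this are relabeled 0.
    symmetrization: 'union' (edge if either direction is significant) or
        'intersection' (both directions required).
    filter_fraction: keep genes with non-zero values in strictly more than
        this fraction of samples; None disables filtering.
    log_transform: apply log(x+1) before analysis.
    community_method: 'multilevel' or 'labelprop'.
    """

    input_path: str | Path | None = None
    out_dir: str | Path | None = None
    n_perm: int = 500
    seed: int = 0
    target_degree: float = 15.0
    min_community_size: int = 100
    symmetrization: str = "union"
    filter_fraction: float | None = 2.0 / 3.0
    log_transform: bool = False
    community_method: str = "multilevel"

    def __post_init__(self) -> None:
        if self.n_perm < 2:
            raise ValueError("n_perm must be >= 2")
        if self.target_degree <= 0:
            raise ValueError("target_degree must be positive")
        if self.min_community_size < 1:
            raise ValueError("min_community_size must be >= 1")
        if self.symmetrization not in ("union", "intersection"):
            raise ValueError("symmetrization must be 'union' or 'intersection'")
        if self.filter_fraction is not None and not 0 < self.filter_fraction < 1:
            raise ValueError("filter_fraction must be in (0, 1)")
        if self.community_method not in ("multilevel", "labelprop"):
            raise ValueError("community_method must be 'multilevel' or 'labelprop'")


@dataclass(frozen=True)
class PipelineResult:
    network: GeneNetwork
    partition: Partition
    summary: dict


def read_expression(path, fmt: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples matrix; first column gene ids, header sample ids.

    `fmt` is 'tsv' or 'csv'; inferred from the suffix when omitted.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValueError("fmt must be 'tsv' or 'csv'")
    sep = "\t" if fmt == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene id {dup[0]!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression values ({exc})") from None
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: missing or non-finite values")
    return ExpressionMatrix(values, tuple(df.index.astype(str)),
                            tuple(df.columns.astype(str)))


def write_expression(expr: ExpressionMatrix, path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "\t" if fmt == "tsv" else ","
    # %.17g round-trips float64 exactly
    expr.to_dataframe().to_csv(path, sep=sep, float_format="%.17g")


def filter_genes(expr: ExpressionMatrix, fraction: float = 2.0 / 3.0) -> ExpressionMatrix:
    """Keep genes whose non-zero count is strictly greater than
    fraction * n_samples (the usual sparse single-cell filter)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    nonzero = (expr.values != 0).sum(axis=1)
    keep = nonzero > fraction * expr.n_samples
    if keep.sum() < 2:
        raise ValueError(
            f"filtering at fraction {fraction:.3f} keeps {int(keep.sum())} gene(s); "
            "lower the fraction or check the input")
    ids = tuple(g for g, k in zip(expr.gene_ids, keep) if k)
    return ExpressionMatrix(expr.values[keep], ids, expr.sample_ids)


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log(x + 1); input must be nonnegative."""
    if (expr.values < 0).any():
        raise ValueError("log(x+1) transform requires nonnegative values")
    return ExpressionMatrix(np.log1p(expr.values), expr.gene_ids, expr.sample_ids)


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("%s done in %.2fs", name, t1 - t0)
    return t1


def run_pipeline(cfg: PipelineConfig,
                 expr: ExpressionMatrix | None = None) -> PipelineResult:
    """Full reconstruction: preprocessing, DCOL, inference, network,
    communities.  Pass `expr` directly or set cfg.input_path.

    When cfg.out_dir is set, writes ``edges.tsv`` (gene_a, gene_b,
    lfdr_min), ``membership.tsv`` (gene_id, community_id) and
    ``summary.json``.
    """
    t0 = time.perf_counter()
    if expr is None:
        if cfg.input_path is None:
            raise ValueError("either expr or cfg.input_path is required")
        expr = read_expression(cfg.input_path)
    t = _stage("load", t0)

    if cfg.filter_fraction is not None:
        expr = filter_genes(expr, cfg.filter_fraction)
    if cfg.log_transform:
        expr = log_transform(expr)
    t = _stage("preprocess", t)

    d = dcol_matrix(expr)
    t = _stage("dcol_matrix", t)
    null = permutation_null(expr, n_perm=cfg.n_perm, seed=cfg.seed)
    t = _stage("permutation_null", t)
    pv = dcol_pvalues(d, null)
    l = lfdr_matrix(pv)
    t = _stage("lfdr", t)

    cutoff = select_cutoff(l, cfg.target_degree, cfg.symmetrization)
    net = build_network(l, cutoff, cfg.symmetrization, cfg.target_degree)
    t = _stage("network", t)

    detect = (communities_multilevel if cfg.community_method == "multilevel"
              else communities_label_propagation)
    part = detect(net, seed=cfg.seed, min_size=cfg.min_community_size)
    t = _stage("communities", t)

    sizes = {str(k): v for k, v in sorted(part.sizes().items())}
    summary = {
        "n_genes": expr.n_genes,
        "n_samples": expr.n_samples,
        "n_perm": cfg.n_perm,
        "seed": cfg.seed,
        "cutoff_used": net.cutoff_used,
        "target_degree": cfg.target_degree,
        "average_degree": net.average_degree(),
        "n_edges": net.graph.number_of_edges(),
        "community_sizes": sizes,
        "community_method": cfg.community_method,
        "symmetrization": cfg.symmetrization,
        "total_seconds": time.perf_counter() - t0,
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in asdict(cfg).items()},
    }

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        edges = pd.DataFrame(net.edge_table(),
                             columns=["gene_a", "gene_b", "lfdr_min"])
        edges.to_csv(out / "edges.tsv", sep="\t", index=False)
        memb = pd.DataFrame(
            sorted(part.labels.items()), columns=["gene_id", "community_id"])
        memb.to_csv(out / "membership.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        logger.info("wrote %s", out)

    return PipelineResult(network=net, partition=part, summary=summary)
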