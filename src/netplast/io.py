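"""Readers/writers for the pipeline's plain-text interchange formats.

FC matrices are square CSVs with a node-label header; adjacency matrices get
the same plus an edge-list TSV; metrics are tidy CSVs; partitions are CSV +
JSON summary + a BrainNet-Viewer-style .node file; differential edges are a
flat CSV mirroring the usual report table (node pair, t, p, q, direction).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .community import Partition
from .connectivity import BinaryNetwork, FCMatrix
from .groupstats import DifferentialEdgeSet

__all__ = [
    "write_fc_matrix", "read_fc_matrix", "write_adjacency", "read_adjacency",
    "write_nodal_metrics", "write_global_metrics", "write_partition",
    "write_differential_edges",
]


def write_fc_matrix(fc: FCMatrix, path: str | Path) -> None:
    df = pd.DataFrame(fc.values, index=fc.node_labels, columns=fc.node_labels)
    df.to_csv(path, float_format="%.17g")


def read_fc_matrix(path: str | Path, space: str = "pearson",
                   subject_id: str = "subject") -> FCMatrix:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return FCMatrix(df.to_numpy(dtype=float), space=space, subject_id=subject_id,
                    node_labels=[str(c) for c in df.columns])


def write_adjacency(net: BinaryNetwork, path: str | Path,
                    edge_list_path: str | Path | None = None) -> None:
    df = pd.DataFrame(net.values, index=net.node_labels, columns=net.node_labels)
    df.to_csv(path)
    if edge_list_path is not None:
        edges = net.edge_list()
        pd.DataFrame({
            "node_i": [net.node_labels[i] for i in edges[:, 0]],
            "node_j": [net.node_labels[j] for j in edges[:, 1]],
        }).to_csv(edge_list_path, sep="\t", index=False)


def read_adjacency(path: str | Path, threshold: float = float("nan")) -> BinaryNetwork:
    df = pd.read_csv(path, index_col=0)
    return BinaryNetwork(df.to_numpy(dtype=int), threshold_used=threshold,
                         node_labels=[str(c) for c in df.columns])


def write_nodal_metrics(rows: pd.DataFrame, path: str | Path) -> None:
    """Tidy nodal metrics: subject_id, threshold, node_label, metric, value."""
    cols = ["subject_id", "threshold", "node_label", "metric", "value"]
    rows.loc[:, cols].to_csv(path, index=False, float_format="%.17g")


def write_global_metrics(rows: pd.DataFrame, path: str | Path) -> None:
    """Tidy global metrics: subject_id, threshold, metric, value."""
    cols = ["subject_id", "threshold", "metric", "value"]
    rows.loc[:, cols].to_csv(path, index=False, float_format="%.17g")


def write_partition(partition: Partition, node_labels: Sequence[str],
                    out_prefix: str | Path, degrees: np.ndarray | None = None,
                    coordinates: np.ndarray | None = None) -> None:
    """Write <prefix>.csv (node_label, module_id), <prefix>.json (Q, sizes) and
    a BrainNet-Viewer-style <prefix>.node file (x y z color size label)."""
    prefix = Path(out_prefix)
    pd.DataFrame({"node_label": list(node_labels),
                  "module_id": partition.assignment}).to_csv(
        prefix.with_suffix(".csv"), index=False)
    summary = {"q": partition.q, "n_modules": partition.n_modules,
               "module_sizes": {str(k): v for k, v in partition.module_sizes().items()}}
    prefix.with_suffix(".json").write_text(json.dumps(summary, indent=1))
    n = len(node_labels)
    coords = coordinates if coordinates is not None else np.zeros((n, 3))
    size = degrees if degrees is not None else np.ones(n)
    with open(prefix.with_suffix(".node"), "w") as fh:
        for i in range(n):
            fh.write(f"{coords[i, 0]:g}\t{coords[i, 1]:g}\t{coords[i, 2]:g}\t"
                     f"{int(partition.assignment[i])}\t{float(size[i]):g}\t"
                     f"{node_labels[i]}\n")


def write_differential_edges(diff: DifferentialEdgeSet, path: str | Path) -> None:
    diff.edges.to_csv(path, index=False, float_format="%.6g")
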