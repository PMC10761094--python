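"""kNN feature graphs over similarity matrices.

Each drug (disease) is linked to itself plus its k most similar peers
(the extended neighborhood), the resulting directed adjacency is
symmetrized by union, and the graph is summarized by its symmetric
normalized propagation operator D^{-1/2} A D^{-1/2}.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset_io import SimilarityMatrix

__all__ = ["KnnGraph", "build_knn_adjacency", "normalize_adjacency",
           "build_knn_graph", "write_edge_list"]


@dataclass
class KnnGraph:
    adjacency: np.ndarray            # binary, symmetric, unit diagonal
    normalized_operator: np.ndarray  # D^{-1/2} A D^{-1/2}
    k: int


def build_knn_adjacency(sim: SimilarityMatrix | np.ndarray, k: int) -> np.ndarray:
    """Binary adjacency of the extended-kNN graph.

    Row i selects node i itself plus the k columns with the largest
    similarity to i (self excluded from the k; ties broken by ascending
    column index), then the matrix is symmetrized as A <- 1[A + A^T > 0]
    so the normalized operator stays symmetric.
    """
    values = sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim, float)
    n = values.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must satisfy 1 <= k <= n-1 = {n - 1}, got {k}")
    adj = np.zeros((n, n), dtype=np.int8)
    idx = np.arange(n)
    for i in range(n):
        # descending similarity, ties by ascending index (lexsort: last key primary)
        order = np.lexsort((idx, -values[i]))
        order = order[order != i]
        adj[i, order[:k]] = 1
        adj[i, i] = 1
    return ((adj + adj.T) > 0).astype(np.int8)


def normalize_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric normalization D^{-1/2} A D^{-1/2} of a symmetric adjacency."""
    adjacency = np.asarray(adjacency, dtype=float)
    if not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    degrees = adjacency.sum(axis=1)
    if (degrees == 0).any():
        raise ValueError("zero-degree node; self-loops should make this unreachable")
    inv_sqrt = 1.0 / np.sqrt(degrees)
    return adjacency * np.outer(inv_sqrt, inv_sqrt)


def build_knn_graph(sim: SimilarityMatrix | np.ndarray, k: int) -> KnnGraph:
    adjacency = build_knn_adjacency(sim, k)
    return KnnGraph(adjacency=adjacency,
                    normalized_operator=normalize_adjacency(adjacency), k=k)


def write_edge_list(graph: KnnGraph, path) -> None:
    """Dump the adjacency as a two-column TSV edge list (i <= j)."""
    rows = ["source\ttarget"]
    ii, jj = np.nonzero(np.triu(graph.adjacency))
    rows += [f"{i}\t{j}" for i, j in zip(ii, jj)]
    Path(path).write_text("\n".join(rows) + "\n")
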