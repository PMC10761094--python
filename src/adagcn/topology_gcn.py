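"""Topology-space convolution over the bipartite association graph.

Known (type-1) and unknown (type-0) drug-disease pairs form two edge
channels.  A message from disease j to drug i on channel t is
``(1 / c_ij) W_t x_j`` with the symmetric normalization
``c_ij = sqrt(|N_t(r_i)| * |N_t(d_j)|)`` over type-specific degrees;
incoming messages are summed over both channels and passed through
tanh.  Node inputs are one-hot identity codes, realized as learnable
per-type embedding tables (the columns of W_t applied to one-hot
vectors).  After the message-passing rounds a single dense weight,
shared between drugs and diseases, produces the topology embeddings.

The type-0 channel connects almost every pair, so its messages are
computed by a complement identity (all-pairs column sums minus the
type-1 contributions) instead of materializing the dense complement
adjacency; the test suite checks this shortcut against an explicit
double loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, glorot_uniform
from .dataset_io import AssociationMatrix

__all__ = ["TopologyGraph", "TopologyGcnParams", "build_topology_graph",
           "init_topology_gcn_params", "message_passing_forward", "dense_transform"]


def _inv_sqrt(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    out[pos] = 1.0 / np.sqrt(x[pos])
    return out


@dataclass
class TopologyGraph:
    """Edge channels and degree data of the bipartite pair graph."""

    a1: np.ndarray                    # (n, m) binary training positives
    drug_degree: dict[int, np.ndarray]
    disease_degree: dict[int, np.ndarray]
    norm1: np.ndarray                 # (n, m) type-1 adjacency / c_ij
    _dr0: np.ndarray = field(repr=False, default=None)
    _dd0: np.ndarray = field(repr=False, default=None)

    @property
    def n_drugs(self) -> int:
        return self.a1.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.a1.shape[1]

    def edge_counts(self) -> dict[int, int]:
        n1 = int(self.a1.sum())
        return {1: n1, 0: self.a1.size - n1}


def build_topology_graph(assoc: AssociationMatrix,
                         train_mask: np.ndarray | None = None) -> TopologyGraph:
    """Split all pairs into channels given the training-visible mask.

    Type-1 edges are the training-visible positives; type-0 edges are
    every other pair, including held-out test pairs, which are simply
    unknown at training time.
    """
    y = assoc.values if isinstance(assoc, AssociationMatrix) else np.asarray(assoc)
    if train_mask is None:
        train_mask = np.ones_like(y, dtype=bool)
    train_mask = np.asarray(train_mask, dtype=bool)
    if train_mask.shape != y.shape:
        raise ValueError("train_mask shape must match the association matrix")
    a1 = ((y == 1) & train_mask).astype(np.int8)
    if a1.sum() == 0:
        raise ValueError("degenerate topology graph: no training-visible positives")
    n, m = a1.shape
    dr = {1: a1.sum(axis=1).astype(float), 0: (m - a1.sum(axis=1)).astype(float)}
    dd = {1: a1.sum(axis=0).astype(float), 0: (n - a1.sum(axis=0)).astype(float)}
    norm1 = a1 * np.outer(_inv_sqrt(dr[1]), _inv_sqrt(dd[1]))
    return TopologyGraph(a1=a1, drug_degree=dr, disease_degree=dd, norm1=norm1,
                         _dr0=_inv_sqrt(dr[0]), _dd0=_inv_sqrt(dd[0]))


@dataclass
class TopologyGcnParams:
    """Learnable pieces of the topology convolution."""

    drug_codes: dict[int, Tensor]      # per-type (n, h) identity-code tables
    disease_codes: dict[int, Tensor]   # per-type (m, h)
    round_weights: list[dict[int, Tensor]]  # (h, h) per type, rounds >= 2
    dense_weight: Tensor               # (h, h), shared drugs/diseases
    dropout_rate: float = 0.0

    def parameters(self) -> list[Tensor]:
        out = [*self.drug_codes.values(), *self.disease_codes.values()]
        for rw in self.round_weights:
            out.extend(rw.values())
        out.append(self.dense_weight)
        return out


def init_topology_gcn_params(n_drugs: int, n_diseases: int, hidden: int,
                             n_rounds: int, rng: np.random.Generator,
                             dropout_rate: float = 0.0) -> TopologyGcnParams:
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    drug_codes = {t: Tensor(glorot_uniform(rng, (n_drugs, hidden)), requires_grad=True,
                            name=f"topo_drug_codes_t{t}") for t in (1, 0)}
    disease_codes = {t: Tensor(glorot_uniform(rng, (n_diseases, hidden)), requires_grad=True,
                               name=f"topo_dis_codes_t{t}") for t in (1, 0)}
    round_weights = [
        {t: Tensor(glorot_uniform(rng, (hidden, hidden)), requires_grad=True,
                   name=f"topo_round{r + 2}_t{t}") for t in (1, 0)}
        for r in range(n_rounds - 1)
    ]
    dense = Tensor(glorot_uniform(rng, (hidden, hidden)), requires_grad=True,
                   name="topo_dense_w")
    return TopologyGcnParams(drug_codes=drug_codes, disease_codes=disease_codes,
                             round_weights=round_weights, dense_weight=dense,
                             dropout_rate=dropout_rate)


def _type0_aggregate(a1: np.ndarray, row_inv_sqrt: np.ndarray,
                     col_inv_sqrt: np.ndarray, features: Tensor) -> Tensor:
    """Complement identity for the dense type-0 channel.

    Aggregates ``sum_j (1/c_ij) x_j`` over the type-0 neighbors of each
    row node, using (all-ones minus A1) = J - A1 without forming it:
    ``D_r0^{-1/2} [ 1 (1^T X_s) - A1 X_s ]`` with
    ``X_s = D_c0^{-1/2} X``.
    """
    scaled = Tensor(col_inv_sqrt[:, None]) * features
    total = Tensor(np.ones((a1.shape[0], 1))) @ scaled.sum(axis=0, keepdims=True)
    type1_part = Tensor(np.asarray(a1, dtype=float)) @ scaled
    return Tensor(row_inv_sqrt[:, None]) * (total - type1_part)


def _dropout(z: Tensor, rate: float, training: bool,
             rng: np.random.Generator | None) -> Tensor:
    if not training or rate <= 0.0:
        return z
    mask = (rng.random(z.shape) >= rate) / (1.0 - rate)
    return z * Tensor(mask)


def message_passing_forward(graph: TopologyGraph, params: TopologyGcnParams, *,
                            training: bool = False,
                            rng: np.random.Generator | None = None
                            ) -> tuple[Tensor, Tensor]:
    """Run all message-passing rounds; returns drug and disease hiddens."""
    norm1 = Tensor(graph.norm1)
    norm1_t = Tensor(graph.norm1.T)

    # round 1: one-hot inputs, i.e. the code tables themselves
    # (layer-input dropout applies here exactly as in later rounds)
    drugs_in = {t: _dropout(params.disease_codes[t], params.dropout_rate,
                            training, rng) for t in (1, 0)}
    dis_in = {t: _dropout(params.drug_codes[t], params.dropout_rate,
                          training, rng) for t in (1, 0)}
    h_r = (norm1 @ drugs_in[1]
           + _type0_aggregate(graph.a1, graph._dr0, graph._dd0, drugs_in[0])).tanh()
    h_d = (norm1_t @ dis_in[1]
           + _type0_aggregate(graph.a1.T, graph._dd0, graph._dr0, dis_in[0])).tanh()

    for weights in params.round_weights:
        h_r_in = _dropout(h_r, params.dropout_rate, training, rng)
        h_d_in = _dropout(h_d, params.dropout_rate, training, rng)
        h_r_new = (norm1 @ (h_d_in @ weights[1])
                   + _type0_aggregate(graph.a1, graph._dr0, graph._dd0,
                                      h_d_in @ weights[0])).tanh()
        h_d_new = (norm1_t @ (h_r_in @ weights[1])
                   + _type0_aggregate(graph.a1.T, graph._dd0, graph._dr0,
                                      h_r_in @ weights[0])).tanh()
        h_r, h_d = h_r_new, h_d_new
    return h_r, h_d


def dense_transform(hidden: Tensor, params: TopologyGcnParams) -> Tensor:
    """Shared linear output layer mapping hiddens to topology embeddings."""
    if hidden.shape[-1] != params.dense_weight.shape[0]:
        raise ValueError("hidden dimension does not match the dense weight")
    return hidden @ params.dense_weight
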