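"""Feature-space graph convolution over the kNN similarity graphs.

A standard GCN layer stack: Z^(l) = ReLU(A_hat Z^(l-1) W^(l)) with
A_hat the symmetric-normalized kNN operator and Z^(0) the similarity
matrix itself, so layer 1 maps from dimension n (all similarity scores
of a node) to the hidden size.  Dropout is applied to each layer's
input activations during training only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, astensor, glorot_uniform
from .graph_construction import KnnGraph

__all__ = ["FeatureGcnParams", "init_feature_gcn_params", "feature_gcn_forward"]


@dataclass
class FeatureGcnParams:
    layer_weights: list[Tensor]
    dropout_rate: float = 0.0

    def parameters(self) -> list[Tensor]:
        return list(self.layer_weights)


def init_feature_gcn_params(input_dim: int, hidden: int, n_layers: int,
                            rng: np.random.Generator,
                            dropout_rate: float = 0.0) -> FeatureGcnParams:
    dims = [input_dim] + [hidden] * n_layers
    weights = [Tensor(glorot_uniform(rng, (dims[l], dims[l + 1])), requires_grad=True,
                      name=f"feature_w{l + 1}")
               for l in range(n_layers)]
    return FeatureGcnParams(layer_weights=weights, dropout_rate=dropout_rate)


def _dropout(z: Tensor, rate: float, training: bool,
             rng: np.random.Generator | None) -> Tensor:
    if not training or rate <= 0.0:
        return z
    if rng is None:
        raise ValueError("training-mode dropout needs an rng")
    mask = (rng.random(z.shape) >= rate) / (1.0 - rate)
    return z * Tensor(mask)


def feature_gcn_forward(graph: KnnGraph, params: FeatureGcnParams,
                        features: np.ndarray | Tensor, *, training: bool = False,
                        rng: np.random.Generator | None = None) -> Tensor:
    """Run the layer stack; returns the final embedding (n x hidden)."""
    operator = Tensor(graph.normalized_operator)
    z = astensor(features)
    if z.shape[0] != graph.normalized_operator.shape[0]:
        raise ValueError(
            f"features have {z.shape[0]} rows but the graph has "
            f"{graph.normalized_operator.shape[0]} nodes")
    for weight in params.layer_weights:
        if z.shape[1] != weight.shape[0]:
            raise ValueError(
                f"layer expects input dim {weight.shape[0]}, got {z.shape[1]}")
        z = _dropout(z, params.dropout_rate, training, rng)
        z = (operator @ z @ weight).relu()
    return z
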