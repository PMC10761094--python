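"""Per-node attention over the feature and topology embeddings.

For each node the two space embeddings are scored with
``omega = q^T tanh(W' z^T + b')`` (separate W', b' per space, one
shared attention vector q per entity kind), the two scores pass
through a pairwise softmax, and the fused embedding is the resulting
convex combination of the two space embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, astensor, glorot_uniform

__all__ = ["AttentionParams", "AttentionWeights", "init_attention_params",
           "attention_scores", "softmax_pair", "fuse_embeddings", "attend_and_fuse"]

SPACES = ("feature", "topology")


@dataclass
class AttentionParams:
    """Attention parameters for one entity kind (drugs or diseases)."""

    transform: dict[str, tuple[Tensor, Tensor]]  # space -> (W' (h, h'), b' (1, h'))
    query: Tensor                                # shared q, (h', 1)

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for w, b in self.transform.values():
            out += [w, b]
        out.append(self.query)
        return out


@dataclass
class AttentionWeights:
    """Per-node convex weights over the two spaces (rows sum to 1)."""

    alpha_feature: np.ndarray
    alpha_topology: np.ndarray


def init_attention_params(hidden: int, attention_hidden: int,
                          rng: np.random.Generator) -> AttentionParams:
    transform = {
        space: (Tensor(glorot_uniform(rng, (hidden, attention_hidden)),
                       requires_grad=True, name=f"att_w_{space}"),
                Tensor(np.zeros((1, attention_hidden)), requires_grad=True,
                       name=f"att_b_{space}"))
        for space in SPACES
    }
    query = Tensor(glorot_uniform(rng, (attention_hidden, 1)), requires_grad=True,
                   name="att_q")
    return AttentionParams(transform=transform, query=query)


def attention_scores(z: Tensor | np.ndarray, params: AttentionParams,
                     space: str) -> Tensor:
    """Score every node's embedding in the given space; returns (n, 1)."""
    if space not in SPACES:
        raise ValueError(f"space must be one of {SPACES}, got {space!r}")
    z = astensor(z)
    w, b = params.transform[space]
    if z.shape[1] != w.shape[0]:
        raise ValueError(f"embedding dim {z.shape[1]} != transform input {w.shape[0]}")
    return (z @ w + b).tanh() @ params.query


def softmax_pair(omega_f: Tensor | np.ndarray,
                 omega_t: Tensor | np.ndarray) -> tuple[Tensor, Tensor]:
    """Two-way softmax per node, computed stably as sigmoid(omega_f - omega_t).

    (Subtracting the per-node max before exponentiation and the
    sigmoid-of-difference form are the same function; the latter never
    overflows.)
    """
    omega_f, omega_t = astensor(omega_f), astensor(omega_t)
    if omega_f.shape != omega_t.shape:
        raise ValueError("score vectors must have equal shapes")
    alpha_f = (omega_f - omega_t).sigmoid()
    return alpha_f, 1.0 - alpha_f


def fuse_embeddings(alpha_f: Tensor | np.ndarray, alpha_t: Tensor | np.ndarray,
                    z_f: Tensor | np.ndarray, z_t: Tensor | np.ndarray) -> Tensor:
    """Row-wise convex combination alpha_f[i] * z_f[i] + alpha_t[i] * z_t[i]."""
    alpha_f, alpha_t = astensor(alpha_f), astensor(alpha_t)
    z_f, z_t = astensor(z_f), astensor(z_t)
    if z_f.shape != z_t.shape:
        raise ValueError("space embeddings must have equal shapes")
    if alpha_f.shape[0] != z_f.shape[0]:
        raise ValueError("weight vector length must match the node count")
    return alpha_f * z_f + alpha_t * z_t


def attend_and_fuse(z_f: Tensor, z_t: Tensor, params: AttentionParams
                    ) -> tuple[Tensor, Tensor, Tensor]:
    """Full attention block: returns (fused Z, alpha_f, alpha_t)."""
    omega_f = attention_scores(z_f, params, "feature")
    omega_t = attention_scores(z_t, params, "topology")
    alpha_f, alpha_t = softmax_pair(omega_f, omega_t)
    return fuse_embeddings(alpha_f, alpha_t, z_f, z_t), alpha_f, alpha_t
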