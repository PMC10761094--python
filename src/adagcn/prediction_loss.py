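"""Pair scoring MLP and the three-term training objective.

A drug-disease pair is scored by a three-layer MLP (two ReLU hidden
layers, scalar sigmoid output) on the concatenation of the fused drug
and disease embeddings.  The objective is

    L = L_bce + lambda * (L_Cr + L_Cd)

where L_bce is the binary cross-entropy summed over all training
pairs (positives plus training unknowns as negatives, no negative
sampling) and L_Cr / L_Cd are consistency constraints: the squared
Frobenius distance between the cosine-similarity matrices of the
feature-space and topology-space embeddings of drugs / diseases.

Since the first MLP layer acts on a concatenation, its weight splits
into a drug block and a disease block; scoring all n*m pairs then
costs two small products plus a broadcast add instead of an explicit
(n*m) x 2h design matrix.  The layer-by-layer equivalence is part of
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor, astensor, glorot_uniform

__all__ = ["MlpParams", "LossBreakdown", "init_mlp_params", "predict_logits",
           "predict_pairs", "bce_loss", "bce_loss_from_logits",
           "embedding_similarity", "consistency_loss", "total_loss",
           "ranked_pair_table"]

LOG_CLAMP = 1e-12


@dataclass
class MlpParams:
    """Three-layer MLP; w1_drug / w1_disease are the two blocks of the
    first-layer weight over the concatenated pair embedding."""

    w1_drug: Tensor     # (h, h1)
    w1_disease: Tensor  # (h, h1)
    b1: Tensor          # (1, h1)
    w2: Tensor          # (h1, h2)
    b2: Tensor          # (1, h2)
    w3: Tensor          # (h2, 1)
    b3: Tensor          # (1, 1)
    dropout_rate: float = 0.0

    def parameters(self) -> list[Tensor]:
        return [self.w1_drug, self.w1_disease, self.b1,
                self.w2, self.b2, self.w3, self.b3]


def init_mlp_params(hidden: int, mlp_hidden: tuple[int, int],
                    rng: np.random.Generator,
                    dropout_rate: float = 0.0) -> MlpParams:
    h1, h2 = mlp_hidden
    w1 = glorot_uniform(rng, (2 * hidden, h1))
    return MlpParams(
        w1_drug=Tensor(w1[:hidden], requires_grad=True, name="mlp_w1_drug"),
        w1_disease=Tensor(w1[hidden:], requires_grad=True, name="mlp_w1_disease"),
        b1=Tensor(np.zeros((1, h1)), requires_grad=True, name="mlp_b1"),
        w2=Tensor(glorot_uniform(rng, (h1, h2)), requires_grad=True, name="mlp_w2"),
        b2=Tensor(np.zeros((1, h2)), requires_grad=True, name="mlp_b2"),
        w3=Tensor(glorot_uniform(rng, (h2, 1)), requires_grad=True, name="mlp_w3"),
        b3=Tensor(np.zeros((1, 1)), requires_grad=True, name="mlp_b3"),
        dropout_rate=dropout_rate,
    )


def _dropout(z: Tensor, rate: float, training: bool,
             rng: np.random.Generator | None) -> Tensor:
    if not training or rate <= 0.0:
        return z
    mask = (rng.random(z.shape) >= rate) / (1.0 - rate)
    return z * Tensor(mask)


def predict_logits(z_drug: Tensor | np.ndarray, z_disease: Tensor | np.ndarray,
                   params: MlpParams, *, training: bool = False,
                   rng: np.random.Generator | None = None) -> Tensor:
    """Pre-sigmoid scores for every drug-disease pair; returns (n, m)."""
    z_drug, z_disease = astensor(z_drug), astensor(z_disease)
    if z_drug.shape[1] != params.w1_drug.shape[0]:
        raise ValueError("drug embedding dim does not match the MLP input")
    if z_disease.shape[1] != params.w1_disease.shape[0]:
        raise ValueError("disease embedding dim does not match the MLP input")
    n, m = z_drug.shape[0], z_disease.shape[0]
    h1 = params.b1.shape[1]
    pre1 = ((z_drug @ params.w1_drug).reshape(n, 1, h1)
            + (z_disease @ params.w1_disease).reshape(1, m, h1)
            + params.b1.reshape(1, 1, h1))
    hid1 = _dropout(pre1.relu(), params.dropout_rate, training, rng)
    hid2 = _dropout((hid1 @ params.w2 + params.b2).relu(),
                    params.dropout_rate, training, rng)
    return (hid2 @ params.w3 + params.b3).reshape(n, m)


def predict_pairs(z_drug, z_disease, params: MlpParams,
                  pairs: np.ndarray | None = None) -> np.ndarray:
    """Sigmoid scores; the full (n, m) matrix, or a vector for `pairs`
    given as an integer array of (drug, disease) index rows."""
    logits = predict_logits(z_drug, z_disease, params).sigmoid().data
    if pairs is None:
        return logits
    pairs = np.asarray(pairs)
    return logits[pairs[:, 0], pairs[:, 1]]


def bce_loss(scores, labels, pairs: np.ndarray | None = None) -> float:
    """Binary cross-entropy summed over the given pairs (clamped logs)."""
    scores = np.asarray(scores.data if isinstance(scores, Tensor) else scores, float)
    labels = np.asarray(labels.data if isinstance(labels, Tensor) else labels, float)
    if pairs is not None:
        pairs = np.asarray(pairs)
        if pairs.size == 0:
            raise ValueError("empty pair set")
        scores = scores[pairs[:, 0], pairs[:, 1]]
        labels = labels[pairs[:, 0], pairs[:, 1]]
    if scores.size == 0:
        raise ValueError("empty pair set")
    s = np.clip(scores, LOG_CLAMP, 1.0 - LOG_CLAMP)
    return float(-(labels * np.log(s) + (1.0 - labels) * np.log(1.0 - s)).sum())


def bce_loss_from_logits(logits: Tensor, labels: np.ndarray,
                         mask: np.ndarray | None = None) -> Tensor:
    """Differentiable BCE sum via softplus on logits (same quantity as
    `bce_loss` away from the clamp), restricted to `mask` when given."""
    labels = np.asarray(labels, float)
    y = Tensor(labels)
    per_pair = y * (-logits).softplus() + (1.0 - y) * logits.softplus()
    if mask is not None:
        mask = np.asarray(mask, float)
        if mask.sum() == 0:
            raise ValueError("empty pair set")
        per_pair = per_pair * Tensor(mask)
    return per_pair.sum()


def embedding_similarity(z: Tensor | np.ndarray, eps: float = 0.0) -> Tensor:
    """Cosine-similarity matrix of the rows (L2-normalize, then Z Z^T).

    An exactly zero row makes the cosine undefined and raises unless
    ``eps > 0``, in which case the row normalizes to zero similarity
    (used in the training loss, where ReLU outputs can have dead rows;
    such rows carry no gradient through the ReLU in any case).
    """
    z = astensor(z)
    norms = np.sqrt((z.data ** 2).sum(axis=1))
    if eps <= 0.0 and (norms == 0).any():
        raise ValueError("zero row: cosine similarity undefined")
    sq = (z * z).sum(axis=1, keepdims=True) + eps
    z_norm = z / sq.sqrt()
    return z_norm @ z_norm.T


def consistency_loss(s_f: Tensor | np.ndarray, s_t: Tensor | np.ndarray) -> Tensor:
    """Squared Frobenius norm of S_F - S_T."""
    s_f, s_t = astensor(s_f), astensor(s_t)
    if s_f.shape != s_t.shape:
        raise ValueError("similarity matrices must have equal shapes")
    diff = s_f - s_t
    return (diff * diff).sum()


@dataclass(frozen=True)
class LossBreakdown:
    """The three objective terms and their weighted total."""

    l_bce: float
    l_cr: float
    l_cd: float
    trade_off: float

    @property
    def l_total(self) -> float:
        return self.l_bce + self.trade_off * self.l_cr + self.trade_off * self.l_cd


def total_loss(l_bce, l_cr, l_cd, trade_off: float) -> LossBreakdown:
    """Combine the terms; `trade_off` (lambda) = 0 drops the consistency
    constraint entirely (the w/o-l ablation)."""
    if trade_off < 0:
        raise ValueError("trade_off must be nonnegative")
    return LossBreakdown(l_bce=float(l_bce), l_cr=float(l_cr), l_cd=float(l_cd),
                         trade_off=float(trade_off))


def ranked_pair_table(scores: np.ndarray, drug_ids: list[str],
                      disease_ids: list[str],
                      known: np.ndarray | None = None) -> pd.DataFrame:
    """All pairs sorted by score, for case-study style inspection.

    With `known` given, known positives are flagged so novel candidates
    can be read off the top of the list.
    """
    n, m = scores.shape
    frame = pd.DataFrame({
        "drug": np.repeat(drug_ids, m),
        "disease": np.tile(disease_ids, n),
        "score": scores.ravel(),
    })
    if known is not None:
        frame["known"] = np.asarray(known).astype(bool).ravel()
    return frame.sort_values("score", ascending=False, ignore_index=True)
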