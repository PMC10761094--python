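"""End-to-end training and the evaluation protocols.

Covers the full model assembly (feature GCN + topology GCN + attention
fusion + MLP head), full-batch Adam training, repeated k-fold
cross-validation over all drug-disease pairs, the new-drug cold-start
protocol, hyperparameter sweeps over the neighbor count K and the
consistency trade-off lambda, the four ablation switches and the
attention-distribution report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import average_precision_score, roc_auc_score

from .attention_fusion import (AttentionParams, attend_and_fuse, fuse_embeddings,
                               init_attention_params)
from .autodiff import Adam, Tensor
from .dataset_io import DrugDiseaseDataset
from .feature_gcn import FeatureGcnParams, feature_gcn_forward, init_feature_gcn_params
from .graph_construction import KnnGraph, build_knn_graph
from .prediction_loss import (LossBreakdown, MlpParams, bce_loss_from_logits,
                              consistency_loss, embedding_similarity,
                              init_mlp_params, predict_logits, total_loss)
from .topology_gcn import (TopologyGcnParams, TopologyGraph, build_topology_graph,
                           dense_transform, init_topology_gcn_params,
                           message_passing_forward)

__all__ = ["ModelConfig", "FoldSplit", "EvalResult", "CVResult", "AdaGcnModel",
           "TrainingError", "MetricError", "train_model", "evaluate",
           "make_fold_split", "cross_validate", "new_drug_evaluation", "sweep",
           "attention_report"]

ABLATIONS = ("none", "w/o-l", "w/o-a", "w/o-f", "w/o-t")


class TrainingError(RuntimeError):
    """Raised when optimization produces a non-finite loss."""


class MetricError(ValueError):
    """Raised when a metric is undefined (e.g. single-class test set)."""


@dataclass(frozen=True)
class ModelConfig:
    """All hyperparameters of one training run.

    Defaults follow the published tuning on the drug-repositioning
    benchmarks: 4000 epochs, learning rate 0.01, dropout 0.3, K = 4
    feature-graph neighbors and consistency trade-off lambda = 0.1
    (0.01 suits very sparse LRSSL-like data).
    """

    epochs: int = 4000
    learning_rate: float = 0.01
    dropout: float = 0.3
    k_neighbors: int = 4
    trade_off: float = 0.1
    hidden: int = 64
    attention_hidden: int = 32
    feature_layers: int = 2
    topology_rounds: int = 2
    mlp_hidden: tuple[int, int] | None = None
    ablation: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0 or self.epochs < 1 or self.k_neighbors < 1:
            raise ValueError("invalid optimization hyperparameters")
        if self.trade_off < 0:
            raise ValueError("trade_off must be nonnegative")

    @property
    def mlp_sizes(self) -> tuple[int, int]:
        return self.mlp_hidden if self.mlp_hidden else (self.hidden, self.hidden // 2)

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)

    # YAML round-trip for config files
    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "mlp_hidden" in raw and raw["mlp_hidden"] is not None:
            raw["mlp_hidden"] = tuple(raw["mlp_hidden"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        if raw["mlp_hidden"] is not None:
            raw["mlp_hidden"] = list(raw["mlp_hidden"])
        Path(path).write_text(yaml.safe_dump(raw))


@dataclass(frozen=True)
class FoldSplit:
    """Assignment of every (drug, disease) pair to one of n_folds folds."""

    assignments: np.ndarray  # flat (n*m,) fold index per pair
    shape: tuple[int, int]
    n_folds: int
    repeat: int = 0

    def train_mask(self, fold: int) -> np.ndarray:
        return (self.assignments != fold).reshape(self.shape)

    def test_pairs(self, fold: int) -> np.ndarray:
        flat = np.flatnonzero(self.assignments == fold)
        return np.column_stack(np.unravel_index(flat, self.shape))


def make_fold_split(shape: tuple[int, int], n_folds: int,
                    rng: np.random.Generator, repeat: int = 0) -> FoldSplit:
    """Random partition of all pairs into folds whose sizes differ by <= 1."""
    n_pairs = shape[0] * shape[1]
    if not 2 <= n_folds <= n_pairs:
        raise ValueError("n_folds must be between 2 and the pair count")
    perm = rng.permutation(n_pairs)
    assignments = np.empty(n_pairs, dtype=np.int64)
    for fold, chunk in enumerate(np.array_split(perm, n_folds)):
        assignments[chunk] = fold
    return FoldSplit(assignments=assignments, shape=shape, n_folds=n_folds,
                     repeat=repeat)


@dataclass(frozen=True)
class EvalResult:
    auroc: float
    auprc: float
    n_pairs: int = 0


def evaluate(scores: np.ndarray, labels: np.ndarray,
             test_pairs: np.ndarray) -> EvalResult:
    """AUROC (rank statistic, ties averaged) and AUPRC (step integration
    of the precision-recall curve) on the held-out pairs."""
    test_pairs = np.asarray(test_pairs)
    if test_pairs.size == 0:
        raise MetricError("empty test pair set")
    y = np.asarray(labels)[test_pairs[:, 0], test_pairs[:, 1]]
    s = np.asarray(scores)[test_pairs[:, 0], test_pairs[:, 1]]
    if len(np.unique(y)) < 2:
        raise MetricError("test set contains a single class; metrics undefined")
    return EvalResult(auroc=float(roc_auc_score(y, s)),
                      auprc=float(average_precision_score(y, s)),
                      n_pairs=len(y))


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

@dataclass
class _Forward:
    logits: Tensor
    z_f_drug: Tensor | None
    z_f_disease: Tensor | None
    z_t_drug: Tensor | None
    z_t_disease: Tensor | None
    alpha_drug: tuple[np.ndarray, np.ndarray] | None
    alpha_disease: tuple[np.ndarray, np.ndarray] | None


class AdaGcnModel:
    """The assembled model plus its training state.

    ``train_mask`` is a boolean (n, m) array marking the pairs whose
    labels are visible during training; held-out pairs contribute
    neither to the BCE sum nor to the type-1 edge set of the topology
    graph (they sit in the unknown channel).
    """

    def __init__(self, data: DrugDiseaseDataset, config: ModelConfig,
                 train_mask: np.ndarray | None = None,
                 seed_seq: np.random.SeedSequence | None = None):
        self.data = data
        self.config = config
        n, m = data.shape
        self.train_mask = (np.ones((n, m), dtype=bool) if train_mask is None
                           else np.asarray(train_mask, dtype=bool))
        if self.train_mask.shape != (n, m):
            raise ValueError("train_mask shape must match the dataset")
        labels = data.assoc.values
        if not ((labels == 1) & self.train_mask).any() or \
                not ((labels == 0) & self.train_mask).any():
            raise ValueError("training mask must expose both label classes")

        if seed_seq is None:
            seed_seq = np.random.SeedSequence(config.seed)
        ss_init, ss_drop = seed_seq.spawn(2)
        init_rng = np.random.default_rng(ss_init)
        self._dropout_rng = np.random.default_rng(ss_drop)

        self.use_feature = config.ablation != "w/o-f"
        self.use_topology = config.ablation != "w/o-t"
        cfg = config
        self.drug_graph: KnnGraph | None = None
        self.disease_graph: KnnGraph | None = None
        self.topology_graph: TopologyGraph | None = None
        self.feat_drug: FeatureGcnParams | None = None
        self.feat_disease: FeatureGcnParams | None = None
        self.topo_params: TopologyGcnParams | None = None
        self.att_drug: AttentionParams | None = None
        self.att_disease: AttentionParams | None = None

        if self.use_feature:
            self.drug_graph = build_knn_graph(data.drug_sim, cfg.k_neighbors)
            self.disease_graph = build_knn_graph(data.disease_sim, cfg.k_neighbors)
            self.feat_drug = init_feature_gcn_params(
                n, cfg.hidden, cfg.feature_layers, init_rng, cfg.dropout)
            self.feat_disease = init_feature_gcn_params(
                m, cfg.hidden, cfg.feature_layers, init_rng, cfg.dropout)
        if self.use_topology:
            self.topology_graph = build_topology_graph(data.assoc, self.train_mask)
            self.topo_params = init_topology_gcn_params(
                n, m, cfg.hidden, cfg.topology_rounds, init_rng, cfg.dropout)
        if self.use_feature and self.use_topology and cfg.ablation != "w/o-a":
            self.att_drug = init_attention_params(cfg.hidden, cfg.attention_hidden,
                                                  init_rng)
            self.att_disease = init_attention_params(cfg.hidden, cfg.attention_hidden,
                                                     init_rng)
        self.mlp = init_mlp_params(cfg.hidden, cfg.mlp_sizes, init_rng, cfg.dropout)
        self.loss_history: list[LossBreakdown] = []

    # consistency applies only when both spaces exist and lambda > 0
    @property
    def effective_trade_off(self) -> float:
        if self.config.ablation == "w/o-l" or not (self.use_feature and self.use_topology):
            return 0.0
        return self.config.trade_off

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for block in (self.feat_drug, self.feat_disease, self.topo_params,
                      self.att_drug, self.att_disease, self.mlp):
            if block is not None:
                out.extend(block.parameters())
        return out

    def forward(self, *, training: bool = False,
                rng: np.random.Generator | None = None) -> _Forward:
        cfg = self.config
        rng = rng if rng is not None else (self._dropout_rng if training else None)
        zfr = zfd = ztr = ztd = None
        if self.use_feature:
            zfr = feature_gcn_forward(self.drug_graph, self.feat_drug,
                                      self.data.drug_sim.values,
                                      training=training, rng=rng)
            zfd = feature_gcn_forward(self.disease_graph, self.feat_disease,
                                      self.data.disease_sim.values,
                                      training=training, rng=rng)
        if self.use_topology:
            h_r, h_d = message_passing_forward(self.topology_graph, self.topo_params,
                                               training=training, rng=rng)
            ztr = dense_transform(h_r, self.topo_params)
            ztd = dense_transform(h_d, self.topo_params)

        alpha_drug = alpha_disease = None
        if self.use_feature and self.use_topology:
            if cfg.ablation == "w/o-a":
                n, m = self.data.shape
                half_n = Tensor(np.full((n, 1), 0.5))
                half_m = Tensor(np.full((m, 1), 0.5))
                z_drug = fuse_embeddings(half_n, half_n, zfr, ztr)
                z_disease = fuse_embeddings(half_m, half_m, zfd, ztd)
                alpha_drug = (half_n.data.ravel(), half_n.data.ravel())
                alpha_disease = (half_m.data.ravel(), half_m.data.ravel())
            else:
                z_drug, afr, atr = attend_and_fuse(zfr, ztr, self.att_drug)
                z_disease, afd, atd = attend_and_fuse(zfd, ztd, self.att_disease)
                alpha_drug = (afr.data.ravel(), atr.data.ravel())
                alpha_disease = (afd.data.ravel(), atd.data.ravel())
        elif self.use_feature:
            z_drug, z_disease = zfr, zfd
        else:
            z_drug, z_disease = ztr, ztd

        logits = predict_logits(z_drug, z_disease, self.mlp,
                                training=training, rng=rng)
        return _Forward(logits=logits, z_f_drug=zfr, z_f_disease=zfd,
                        z_t_drug=ztr, z_t_disease=ztd,
                        alpha_drug=alpha_drug, alpha_disease=alpha_disease)

    def compute_loss(self, *, training: bool = False,
                     rng: np.random.Generator | None = None
                     ) -> tuple[Tensor, LossBreakdown]:
        out = self.forward(training=training, rng=rng)
        labels = self.data.assoc.values
        l_bce = bce_loss_from_logits(out.logits, labels, self.train_mask)
        lam = self.effective_trade_off
        if lam > 0:
            eps = 1e-12  # ReLU embeddings can have dead rows mid-training
            l_cr = consistency_loss(embedding_similarity(out.z_f_drug, eps),
                                    embedding_similarity(out.z_t_drug, eps))
            l_cd = consistency_loss(embedding_similarity(out.z_f_disease, eps),
                                    embedding_similarity(out.z_t_disease, eps))
            loss = l_bce + lam * l_cr + lam * l_cd
            breakdown = total_loss(l_bce.item(), l_cr.item(), l_cd.item(), lam)
        else:
            loss = l_bce
            breakdown = total_loss(l_bce.item(), 0.0, 0.0, 0.0)
        return loss, breakdown

    def fit(self, progress: bool = False) -> "AdaGcnModel":
        optimizer = Adam(self.parameters(), lr=self.config.learning_rate)
        for epoch in range(self.config.epochs):
            optimizer.zero_grad()
            loss, breakdown = self.compute_loss(training=True)
            if not np.isfinite(breakdown.l_total):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            optimizer.step()
            self.loss_history.append(breakdown)
            if progress and (epoch % 200 == 0 or epoch == self.config.epochs - 1):
                print(f"epoch {epoch:5d}  loss {breakdown.l_total:.4f} "
                      f"(bce {breakdown.l_bce:.4f})")
        return self

    def predict_matrix(self) -> np.ndarray:
        """Full (n, m) matrix of sigmoid pair scores, dropout off."""
        return self.forward(training=False).logits.sigmoid().data

    def attention_weights(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Per-node attention weights for drugs and diseases."""
        if self.config.ablation == "w/o-a":
            raise ValueError("attention disabled (w/o-a ablation); nothing to report")
        if not (self.use_feature and self.use_topology):
            raise ValueError("attention requires both embedding spaces")
        out = self.forward(training=False)
        drugs = pd.DataFrame({"node": self.data.assoc.drug_ids,
                              "alpha_feature": out.alpha_drug[0],
                              "alpha_topology": out.alpha_drug[1]})
        diseases = pd.DataFrame({"node": self.data.assoc.disease_ids,
                                 "alpha_feature": out.alpha_disease[0],
                                 "alpha_topology": out.alpha_disease[1]})
        return drugs, diseases


def train_model(data: DrugDiseaseDataset, config: ModelConfig,
                train_mask: np.ndarray | None = None,
                seed_seq: np.random.SeedSequence | None = None,
                progress: bool = False) -> AdaGcnModel:
    """Build and fit a model; returns it with its loss history."""
    return AdaGcnModel(data, config, train_mask, seed_seq).fit(progress=progress)


# ---------------------------------------------------------------------------
# evaluation protocols
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-fold metrics plus the two aggregation conventions (sd over all
    folds, and sd over the repeat means)."""

    per_fold: pd.DataFrame  # columns: repeat, fold, auroc, auprc, n_pairs
    n_folds: int
    n_repeats: int
    skipped: list[tuple[int, int]] = field(default_factory=list)

    def summary(self) -> dict[str, float]:
        folds = self.per_fold
        repeat_means = folds.groupby("repeat")[["auroc", "auprc"]].mean()
        return {
            "auroc_mean": float(folds["auroc"].mean()),
            "auroc_sd_folds": float(folds["auroc"].std(ddof=1)) if len(folds) > 1 else 0.0,
            "auroc_sd_repeats": float(repeat_means["auroc"].std(ddof=1))
                                if len(repeat_means) > 1 else 0.0,
            "auprc_mean": float(folds["auprc"].mean()),
            "auprc_sd_folds": float(folds["auprc"].std(ddof=1)) if len(folds) > 1 else 0.0,
            "auprc_sd_repeats": float(repeat_means["auprc"].std(ddof=1))
                                if len(repeat_means) > 1 else 0.0,
        }


def cross_validate(data: DrugDiseaseDataset, config: ModelConfig,
                   n_folds: int = 10, n_repeats: int = 10,
                   progress: bool = False) -> CVResult:
    """Repeated k-fold cross-validation over all drug-disease pairs.

    All known and unknown pairs are partitioned together; each fold is
    held out in turn, the model trains on the remaining folds' labels
    (held-out pairs enter the topology graph only as unknowns) and is
    scored on the held-out pairs.  Folds whose test pairs carry a
    single class are skipped with a warning and recorded.
    """
    rows = []
    skipped: list[tuple[int, int]] = []
    for repeat in range(n_repeats):
        split_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1000 + repeat]))
        split = make_fold_split(data.shape, n_folds, split_rng, repeat=repeat)
        for fold in range(n_folds):
            seed_seq = np.random.SeedSequence([config.seed, repeat, fold])
            model = train_model(data, config, split.train_mask(fold), seed_seq)
            scores = model.predict_matrix()
            try:
                res = evaluate(scores, data.assoc.values, split.test_pairs(fold))
            except MetricError:
                import warnings
                warnings.warn(f"fold {fold} of repeat {repeat} has a single class; "
                              "skipped", stacklevel=2)
                skipped.append((repeat, fold))
                continue
            rows.append({"repeat": repeat, "fold": fold, "auroc": res.auroc,
                         "auprc": res.auprc, "n_pairs": res.n_pairs})
            if progress:
                print(f"repeat {repeat} fold {fold}: AUROC {res.auroc:.3f} "
                      f"AUPRC {res.auprc:.3f}")
    return CVResult(per_fold=pd.DataFrame(rows), n_folds=n_folds,
                    n_repeats=n_repeats, skipped=skipped)


def new_drug_evaluation(data: DrugDiseaseDataset, config: ModelConfig,
                        max_drugs: int | None = None,
                        progress: bool = False) -> tuple[pd.DataFrame, dict[str, float]]:
    """Cold-start protocol: per drug, hide its entire row during training
    and rank its diseases at test time.

    Drugs with zero known associations are excluded (their metrics are
    undefined).  ``max_drugs`` caps the number of drugs for desk-scale
    runs; the protocol itself is a single pass, no repeats.
    """
    labels = data.assoc.values
    eligible = [i for i in range(labels.shape[0]) if labels[i].sum() >= 1
                and labels[i].sum() < labels.shape[1]]
    if len(eligible) < 1:
        raise ValueError("no drug with at least one association to hold out")
    if max_drugs is not None:
        eligible = eligible[:max_drugs]
    rows = []
    for count, i in enumerate(eligible):
        mask = np.ones_like(labels, dtype=bool)
        mask[i, :] = False
        seed_seq = np.random.SeedSequence([config.seed, 2000, i])
        model = train_model(data, config, mask, seed_seq)
        scores = model.predict_matrix()
        pairs = np.column_stack([np.full(labels.shape[1], i),
                                 np.arange(labels.shape[1])])
        res = evaluate(scores, labels, pairs)
        rows.append({"drug": data.assoc.drug_ids[i], "drug_index": i,
                     "n_positives": int(labels[i].sum()),
                     "auroc": res.auroc, "auprc": res.auprc})
        if progress:
            print(f"[{count + 1}/{len(eligible)}] drug {data.assoc.drug_ids[i]}: "
                  f"AUROC {res.auroc:.3f} AUPRC {res.auprc:.3f}")
    frame = pd.DataFrame(rows)
    aggregate = {"auroc_mean": float(frame["auroc"].mean()),
                 "auprc_mean": float(frame["auprc"].mean()),
                 "n_drugs": len(frame)}
    return frame, aggregate


def sweep(data: DrugDiseaseDataset, config: ModelConfig, parameter: str,
          values: list, n_folds: int = 10, n_repeats: int = 1,
          progress: bool = False) -> pd.DataFrame:
    """Cross-validate once per value of K (`"K"`) or lambda (`"lambda"`)."""
    field_name = {"K": "k_neighbors", "lambda": "trade_off"}.get(parameter)
    if field_name is None:
        raise ValueError("parameter must be 'K' or 'lambda'")
    if not values:
        raise ValueError("values must be nonempty")
    rows = []
    for value in values:
        cfg = config.replace(**{field_name: value})
        result = cross_validate(data, cfg, n_folds=n_folds, n_repeats=n_repeats,
                                progress=progress)
        summary = result.summary()
        rows.append({"parameter": parameter, "value": value, **summary})
    return pd.DataFrame(rows)


def attention_report(model: AdaGcnModel) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-node attention weights plus distribution summaries for the four
    groups (drug/disease x feature/topology)."""
    drugs, diseases = model.attention_weights()
    groups = {
        "r-feature": drugs["alpha_feature"],
        "r-topology": drugs["alpha_topology"],
        "d-feature": diseases["alpha_feature"],
        "d-topology": diseases["alpha_topology"],
    }
    summary = pd.DataFrame({
        name: {"mean": s.mean(), "q25": s.quantile(0.25),
               "median": s.median(), "q75": s.quantile(0.75)}
        for name, s in groups.items()
    }).T.reset_index(names="group")
    per_node = pd.concat([drugs.assign(kind="drug"),
                          diseases.assign(kind="disease")], ignore_index=True)
    return per_node, summary
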