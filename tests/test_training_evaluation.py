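"""Training loop, metrics, cross-validation and the evaluation protocols.

Long-horizon behaviour (signal recovery, ablation ordering) lives in
the acceptance suite; these tests exercise the machinery at toy scale.
"""

import numpy as np
import pytest

from adagcn import synthetic_data
from adagcn.dataset_io import AssociationMatrix, DrugDiseaseDataset
from adagcn.training_evaluation import (AdaGcnModel, MetricError, ModelConfig,
                                        attention_report, cross_validate,
                                        evaluate, make_fold_split,
                                        new_drug_evaluation, sweep, train_model)

TOY_CFG = dict(k_neighbors=1, hidden=8, attention_hidden=4, dropout=0.0)


@pytest.fixture(scope="module")
def toy_model():
    data = synthetic_data.toy_dataset()
    cfg = ModelConfig(epochs=500, seed=0, **TOY_CFG)
    return data, cfg, train_model(data, cfg)


class TestConfig:
    def test_defaults_match_published_tuning(self):
        cfg = ModelConfig()
        assert (cfg.epochs, cfg.learning_rate, cfg.dropout,
                cfg.k_neighbors, cfg.trade_off) == (4000, 0.01, 0.3, 4, 0.1)
        assert cfg.mlp_sizes == (64, 32)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(ablation="w/o-x")
        with pytest.raises(ValueError):
            ModelConfig(dropout=1.0)

    def test_yaml_round_trip(self, tmp_path):
        cfg = ModelConfig(epochs=12, trade_off=0.01, mlp_hidden=(8, 4))
        cfg.to_yaml(tmp_path / "c.yaml")
        assert ModelConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestEvaluate:
    def test_perfect_separation(self):
        scores = np.array([[0.9, 0.8], [0.1, 0.2]])
        labels = np.array([[1, 1], [0, 0]])
        pairs = np.argwhere(np.ones((2, 2), bool))
        res = evaluate(scores, labels, pairs)
        assert res.auroc == 1.0 and res.auprc == 1.0

    def test_inverted_ranking(self):
        res = evaluate(np.array([[0.2, 0.9]]), np.array([[1, 0]]),
                       np.array([[0, 0], [0, 1]]))
        assert res.auroc == 0.0

    def test_matches_threshold_enumeration_oracle(self):
        scores = np.array([[0.9, 0.8, 0.7, 0.1]])
        labels = np.array([[1, 0, 1, 0]])
        pairs = np.array([[0, j] for j in range(4)])
        res = evaluate(scores, labels, pairs)
        assert res.auroc == pytest.approx(0.75)
        # brute-force AUPRC: step integration over all score thresholds
        s, y = scores[0], labels[0]
        order = np.argsort(-s)
        tp = np.cumsum(y[order])
        precision = tp / np.arange(1, 5)
        recall = tp / y.sum()
        auprc = 0.0
        prev_r = 0.0
        for p, r in zip(precision, recall):
            auprc += p * (r - prev_r)
            prev_r = r
        assert res.auprc == pytest.approx(auprc)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            evaluate(np.array([[0.5, 0.6]]), np.array([[1, 1]]),
                     np.array([[0, 0], [0, 1]]))


class TestFoldSplit:
    def test_partition_and_balance(self, rng):
        split = make_fold_split((9, 7), 10, rng)
        sizes = [len(split.test_pairs(f)) for f in range(10)]
        assert sum(sizes) == 63
        assert max(sizes) - min(sizes) <= 1
        # disjoint union covers all pairs
        all_pairs = np.vstack([split.test_pairs(f) for f in range(10)])
        assert len(np.unique(all_pairs, axis=0)) == 63

    def test_toy_six_pairs_six_folds(self, rng):
        split = make_fold_split((3, 2), 6, rng)
        assert sorted(len(split.test_pairs(f)) for f in range(6)) == [1] * 6

    def test_train_mask_complements_test_fold(self, rng):
        split = make_fold_split((4, 5), 5, rng)
        mask = split.train_mask(2)
        pairs = split.test_pairs(2)
        assert not mask[pairs[:, 0], pairs[:, 1]].any()
        assert mask.sum() + len(pairs) == 20


class TestTraining:
    def test_loss_decreases_on_toy(self, toy_model):
        _, _, model = toy_model
        assert model.loss_history[-1].l_bce < model.loss_history[0].l_bce

    def test_seed_determinism(self, toy_model):
        data, cfg, model = toy_model
        again = train_model(data, cfg)
        assert again.loss_history[-1].l_total == \
            pytest.approx(model.loss_history[-1].l_total, abs=1e-10)
        np.testing.assert_allclose(again.predict_matrix(),
                                   model.predict_matrix(), atol=1e-10)

    def test_toy_overfits_to_labels(self, toy_model):
        data, _, model = toy_model
        scores = model.predict_matrix()
        assert ((scores > 0.5) == (data.assoc.values == 1)).all()

    def test_loss_breakdown_identity(self, toy_model):
        _, _, model = toy_model
        for bd in model.loss_history[::100]:
            assert bd.l_total == pytest.approx(
                bd.l_bce + bd.trade_off * (bd.l_cr + bd.l_cd), rel=1e-12)

    def test_ablation_switches_change_structure(self):
        data = synthetic_data.toy_dataset()
        cfg = ModelConfig(epochs=5, seed=0, **TOY_CFG)
        full = AdaGcnModel(data, cfg)
        assert full.att_drug is not None
        wo_f = AdaGcnModel(data, cfg.replace(ablation="w/o-f"))
        assert wo_f.drug_graph is None and wo_f.topology_graph is not None
        wo_t = AdaGcnModel(data, cfg.replace(ablation="w/o-t"))
        assert wo_t.topology_graph is None
        wo_l = AdaGcnModel(data, cfg.replace(ablation="w/o-l"))
        assert wo_l.effective_trade_off == 0.0
        wo_a = AdaGcnModel(data, cfg.replace(ablation="w/o-a"))
        assert wo_a.att_drug is None

    def test_mask_must_keep_both_classes(self):
        data = synthetic_data.toy_dataset()
        mask = np.zeros((3, 2), dtype=bool)
        mask[0, 0] = True  # only a positive visible
        with pytest.raises(ValueError):
            AdaGcnModel(data, ModelConfig(epochs=5, **TOY_CFG), mask)


@pytest.fixture(scope="module")
def small_planted():
    spec = synthetic_data.SyntheticSpec(n_drugs=20, n_diseases=15,
                                        latent_rank=2, density=0.15, seed=3)
    data, _ = synthetic_data.planted_dataset(spec)
    return data


class TestProtocols:
    def test_cross_validate_shapes_and_aggregate(self, small_planted):
        cfg = ModelConfig(epochs=60, seed=1, hidden=8, attention_hidden=4,
                          k_neighbors=2)
        res = cross_validate(small_planted, cfg, n_folds=3, n_repeats=2)
        assert len(res.per_fold) + len(res.skipped) == 6
        summary = res.summary()
        folds = res.per_fold
        assert summary["auroc_mean"] == pytest.approx(folds["auroc"].mean())
        assert folds["auroc"].min() <= summary["auroc_mean"] <= folds["auroc"].max()

    def test_new_drug_protocol_on_toy(self):
        data = synthetic_data.toy_dataset()
        cfg = ModelConfig(epochs=100, seed=0, **TOY_CFG)
        frame, aggregate = new_drug_evaluation(data, cfg)
        # drug 2 has no positives -> excluded; drug 1 is all-ones -> excluded
        assert list(frame["drug_index"]) == [0]
        # one positive of two diseases: AUROC is 0, 0.5 or 1
        assert frame["auroc"].iloc[0] in (0.0, 0.5, 1.0)
        assert aggregate["n_drugs"] == 1

    def test_new_drug_max_drugs_cap(self, small_planted):
        cfg = ModelConfig(epochs=30, seed=0, hidden=8, attention_hidden=4,
                          k_neighbors=2)
        frame, aggregate = new_drug_evaluation(small_planted, cfg, max_drugs=2)
        assert aggregate["n_drugs"] == 2

    def test_sweep_shape_and_lambda_zero_equals_ablation(self, small_planted):
        cfg = ModelConfig(epochs=40, seed=5, hidden=8, attention_hidden=4,
                          k_neighbors=2)
        table = sweep(small_planted, cfg, "lambda", [0.0, 0.1],
                      n_folds=2, n_repeats=1)
        assert list(table["value"]) == [0.0, 0.1]
        # lambda = 0 row coincides with the w/o-l ablation under the same seeds
        wo_l = cross_validate(small_planted, cfg.replace(ablation="w/o-l"),
                              n_folds=2, n_repeats=1)
        assert table.iloc[0]["auroc_mean"] == \
            pytest.approx(wo_l.summary()["auroc_mean"], abs=1e-10)

    def test_sweep_rejects_unknown_parameter(self, small_planted):
        with pytest.raises(ValueError):
            sweep(small_planted, ModelConfig(), "gamma", [0.1])


class TestAttentionReport:
    def test_rows_sum_to_one_and_summary_groups(self):
        data = synthetic_data.toy_dataset()
        model = train_model(data, ModelConfig(epochs=50, seed=0, **TOY_CFG))
        per_node, summary = attention_report(model)
        np.testing.assert_allclose(
            per_node["alpha_feature"] + per_node["alpha_topology"], 1.0,
            atol=1e-12)
        assert set(summary["group"]) == {"r-feature", "r-topology",
                                         "d-feature", "d-topology"}

    def test_without_attention_refuses(self):
        data = synthetic_data.toy_dataset()
        model = train_model(data, ModelConfig(epochs=5, seed=0,
                                              ablation="w/o-a", **TOY_CFG))
        with pytest.raises(ValueError, match="attention"):
            attention_report(model)
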