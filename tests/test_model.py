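"""Encoder blocks, joint training mechanics and the zero-shot pathway."""

import numpy as np
import pytest

from ontoball import autodiff as ad
from ontoball import geometry
from ontoball.geometry import EmbeddingSpace
from ontoball.model import (FunctionPredictionModel, FunctionPredictionResults,
                            MLPBlock, PredictionMatrix, ProteinEncoder,
                            ProteinRecord, TrainConfig, encode_protein,
                            joint_loss, label_matrix, propagate_scores)
from conftest import records_for


def identity_block(d_in, d_out, rng):
    """A block whose eval-mode output is ReLU(Wx+b) exactly."""
    block = MLPBlock(d_in, d_out, dropout=0.0, rng=rng)
    block.bn.eps = 0.0  # running stats are (0, 1): normalization = identity
    return block


class TestMLPBlock:
    def test_eval_mode_identity_on_nonnegative_input(self, rng):
        block = identity_block(4, 4, rng)
        block.linear.W.value = np.eye(4)
        block.linear.b.value = np.zeros(4)
        x = np.array([[0.0, 1.0, 2.0, 0.5]])
        assert np.allclose(ad._val(block(x, training=False)), x)

    def test_relu_zeroes_negative_entries(self, rng):
        block = identity_block(3, 3, rng)
        block.linear.W.value = np.eye(3)
        block.linear.b.value = np.zeros(3)
        out = ad._val(block(np.array([[-1.0, 0.5, -0.2]]), training=False))
        assert np.allclose(out, [[0.0, 0.5, 0.0]])

    def test_matches_explicit_composition(self, rng):
        block = MLPBlock(8, 5, dropout=0.0, rng=rng)
        block.bn.running_mean = rng.normal(size=5)
        block.bn.running_var = rng.random(5) + 0.5
        x = rng.normal(size=(6, 8))
        pre = np.maximum(x @ block.linear.W.value + block.linear.b.value, 0)
        want = block.bn.gamma.value * (pre - block.bn.running_mean) \
            / np.sqrt(block.bn.running_var + block.bn.eps) \
            + block.bn.beta.value
        assert np.allclose(ad._val(block(x, training=False)), want)

    def test_training_mode_dropout_needs_rng(self, rng):
        block = MLPBlock(3, 3, dropout=0.5, rng=rng)
        with pytest.raises(ValueError, match="rng"):
            block(np.zeros((1, 3)), training=True)


class TestEncoder:
    def test_residual_reduces_to_first_block_when_second_is_zero(self, rng):
        enc = ProteinEncoder(6, 4, dropout=0.0, rng=rng)
        enc.block2.linear.W.value[:] = 0.0
        enc.block2.linear.b.value[:] = 0.0
        enc.block2.bn.eps = 0.0
        x = rng.random((3, 6))
        h = ad._val(enc.block1(x, training=False))
        assert np.allclose(encode_protein(enc, x), h)

    def test_zero_input_zero_bias_gives_zero_embedding(self, rng):
        enc = ProteinEncoder(5, 4, dropout=0.0, rng=rng)
        for block in (enc.block1, enc.block2):
            block.linear.b.value[:] = 0.0
            block.bn.eps = 0.0
            block.bn.beta.value[:] = 0.0
        out = encode_protein(enc, np.zeros((2, 5)))
        assert np.allclose(out, 0.0)

    def test_wrong_feature_length_rejected(self, rng):
        enc = ProteinEncoder(5, 4, dropout=0.0, rng=rng)
        with pytest.raises(ValueError, match="vocabulary"):
            encode_protein(enc, np.zeros((1, 7)))


class TestJointLoss:
    def _setup(self, rng, raw_radius=-30.0):
        from ontoball.ontology import NormalizedAxiomSet
        enc = ProteinEncoder(4, 3, dropout=0.0, rng=rng)
        for block in (enc.block1, enc.block2):
            block.linear.b.value[:] = 0.0
            block.bn.eps = 0.0
            block.bn.beta.value[:] = 0.0
        space = EmbeddingSpace(["c1", "c2"], [], n=3, gamma=0.0,
                               rng=np.random.default_rng(0))
        space.raw_radii[:] = raw_radius  # radius ~ 0 -> logits ~ 0
        nf = NormalizedAxiomSet()
        return enc, space, nf

    def test_uninformative_scores_cost_log2_per_label(self, rng):
        enc, space, nf = self._setup(rng)
        X = np.zeros((4, 4))  # zero embedding -> logits = radius ~ 0
        Y = np.array([[1, 0], [0, 1], [1, 1], [0, 0]], dtype=bool)
        bd = joint_loss(space, enc, X, Y, ["c1", "c2"], nf)
        assert bd.bce == pytest.approx(np.log(2), abs=1e-6)
        assert bd.total == pytest.approx(bd.bce)

    def test_confident_correct_scores_approach_zero(self, rng):
        enc, space, nf = self._setup(rng)
        space.raw_radii[:] = 30.0  # radius ~ 30 -> score ~ 1
        X = np.zeros((2, 4))
        Y = np.ones((2, 2), dtype=bool)
        bd = joint_loss(space, enc, X, Y, ["c1", "c2"], nf)
        assert bd.bce == pytest.approx(0.0, abs=1e-8)

    def test_breakdown_total_is_component_sum(self, tiny_fixture):
        model = FunctionPredictionModel.from_dataset(tiny_fixture.dataset)
        res = model.fit(TrainConfig(n=16, epochs=2, seed=0, patience=2))
        bd = res.loss_breakdown()
        assert bd.total == pytest.approx(
            bd.bce + bd.nf1 + bd.nf2 + bd.nf3 + bd.nf4)
        assert min(bd.bce, bd.nf1, bd.nf2, bd.nf3, bd.nf4) >= 0


class TestTraining:
    def test_same_seed_reproduces_history_and_predictions(self, tiny_fixture):
        cfg = TrainConfig(n=16, epochs=3, seed=11, patience=3)
        runs = []
        for _ in range(2):
            model = FunctionPredictionModel.from_dataset(tiny_fixture.dataset)
            res = model.fit(cfg)
            pred = res.predict(records_for(tiny_fixture))
            runs.append((res.history, pred.scores))
        assert runs[0][0] == runs[1][0]
        assert np.array_equal(runs[0][1], runs[1][1])

    def test_loss_decreases_on_the_fixture_for_most_seeds(self, tiny_fixture):
        drops = 0
        for seed in range(10):
            model = FunctionPredictionModel.from_dataset(tiny_fixture.dataset)
            res = model.fit(TrainConfig(n=16, epochs=5, seed=seed,
                                        patience=5))
            totals = [h["total"] for h in res.history]
            if totals[-1] < totals[0]:
                drops += 1
        assert drops >= 9

    def test_large_margin_keeps_nf_losses_zero(self, tiny_fixture):
        model = FunctionPredictionModel.from_dataset(tiny_fixture.dataset)
        res = model.fit(TrainConfig(n=16, epochs=2, seed=0, patience=2,
                                    gamma=1e6))
        for h in res.history:
            assert h["nf1"] == 0 and h["nf2"] == 0
            assert h["nf3"] == 0 and h["nf4"] == 0

    def test_empty_target_set_is_an_error(self, tiny_fixture):
        ds = tiny_fixture.dataset
        everything = set().union(*ds.propagated().annotations.values())
        model = FunctionPredictionModel.from_dataset(
            ds, exclude_targets=everything)
        with pytest.raises(ValueError, match="target class"):
            model.fit(TrainConfig(n=16, epochs=1, seed=0))

    def test_overlapping_train_valid_rejected(self, tiny_fixture):
        recs = records_for(tiny_fixture, "train")[:4]
        with pytest.raises(ValueError, match="overlap"):
            FunctionPredictionModel(recs, recs, tiny_fixture.dataset.nf)

    def test_mlp_baseline_differs_from_geometric_model(self, tiny_fixture):
        from sklearn.metrics import roc_auc_score
        profiles = {}
        for mt in ("elembed", "mlp"):
            model = FunctionPredictionModel.from_dataset(
                tiny_fixture.dataset, model_type=mt)
            res = model.fit(TrainConfig(n=16, epochs=20, seed=3, patience=20))
            pred = res.predict(records_for(tiny_fixture))
            aucs = []
            for j in range(pred.scores.shape[1]):
                col = pred.labels[:, j]
                if 0 < col.sum() < len(col):
                    aucs.append(roc_auc_score(col, pred.scores[:, j]))
            profiles[mt] = np.array(aucs)
        assert not np.allclose(profiles["elembed"], profiles["mlp"])

    def test_checkpoint_save_load_round_trip(self, tiny_fixture, tmp_path):
        model = FunctionPredictionModel.from_dataset(tiny_fixture.dataset)
        res = model.fit(TrainConfig(n=16, epochs=3, seed=5, patience=3))
        res.save(tmp_path / "ckpt")
        back = FunctionPredictionResults.load(tmp_path / "ckpt")
        recs = records_for(tiny_fixture)
        X = np.stack([r.features for r in recs]).astype(float)
        assert np.allclose(back.predict(X).scores, res.predict(recs).scores)

    def test_summary_mentions_key_quantities(self, tiny_fixture):
        model = FunctionPredictionModel.from_dataset(tiny_fixture.dataset)
        res = model.fit(TrainConfig(n=16, epochs=2, seed=0, patience=2))
        text = res.summary()
        assert "elembed" in text and "margin" in text and "Fmax" in text


class TestZeroShotMechanics:
    def test_untrained_class_still_scores_finite(self, tiny_fixture):
        ds = tiny_fixture.dataset
        defined = [e for _, _, e in ds.nf.nf2]
        holdout = defined[0]
        model = FunctionPredictionModel.from_dataset(
            ds, exclude_targets=[holdout])
        res = model.fit(TrainConfig(n=16, epochs=2, seed=0, patience=2))
        assert holdout not in res.targets
        pred = res.predict(records_for(tiny_fixture), [holdout])
        assert np.isfinite(pred.scores).all()
        assert ((pred.scores > 0) & (pred.scores < 1)).all()

    def test_excluded_class_center_still_receives_axiom_gradient(
            self, tiny_fixture):
        ds = tiny_fixture.dataset
        defined = [e for _, _, e in ds.nf.nf2]
        holdout = defined[0]
        space = EmbeddingSpace(sorted(ds.nf.all_class_ids()),
                               sorted(ds.nf.all_relation_ids()), n=8,
                               gamma=0.0, rng=np.random.default_rng(1))
        centers = ad.Parameter(space.centers)
        loss = geometry.nf1_loss(space, ds.nf.nf1, centers=centers)
        loss.backward()
        row = space.class_index[holdout]
        assert np.abs(centers.grad[row]).sum() > 0

    def test_mlp_refuses_untrained_classes(self, tiny_fixture):
        ds = tiny_fixture.dataset
        defined = [e for _, _, e in ds.nf.nf2]
        model = FunctionPredictionModel.from_dataset(
            ds, model_type="mlp", exclude_targets=[defined[0]])
        res = model.fit(TrainConfig(n=16, epochs=2, seed=0, patience=2))
        with pytest.raises(KeyError, match="untrained"):
            res.predict(records_for(tiny_fixture), [defined[0]])


class TestScorePropagation:
    def test_ancestors_dominate_descendants_after_propagation(self, rng):
        closure = {"leaf": {"leaf", "mid", "root"},
                   "mid": {"mid", "root"}, "root": {"root"}}
        pm = PredictionMatrix(["p"], ["leaf", "mid", "root"],
                              np.array([[0.9, 0.2, 0.1]]))
        out = propagate_scores(pm, closure)
        assert out.scores[0].tolist() == [0.9, 0.9, 0.9]
        # original matrix untouched
        assert pm.scores[0].tolist() == [0.9, 0.2, 0.1]

    def test_propagated_matrix_satisfies_pairwise_dominance(
            self, tiny_fixture):
        ds = tiny_fixture.dataset
        model = FunctionPredictionModel.from_dataset(ds)
        res = model.fit(TrainConfig(n=16, epochs=2, seed=0, patience=2))
        pred = res.predict(records_for(tiny_fixture), propagate=True,
                           closure=ds.closure)
        idx = {c: j for j, c in enumerate(pred.class_ids)}
        for cid in pred.class_ids:
            for anc in ds.closure.get(cid, ()):
                if anc in idx:
                    assert (pred.scores[:, idx[anc]]
                            >= pred.scores[:, idx[cid]] - 1e-12).all()


def test_label_matrix_alignment():
    recs = [ProteinRecord("p1", np.zeros(2), {"a", "b"}),
            ProteinRecord("p2", np.zeros(2), {"b"})]
    y = label_matrix(recs, ["a", "b", "c"])
    assert y.tolist() == [[True, True, False], [False, True, False]]
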