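"""Classifier behaviour: attention algebra, inference purity, training contract."""

import numpy as np
import pytest

from dualpet._autodiff import Tensor, softmax
from dualpet.datatypes import build_features
from dualpet.model import (
    ADPositivityNet,
    ModelConfig,
    TrainedModel,
    attention_pool,
    train_model,
)
from dualpet.synthetic import CohortSpec, generate_cohort
from dualpet.evaluation import stratified_split


class TestAttentionPool:
    def test_single_phase_is_identity(self, rng):
        h = rng.normal(size=4)
        a, C = attention_pool([h], h * 0, rng.normal(size=8), [0.0])
        np.testing.assert_allclose(a, [1.0])
        np.testing.assert_allclose(C, h)

    def test_identical_phases_split_evenly(self, rng):
        h = rng.normal(size=6)
        a, C = attention_pool([h, h], rng.normal(size=6), rng.normal(size=12), [0.0, 0.0])
        np.testing.assert_allclose(a, [0.5, 0.5])
        np.testing.assert_allclose(C, h)

    def test_hand_computed_one_dimensional_case(self):
        # D=1, h = {[1], [-1]}, h' = [0], W = [1, 1], b = 0:
        # e = (tanh 1, tanh -1); a = (0.8210, 0.1790); C = 0.6420
        a, C = attention_pool([[1.0], [-1.0]], [0.0], [1.0, 1.0], [0.0, 0.0])
        np.testing.assert_allclose(a, [0.8210, 0.1790], atol=1e-3)
        assert C[0] == pytest.approx(0.6420, abs=1e-3)

    def test_weights_form_convex_combination(self, rng):
        for _ in range(200):
            D, N = int(rng.integers(1, 8)), int(rng.integers(1, 5))
            hs = [rng.normal(size=D) * 3 for _ in range(N)]
            a, C = attention_pool(hs, rng.normal(size=D), rng.normal(size=2 * D),
                                  rng.normal(size=N))
            assert np.all(a >= 0)
            assert a.sum() == pytest.approx(1.0, abs=1e-12)
            H = np.stack(hs)
            assert np.all(C >= H.min(axis=0) - 1e-12)
            assert np.all(C <= H.max(axis=0) + 1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            attention_pool([[1.0, 2.0]], [0.0, 0.0], [1.0, 1.0, 1.0], [0.0])


class TestNetworkAlgebra:
    def test_encoder_output_width_constant_in_sequence_length(self):
        cfg = ModelConfig(seed=0)
        net = ADPositivityNet("early", cfg).eval()
        for T in (5, 27, 40):
            steps = [Tensor(np.random.default_rng(1).normal(size=(3, 6))) for _ in range(T)]
            logits, state = net(steps, None, return_state=True)
            assert state["h_e"].shape == (3, 6)
            assert logits.shape == (3, 2)

    def test_softmax_outputs_sum_to_one(self, trained_dual, small_splits):
        _, _, te = small_splits
        tac_steps, suvr = trained_dual._scaled_inputs(te)
        probs = softmax(trained_dual.net(tac_steps, suvr), axis=1).data
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-7)

    def test_zero_output_layer_scores_half(self, trained_dual, small_splits):
        _, _, te = small_splits
        saved = trained_dual.net.out.W.data.copy(), trained_dual.net.out.b.data.copy()
        try:
            trained_dual.net.out.W.data[...] = 0.0
            trained_dual.net.out.b.data[...] = 0.0
            np.testing.assert_allclose(trained_dual.predict_scores(te), 0.5, atol=1e-12)
        finally:
            trained_dual.net.out.W.data[...] = saved[0]
            trained_dual.net.out.b.data[...] = saved[1]

    def test_first_aggregation_is_order_sensitive(self):
        from dualpet._autodiff import concat

        cfg = ModelConfig(seed=2)
        net = ADPositivityNet("dual", cfg).eval()
        rng = np.random.default_rng(3)
        h_e, h_d = Tensor(rng.normal(size=(2, 6))), Tensor(rng.normal(size=(2, 6)))
        a = net.agg(concat([h_e, h_d], axis=1)).data
        b = net.agg(concat([h_d, h_e], axis=1)).data
        assert not np.allclose(a, b)

    def test_constant_input_lstm_reaches_fixed_point(self):
        """On a constant sequence the hidden state converges: h(T) ~ h(T+10)."""
        cfg = ModelConfig(seed=4)
        net = ADPositivityNet("early", cfg).eval()
        x = np.random.default_rng(5).normal(size=(1, 6))
        lstm = net.enc_e.lstms[0]
        h_T = lstm([Tensor(x)] * 60)[-1].data
        h_T10 = lstm([Tensor(x)] * 70)[-1].data
        np.testing.assert_allclose(h_T, h_T10, atol=1e-3)


class TestInferencePurity:
    def test_repeated_and_batchwise_prediction_identical(self, trained_dual, small_splits):
        _, _, te = small_splits
        s1 = trained_dual.predict_scores(te)
        s2 = trained_dual.predict_scores(te)
        np.testing.assert_array_equal(s1, s2)
        # batch composition must not matter (batch norm in inference mode)
        half = te.subset(np.arange(len(te) // 2))
        np.testing.assert_allclose(
            trained_dual.predict_scores(half), s1[: len(te) // 2], atol=1e-12
        )

    def test_nan_inputs_rejected(self, trained_dual, small_splits):
        _, _, te = small_splits
        bad = te.subset(np.arange(3))
        bad.tac = bad.tac.copy()
        bad.tac[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            trained_dual.predict_scores(bad)


class TestTraining:
    def test_seeded_determinism(self, small_splits):
        tr, va, _ = small_splits
        cfg = ModelConfig(seed=5, lr=1e-3, max_epochs=8, early_stop_patience=8,
                          lr_decay_patience=4)
        m1 = train_model(tr, va, cfg, phase="delay")
        m2 = train_model(tr, va, cfg, phase="delay")
        for a, b in zip(m1.net.state_arrays(), m2.net.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_early_stopping_contract(self, small_splits):
        tr, va, _ = small_splits
        cfg = ModelConfig(seed=6, lr=1e-2, max_epochs=400, early_stop_patience=20,
                          lr_decay_patience=10)
        m = train_model(tr, va, cfg, phase="delay")
        epochs_run = len(m.history["val_loss"])
        assert epochs_run <= cfg.max_epochs
        assert epochs_run <= m.best_epoch + cfg.early_stop_patience + 1

    def test_training_loss_decreases(self, small_splits):
        tr, va, _ = small_splits
        deltas = []
        for seed in range(3):
            cfg = ModelConfig(seed=seed, lr=1e-3, max_epochs=50,
                              early_stop_patience=50, lr_decay_patience=25)
            m = train_model(tr, va, cfg, phase="delay")
            deltas.append(m.history["train_loss"][-1] - m.history["train_loss"][0])
        assert np.median(deltas) < 0

    def test_separable_cohort_reaches_perfect_validation_accuracy(self):
        """Noise-free large-effect cohort: the model and a linear-SVM oracle
        on the same features both classify the validation split perfectly."""
        from sklearn.svm import SVC

        spec = CohortSpec(n_cn=40, n_ad=40, n_abpos_cn=4, n_abneg_ad=4,
                          perfusion_effect=0.5, amyloid_effect=0.8,
                          noise_sd=0.01, seed=21)
        recs = generate_cohort(spec)
        sp = stratified_split(recs, seed=21)
        by = {p: [r for r in recs if sp.assignment[r.subject_id] == p]
              for p in ("train", "validation", "test")}
        tr, va = build_features(by["train"]), build_features(by["validation"])
        cfg = ModelConfig(seed=21, lr=1e-3, max_epochs=200, early_stop_patience=80,
                          lr_decay_patience=40)
        m = train_model(tr, va, cfg, phase="dual")
        assert np.mean(m.predict_labels(va) == va.y) == 1.0
        # independent separability oracle
        Xtr = np.hstack([tr.tac.reshape(len(tr), -1), tr.suvr])
        Xva = np.hstack([va.tac.reshape(len(va), -1), va.suvr])
        svm = SVC(kernel="linear").fit(Xtr, tr.y)
        assert svm.score(Xva, va.y) == 1.0

    def test_single_class_training_rejected(self, small_splits):
        tr, va, _ = small_splits
        only_ad = tr.subset(tr.y == 1)
        with pytest.raises(ValueError):
            train_model(only_ad, va, ModelConfig(seed=0, max_epochs=2), phase="delay")

    def test_train_val_overlap_rejected(self, small_splits):
        tr, _, _ = small_splits
        with pytest.raises(ValueError):
            train_model(tr, tr, ModelConfig(seed=0, max_epochs=2), phase="delay")


def test_checkpoint_round_trip(tmp_path, trained_dual, small_splits):
    _, _, te = small_splits
    path = tmp_path / "model.ckpt"
    trained_dual.save(path)
    back = TrainedModel.load(path)
    np.testing.assert_allclose(
        back.predict_scores(te), trained_dual.predict_scores(te), atol=1e-12
    )
    assert back.phase == "dual" and back.best_epoch == trained_dual.best_epoch
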