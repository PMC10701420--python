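"""Loss definitions, the adversarial minimax wiring, and both phases."""

import numpy as np
import pytest

from focusloc import autodiff as ad
from focusloc.autodiff import Tensor
from focusloc.network import FocusNet, ModelConfig
from focusloc.synthetic import generate_dataset
from focusloc.preprocess import preprocess_segments
from focusloc.training import (LossWeights, TrainConfig, TrainingData,
                               class_weights, evaluate_losses, finetune,
                               loss_cls, loss_mse, loss_pd,
                               parameter_checksum, pretrain, weighted_ce)

RNG = np.random.default_rng(11)


def small_net(width=64, n_patients=5, seed=0):
    return FocusNet(np.random.default_rng(seed), width=width,
                    n_patients=n_patients)


def tiny_data(tiny_cfg, patients=None):
    segs = preprocess_segments(generate_dataset(tiny_cfg))
    if patients is not None:
        segs = [s for s in segs if s.patient_id in patients]
    return TrainingData.from_segments(segs)


class TestClassWeights:
    @pytest.mark.parametrize("counts,expected", [
        ((50, 50), (0.5, 0.5)),
        ((1, 15), (0.9375, 0.0625)),
        ((9, 1), (0.1, 0.9)),
    ])
    def test_formula(self, counts, expected):
        np.testing.assert_allclose(class_weights(counts), expected,
                                   atol=1e-12)

    def test_binary_weights_sum_to_one(self):
        w = class_weights((7, 13))
        assert w.sum() == pytest.approx(1.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights((5, 0))


class TestWeightedCE:
    def test_balanced_weights_halve_standard_ce(self):
        probs = np.array([[0.8, 0.2], [0.3, 0.7], [0.6, 0.4]])
        labels = np.array([0, 1, 1])
        standard = float(np.mean(-np.log(
            probs[np.arange(3), labels])))
        assert weighted_ce(probs, labels, np.array([0.5, 0.5])) == \
            pytest.approx(0.5 * standard, abs=1e-10)

    def test_perfect_prediction_zero(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert weighted_ce(probs, np.array([0, 1]),
                           np.array([0.9, 0.1])) == 0.0

    def test_direct_substitution_imbalanced(self):
        # true class 2 (index 1), p = (0.3, 0.7), w = (0.9375, 0.0625)
        val = weighted_ce(np.array([[0.3, 0.7]]), np.array([1]),
                          np.array([0.9375, 0.0625]))
        assert val == pytest.approx(-0.0625 * np.log(0.7), abs=1e-10)
        assert val == pytest.approx(0.02229, abs=1e-4)

    def test_zero_probability_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            val = weighted_ce(np.array([[1.0, 0.0]]), np.array([1]),
                              np.array([0.5, 0.5]))
        assert np.isfinite(val)


class TestLossForms:
    def test_uniform_predictions_give_two_ln2(self):
        net = small_net()
        net.classifier.fc3.weight.data[...] = 0.0
        net.classifier.fc3.bias.data[...] = 0.0
        X = RNG.normal(size=(4, 64))
        y = np.array([0, 1, 0, 1])
        val = loss_cls(net, X, y, np.array([1, 0, 3, 2])).item()
        assert val == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_identity_perm_inert_on_standardized_input(self):
        """With zeroed embedding convs and z-scored input, identity-perm
        SR is (up to ε) the identity, so the clean and SR paths agree:
        L_mse ≈ 0 and the two CE terms coincide."""
        cfg = ModelConfig(n_embed=3, se_reduction=4)
        net = FocusNet(np.random.default_rng(0), width=64, n_patients=3,
                       cfg=cfg)
        net.embedding.use_bn = False
        for conv in (net.embedding.conv1, net.embedding.conv2):
            conv.weight.data[...] = 0.0
            conv.bias.data[...] = 0.0
        X = RNG.normal(size=(4, 64))
        X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1,
                                                        keepdims=True)
        identity = np.arange(4)
        assert loss_mse(net, X, identity).item() < 1e-8
        y = np.array([0, 1, 1, 0])
        two_path = loss_cls(net, X, y, identity).item()
        probs = Tensor(X)
        single = ad.cross_entropy_logits(
            net.classifier(net.extractor(net.embedding(probs))), y).item()
        assert two_path == pytest.approx(2 * single, rel=1e-4)

    def test_mse_loss_nonnegative(self):
        net = small_net()
        X = RNG.normal(size=(6, 64))
        assert loss_mse(net, X, RNG.permutation(6)).item() >= 0.0

    def test_uniform_discriminator_gives_ln_n_patients(self):
        net = small_net(n_patients=5)
        net.discriminator.fc2.weight.data[...] = 0.0
        net.discriminator.fc2.bias.data[...] = 0.0
        X = RNG.normal(size=(4, 64))
        d = np.array([0, 1, 2, 3])
        assert loss_pd(net, X, d).item() == pytest.approx(np.log(5),
                                                          abs=1e-12)

    def test_single_patient_batch_warns(self):
        net = small_net()
        with pytest.warns(UserWarning, match="single-patient"):
            loss_pd(net, RNG.normal(size=(3, 64)), np.zeros(3, int))

    def test_unknown_patient_rejected(self):
        net = small_net(n_patients=2)
        with pytest.raises(ValueError, match="vocabulary"):
            loss_pd(net, RNG.normal(size=(3, 64)), np.array([0, 1, 7]))


class TestMinimaxWiring:
    def test_two_parameter_toy_reversal(self):
        """L(a, b) built as b * grl(a * x): the gradient reaching ``a``
        must be -lambda_r times the gradient without the reversal."""
        x = 1.7
        lam = 0.8
        a1 = Tensor(np.array(0.5), requires_grad=True)
        b1 = Tensor(np.array(-1.3), requires_grad=True)
        (b1 * (a1 * x)).backward()
        a2 = Tensor(np.array(0.5), requires_grad=True)
        b2 = Tensor(np.array(-1.3), requires_grad=True)
        (b2 * ad.grad_reverse(a2 * x, lam)).backward()
        assert float(a2.grad) == pytest.approx(-lam * float(a1.grad))
        assert float(b2.grad) == pytest.approx(float(b1.grad))

    def test_discriminator_descends_extractor_ascends(self):
        """Finite-difference sign check on the full objective: a step
        along the discriminator gradient decreases L_pd, while the
        gradient on an extractor parameter is the negative of L_pd's
        own derivative there."""
        net = small_net(n_patients=3, seed=4)
        X = RNG.normal(size=(6, 64))
        d = np.array([0, 1, 2, 0, 1, 2])
        lam2 = 0.01

        def objective_lpd():
            return loss_pd(net, X, d, reverse=True)

        loss = objective_lpd()
        net.zero_grad()
        loss.backward()
        # pick one scalar parameter from each head
        p_disc = net.discriminator.fc2.bias
        p_feat = net.extractor.temporal.convs[0].weight
        g_disc = p_disc.grad[0]
        g_feat = p_feat.grad[0, 0, 0]
        eps = 1e-5

        def lpd_value():
            with ad.no_grad():
                return loss_pd(net, X, d).item()

        base = lpd_value()
        p_disc.data[0] += eps
        fd_disc = (lpd_value() - base) / eps
        p_disc.data[0] -= eps
        p_feat.data[0, 0, 0] += eps
        fd_feat = (lpd_value() - base) / eps
        p_feat.data[0, 0, 0] -= eps
        # discriminator head: gradient equals +dL_pd/dtheta (descends)
        assert g_disc == pytest.approx(fd_disc, rel=1e-2, abs=1e-7)
        # extractor: gradient equals -dL_pd/dtheta (ascends L_pd)
        assert g_feat == pytest.approx(-fd_feat, rel=1e-2, abs=1e-7)

    def test_loss_sum_decomposition(self):
        """L_sum reported by the trainer equals
        loss_cls + λ1·loss_mse − λ2·loss_pd on the same batch/params."""
        net = small_net(n_patients=4, seed=9)
        X = RNG.normal(size=(8, 64))
        y = np.array([0, 1] * 4)
        d = np.array([0, 1, 2, 3] * 2)
        perm = RNG.permutation(8)
        w = LossWeights()
        combo = evaluate_losses(net, X, y, d, perm, w)
        expected = (loss_cls(net, X, y, perm).item()
                    + w.lambda1 * loss_mse(net, X, perm).item()
                    - w.lambda2 * loss_pd(net, X, d).item())
        assert combo["L_sum"] == pytest.approx(expected, abs=1e-6)


class TestPretrain:
    def test_seeded_determinism(self, tiny_cfg):
        data = tiny_data(tiny_cfg)
        cfg = TrainConfig(epochs=2, batch_size=20, seed=5)
        h1 = pretrain(data, cfg).history
        h2 = pretrain(data, cfg).history
        for a, b in zip(h1, h2):
            assert a == b

    def test_supervised_limit_loss_decreases(self, tiny_cfg):
        """λ2 = 0 on a single patient's separable data reduces to plain
        supervised training: the training loss falls epoch on epoch."""
        data = tiny_data(tiny_cfg, patients={"P00"})
        state = pretrain(data, TrainConfig(epochs=5, batch_size=20, seed=1),
                         LossWeights(lambda1=0.01, lambda2=0.0))
        losses = [h["L_cls"] for h in state.history]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_divergence_aborts_with_diagnostics(self, tiny_cfg):
        data = tiny_data(tiny_cfg)
        net = small_net(width=data.width)
        net.classifier.fc1.weight.data[0, 0] = np.nan
        with pytest.raises(RuntimeError, match="diverged"):
            pretrain(data, TrainConfig(epochs=1, batch_size=20),
                     model=net)

    def test_single_class_rejected(self, tiny_cfg):
        data = tiny_data(tiny_cfg)
        focal_only = TrainingData(data.X[data.y == 1], data.y[data.y == 1],
                                  data.d[data.y == 1], data.patients)
        with pytest.raises(ValueError, match="both classes"):
            pretrain(focal_only, TrainConfig(epochs=1))

    def test_batch_size_floor(self):
        with pytest.raises(ValueError, match="batch_size"):
            TrainConfig(batch_size=1)


class TestFinetune:
    def test_zero_epochs_is_identity(self, tiny_cfg):
        data = tiny_data(tiny_cfg)
        state = pretrain(data, TrainConfig(epochs=1, batch_size=20, seed=2))
        before = {k: v.copy() for k, v in state.model.state_dict().items()}
        out = finetune(state, data, TrainConfig(epochs=0, batch_size=20))
        for k, v in out.model.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_extractor_frozen_classifier_moves(self, tiny_cfg):
        data = tiny_data(tiny_cfg)
        state = pretrain(data, TrainConfig(epochs=1, batch_size=20, seed=2))
        feat_before = parameter_checksum(state.model.feature_parameters())
        cls_before = parameter_checksum(state.model.classifier_parameters())
        out = finetune(state, data, TrainConfig(epochs=2, batch_size=20))
        assert parameter_checksum(out.model.feature_parameters()) \
            == feat_before
        assert parameter_checksum(out.model.classifier_parameters()) \
            != cls_before

    def test_checkpoint_round_trip(self, tiny_cfg, tmp_path):
        from focusloc.training import TrainState
        data = tiny_data(tiny_cfg)
        state = pretrain(data, TrainConfig(epochs=1, batch_size=20, seed=2))
        path = str(tmp_path / "model.npz")
        state.save(path)
        loaded = TrainState.load(path)
        np.testing.assert_allclose(loaded.model.predict_proba(data.X[:8]),
                                   state.model.predict_proba(data.X[:8]),
                                   atol=1e-12)
        assert loaded.patients == state.patients
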