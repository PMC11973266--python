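"""Loss definitions, gradient routing, and the training loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pointspv import recognition as rec
from pointspv import simulator as sim
from pointspv import training
from pointspv.encoder import encode, encode_for_training, init_encoder
from pointspv.nn import autograd as ag
from pointspv.nn.optim import Adam
from pointspv.training import (LossConfig, LossRecord, PointSPV, collate,
                               combined_loss, evaluate, perceptual_loss,
                               train_step)


class TestPerceptualLoss:
    def test_identical_maps_zero(self, rng):
        f = rng.normal(size=(3, 4, 5))
        assert perceptual_loss(f, f) == 0.0

    def test_single_element_difference(self):
        a = np.zeros((2, 2, 1))
        b = np.zeros((2, 2, 1))
        b[0, 0, 0] = 2.0
        assert perceptual_loss(a, b) == pytest.approx(4.0 / 4.0)

    def test_matches_double_loop_oracle(self, rng):
        a = rng.normal(size=(3, 4, 5))
        b = rng.normal(size=(3, 4, 5))
        total = 0.0
        for i in range(3):
            for j in range(4):
                for k in range(5):
                    total += (a[i, j, k] - b[i, j, k]) ** 2
        assert perceptual_loss(a, b) == pytest.approx(total / 60.0, rel=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            perceptual_loss(rng.normal(size=(2, 2, 2)), rng.normal(size=(2, 2, 3)))


class TestCombinedLoss:
    def test_perceptual_only_equals_gamma(self):
        assert combined_loss(1.0, 0.0) == pytest.approx(0.75)

    def test_cross_entropy_only_equals_complement(self):
        assert combined_loss(0.0, 1.0) == pytest.approx(0.25)

    @settings(max_examples=50, derandomize=True)
    @given(x=st.floats(0, 10, allow_nan=False), g=st.floats(0, 1, allow_nan=False))
    def test_equal_terms_invariant_under_gamma(self, x, g):
        assert combined_loss(x, x, g) == pytest.approx(x)

    @pytest.mark.parametrize("g", [-0.1, 1.1])
    def test_gamma_out_of_range(self, g):
        with pytest.raises(ValueError):
            combined_loss(1.0, 1.0, g)


@pytest.fixture(scope="module")
def routing_setup(tiny_patch_pairs, tiny_encoder_config, tiny_sim_config):
    """Fresh encoder + pretrain-free units + one collated batch, eval mode
    so repeated forwards are bit-reproducible."""
    train_pairs, _ = tiny_patch_pairs

    def build(seed=0):
        encoder = init_encoder(tiny_encoder_config, rng_seed=seed)
        backbone = rec.make_backbone("surrogate", n_classes=2, rng_seed=seed + 1)
        blind, sighted = rec.make_units(backbone, None, tiny_sim_config.frame_size)
        encoder.eval()
        blind.eval()
        batch = collate(train_pairs[:8])
        return encoder, blind, sighted, batch

    return build


def _ce_only_grads(encoder, blind, batch, sim_config):
    """Reference gradients of the bare cross-entropy through the pipeline."""
    patches, _, labels = batch
    for p in list(encoder.parameters()) + list(blind.parameters()):
        p.zero_grad()
    hard, _ = encode_for_training(encoder, patches)
    frames = sim.simulate_tensor(hard, sim_config)
    _, logits = rec.blind_forward_tensor(blind, frames)
    ag.cross_entropy_logits(logits, labels).backward()
    enc_g = [None if p.grad is None else p.grad.copy() for p in encoder.parameters()]
    cls_g = [None if p.grad is None else p.grad.copy()
             for p in blind.classifier.parameters()]
    for p in list(encoder.parameters()) + list(blind.parameters()):
        p.zero_grad()
    return enc_g, cls_g


class TestGradientRouting:
    def test_record_satisfies_blending_identity(self, routing_setup, tiny_sim_config):
        encoder, blind, sighted, batch = routing_setup()
        r = train_step(encoder, blind, sighted, batch, LossConfig(), tiny_sim_config)
        assert r.L == pytest.approx(0.75 * r.L_P + 0.25 * r.L_CE, abs=1e-9)

    def test_sighted_weights_bit_identical_after_step(self, routing_setup, tiny_sim_config):
        encoder, blind, sighted, batch = routing_setup()
        before = {k: v.copy() for k, v in sighted.extractor.state_dict().items()}
        opt = Adam(list(encoder.parameters()) + list(blind.parameters()), lr=1e-3)
        train_step(encoder, blind, sighted, batch, LossConfig(), tiny_sim_config, opt)
        after = sighted.extractor.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    @pytest.mark.parametrize("gamma", [0.75, 1.0])
    def test_classifier_gradient_is_pure_cross_entropy(self, routing_setup,
                                                       tiny_sim_config, gamma):
        """The classifier's update direction comes solely from L_CE, for
        any blending weight (including gamma=1 where the blended loss
        contains no cross-entropy term at all)."""
        encoder, blind, sighted, batch = routing_setup()
        _, cls_ref = _ce_only_grads(encoder, blind, batch, tiny_sim_config)
        train_step(encoder, blind, sighted, batch, LossConfig(gamma=gamma),
                   tiny_sim_config)
        for p, g in zip(blind.classifier.parameters(), cls_ref):
            np.testing.assert_allclose(p.grad, g, rtol=1e-5, atol=1e-8)

    def test_gamma_zero_encoder_gradient_is_cross_entropy_only(self, routing_setup,
                                                               tiny_sim_config):
        encoder, blind, sighted, batch = routing_setup()
        enc_ref, _ = _ce_only_grads(encoder, blind, batch, tiny_sim_config)
        r = train_step(encoder, blind, sighted, batch, LossConfig(gamma=0.0),
                       tiny_sim_config)
        assert r.L_P > 0  # still reported
        for p, g in zip(encoder.parameters(), enc_ref):
            np.testing.assert_allclose(p.grad, g, rtol=1e-5, atol=1e-8)

    def test_end_to_end_gradient_reaches_encoder(self, routing_setup, tiny_sim_config):
        encoder, blind, sighted, batch = routing_setup()
        train_step(encoder, blind, sighted, batch, LossConfig(), tiny_sim_config)
        g = encoder.layer_groups[0][0].weight.grad
        assert g is not None and np.linalg.norm(g) > 0

    def test_empty_batch_rejected(self, routing_setup, tiny_sim_config):
        encoder, blind, sighted, _ = routing_setup()
        with pytest.raises(ValueError):
            train_step(encoder, blind, sighted, [], LossConfig(), tiny_sim_config)


class TestEvaluate:
    def test_agrees_with_per_patch_oracle(self, routing_setup, tiny_patch_pairs,
                                          tiny_sim_config):
        encoder, blind, _, _ = routing_setup()
        _, val_pairs = tiny_patch_pairs
        acc = evaluate(encoder, blind, val_pairs, tiny_sim_config)
        correct = 0
        for pair in val_pairs:
            frame = sim.simulate(encode(encoder, pair.patch), tiny_sim_config)
            correct += int(np.argmax(rec.classify(blind, frame)) == pair.label)
        assert acc == pytest.approx(correct / len(val_pairs))

    def test_deterministic(self, routing_setup, tiny_patch_pairs, tiny_sim_config):
        encoder, blind, _, _ = routing_setup()
        _, val_pairs = tiny_patch_pairs
        assert (evaluate(encoder, blind, val_pairs, tiny_sim_config)
                == evaluate(encoder, blind, val_pairs, tiny_sim_config))

    def test_empty_set_rejected(self, routing_setup, tiny_sim_config):
        encoder, blind, _, _ = routing_setup()
        with pytest.raises(ValueError):
            evaluate(encoder, blind, [], tiny_sim_config)


class TestFit:
    def make_model(self, pairs, enc_cfg, sim_cfg, **cfg_kw):
        train_pairs, val_pairs = pairs
        kw = dict(learning_rate=1e-3, batch_size=8, epochs=1, rng_seed=0)
        kw.update(cfg_kw)
        return PointSPV(train_pairs, val_pairs, n_classes=2,
                        encoder_config=enc_cfg, sim_config=sim_cfg,
                        config=LossConfig(**kw))

    def test_zero_epochs_returns_initialized_units(self, tiny_patch_pairs,
                                                   tiny_encoder_config, tiny_sim_config):
        res = self.make_model(tiny_patch_pairs, tiny_encoder_config,
                              tiny_sim_config, epochs=0).fit()
        assert res.records == []
        assert res.encoder is not None and res.blind is not None

    def test_one_epoch_records_and_identity(self, tiny_patch_pairs,
                                            tiny_encoder_config, tiny_sim_config):
        res = self.make_model(tiny_patch_pairs, tiny_encoder_config,
                              tiny_sim_config).fit()
        assert len(res.records) == 1
        r = res.records[0]
        assert r.L == pytest.approx(0.75 * r.L_P + 0.25 * r.L_CE, abs=1e-9)
        assert 0.0 <= r.val_accuracy <= 1.0
        assert "val_acc" in res.summary()

    def test_fit_deterministic_for_fixed_seed(self, tiny_patch_pairs,
                                              tiny_encoder_config, tiny_sim_config):
        a = self.make_model(tiny_patch_pairs, tiny_encoder_config, tiny_sim_config).fit()
        b = self.make_model(tiny_patch_pairs, tiny_encoder_config, tiny_sim_config).fit()
        assert [(r.L_P, r.L_CE, r.val_accuracy) for r in a.records] == \
               [(r.L_P, r.L_CE, r.val_accuracy) for r in b.records]
        sa, sb = a.encoder.state_dict(), b.encoder.state_dict()
        for k in sa:
            np.testing.assert_array_equal(sa[k], sb[k])

    def test_predict_returns_simplex(self, tiny_patch_pairs, tiny_encoder_config,
                                     tiny_sim_config):
        res = self.make_model(tiny_patch_pairs, tiny_encoder_config,
                              tiny_sim_config, epochs=0).fit()
        p = res.predict(tiny_patch_pairs[1][0].patch)
        assert p.shape == (2,) and abs(p.sum() - 1.0) < 1e-6
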