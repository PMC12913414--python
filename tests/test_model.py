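"""Model contracts: projection, encoders/decoders, cross-modal paths, losses."""

import numpy as np
import pytest

from alignnet.model import (AlignNet, ModelConfig, contrastive_loss,
                            reconstruction_loss)


@pytest.fixture
def model(tiny_cfg):
    return AlignNet(tiny_cfg, seed=0)


def _spikes(cfg, n=3, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    return (scale * rng.poisson(0.5, (n, cfg.n_channels, cfg.n_time))).astype(np.float32)


def _behavior(cfg, n=3, seed=1):
    return np.random.default_rng(seed).normal(
        size=(n, cfg.behavior_dim, cfg.n_time)).astype(np.float32)


class TestBehaviorProject:
    def test_lifts_to_channel_space(self, model, tiny_cfg):
        out = model.behavior_project(_behavior(tiny_cfg))
        assert out.shape == (3, tiny_cfg.n_channels, tiny_cfg.n_time)

    def test_zero_weights_give_zero_output(self, model, tiny_cfg):
        for lin in (model.proj_fc1, model.proj_fc2):
            lin.weight.data[:] = 0
            lin.bias.data[:] = 0
        out = model.behavior_project(_behavior(tiny_cfg))
        assert np.all(out.data == 0)

    def test_distinct_trials_project_distinctly(self, model, tiny_cfg):
        out = model.behavior_project(_behavior(tiny_cfg, n=2)).data
        a, b = out[0].ravel(), out[1].ravel()
        cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cos < 1.0 - 1e-6

    def test_rejects_wrong_shape(self, model):
        with pytest.raises(ValueError):
            model.behavior_project(np.zeros((3, 3, 10)))


class TestEncoders:
    def test_bottleneck_temporal_length_after_k_halvings(self):
        assert ModelConfig(depth=2).latent_time == 25      # 100 / 2^2
        assert ModelConfig(depth=3).latent_time == 13      # pad to 104, / 2^3

    def test_latent_map_shapes_match_config(self, model, tiny_cfg):
        lat = model.encode_spike(_spikes(tiny_cfg))
        assert lat.h.shape == (3, tiny_cfg.latent_dim, tiny_cfg.latent_time,
                               tiny_cfg.latent_channels)
        assert len(lat.skips) == tiny_cfg.depth

    def test_both_modalities_share_latent_shape(self, model, tiny_cfg):
        ls = model.encode_spike(_spikes(tiny_cfg))
        lb = model.encode_behavior(_behavior(tiny_cfg))
        assert ls.h.shape == lb.h.shape
        for a, b in zip(ls.skips, lb.skips):
            assert a.shape == b.shape

    def test_eval_mode_is_deterministic(self, model, tiny_cfg):
        model.eval()
        x = _spikes(tiny_cfg)
        a = model.encode_spike(x).h.data
        b = model.encode_spike(x).h.data
        assert np.array_equal(a, b)

    def test_silent_and_active_inputs_separate_in_latent(self, model, tiny_cfg):
        model.eval()
        quiet = model.encode_spike(np.zeros_like(_spikes(tiny_cfg))).h.data
        loud = model.encode_spike(_spikes(tiny_cfg, scale=4.0)).h.data
        assert np.linalg.norm(quiet - loud) > 0

    def test_no_builtin_scale_invariance(self, model, tiny_cfg):
        model.eval()
        b = _behavior(tiny_cfg)
        e1 = model.encode_behavior(b).h.data
        e2 = model.encode_behavior(2.0 * b).h.data
        assert not np.allclose(e1, e2)

    def test_config_rejects_indivisible_channels(self):
        with pytest.raises(ValueError):
            ModelConfig(n_channels=60, depth=3)


class TestDecode:
    def test_autoencoder_shape_contracts(self, model, tiny_cfg):
        ls = model.encode_spike(_spikes(tiny_cfg))
        lb = model.encode_behavior(_behavior(tiny_cfg))
        assert model.decode(ls, "spike").shape == (3, tiny_cfg.n_channels,
                                                   tiny_cfg.n_time)
        assert model.decode(lb, "behavior").shape == (3, tiny_cfg.behavior_dim,
                                                      tiny_cfg.n_time)

    def test_cross_modal_paths_are_well_formed(self, model, tiny_cfg):
        ls = model.encode_spike(_spikes(tiny_cfg))
        lb = model.encode_behavior(_behavior(tiny_cfg))
        decode = model.decode(ls, "behavior")
        simulate = model.decode(lb, "spike", nonneg=True)
        assert decode.shape == (3, tiny_cfg.behavior_dim, tiny_cfg.n_time)
        assert simulate.shape == (3, tiny_cfg.n_channels, tiny_cfg.n_time)
        assert np.all(simulate.data >= 0)

    def test_rejects_bad_target_and_bad_skips(self, model, tiny_cfg):
        ls = model.encode_spike(_spikes(tiny_cfg))
        with pytest.raises(ValueError):
            model.decode(ls, "latent")
        ls.skips = ls.skips[:-1]
        with pytest.raises(ValueError):
            model.decode(ls, "spike")

    def test_time_padding_crops_back_exactly(self):
        cfg = ModelConfig(n_channels=8, n_time=10, depth=2, base_width=2,
                          latent_dim=4, proj_hidden=4)   # 10 pads to 12
        m = AlignNet(cfg, seed=0)
        out = m.decode(m.encode_spike(_spikes(cfg)), "spike")
        assert out.shape == (3, 8, 10)


class TestContrastiveLoss:
    def test_single_pair_is_exactly_zero(self):
        z = np.random.default_rng(0).normal(size=(1, 16))
        assert contrastive_loss(z, z.copy()).item() == pytest.approx(0.0, abs=1e-12)

    def test_collapse_gives_log_n(self):
        z = np.ones((4, 8))
        assert contrastive_loss(z, z.copy()).item() == pytest.approx(np.log(4), abs=1e-6)

    def test_matches_bruteforce_direct_sum(self):
        rng = np.random.default_rng(1)
        for n, d in [(2, 5), (4, 16), (7, 3)]:
            hs = rng.normal(size=(n, d))
            hb = rng.normal(size=(n, d))
            tau = 0.07
            got = contrastive_loss(hs, hb, tau).item()
            # brute force, term by term on normalized embeddings
            a = hs / np.linalg.norm(hs, axis=1, keepdims=True)
            b = hb / np.linalg.norm(hb, axis=1, keepdims=True)
            ls = lb = 0.0
            for i in range(n):
                num = np.exp(a[i] @ b[i] / tau)
                ls += -np.log(num / sum(np.exp(a[i] @ b[j] / tau) for j in range(n)))
                lb += -np.log(num / sum(np.exp(a[j] @ b[i] / tau) for j in range(n)))
            want = (ls / n + lb / n) / 2
            assert abs(got - want) < 1e-6

    def test_loss_falls_as_matched_similarity_grows(self):
        # diagonal inner products a, off-diagonal 0 (normalization off)
        eye = np.eye(3)
        weak = contrastive_loss(eye, 0.02 * eye, 0.07, normalize=False).item()
        strong = contrastive_loss(eye, 0.06 * eye, 0.07, normalize=False).item()
        assert strong < weak

    def test_nonnegative_on_random_batches(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            z1, z2 = rng.normal(size=(5, 6)), rng.normal(size=(5, 6))
            assert contrastive_loss(z1, z2).item() >= -1e-9

    def test_rejects_empty_or_mismatched_batches(self):
        with pytest.raises(ValueError):
            contrastive_loss(np.zeros((0, 4)), np.zeros((0, 4)))
        with pytest.raises(ValueError):
            contrastive_loss(np.zeros((3, 4)), np.zeros((2, 4)))


class TestReconstructionLoss:
    def test_identity_is_zero(self):
        x = np.random.default_rng(0).normal(size=(2, 4, 5))
        assert reconstruction_loss(x, x).item() == 0.0

    def test_unit_offset_is_one(self):
        assert reconstruction_loss(np.zeros((3, 3)), np.ones((3, 3))).item() == 1.0

    def test_matches_two_line_oracle(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(4, 7)), rng.normal(size=(4, 7))
        assert abs(reconstruction_loss(x, y).item() - np.mean((x - y) ** 2)) < 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 3)), np.zeros((3, 2)))
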