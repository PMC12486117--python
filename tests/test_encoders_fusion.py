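"""Classical encoders, fusion head, hybrid loss and the training loop."""

import numpy as np
import pytest

from quarg import qenc
from quarg.autodiff import Tensor, concat
from quarg.encoders import (
    FusionHead,
    GenomicEncoder,
    GenomicEncoderConfig,
    ImageEncoder,
    ImageEncoderConfig,
    attention,
    fuse_predict,
)
from quarg.evalsplit import expected_calibration_error
from quarg.train import (
    FusionModel,
    TrainConfig,
    TrainData,
    hybrid_loss,
    hybrid_loss_tensor,
    soft_ece,
    train,
)


@pytest.fixture
def tiny_model():
    return FusionModel(
        ImageEncoderConfig(n_res_blocks=2, base_channels=3, d_img=6, seed=1),
        GenomicEncoderConfig(token_size=3, d_model=8, n_heads=2, n_layers=1, d_gen=6, seed=2),
        qenc.VqcConfig(Q=3, L=1, seed=3),
        head_hidden=8,
        seed=4,
    )


def _tiny_data(n, seed=0, effect=2.0, q=3):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    patches = rng.normal(size=(n, 16, 16)) + effect * 0.3 * y[:, None, None]
    gvec = rng.normal(size=(n, 7))
    gvec[:, 0] += effect * y
    angles = np.clip(rng.uniform(0, np.pi, size=(n, q)) + 0.3 * y[:, None], 0, np.pi)
    return TrainData(patches, gvec, angles, y)


class TestImageEncoder:
    def test_output_dimension_and_determinism(self, rng):
        enc = ImageEncoder(ImageEncoderConfig(2, 4, 7, seed=0))
        x = rng.normal(size=(3, 20, 20))
        z1, z2 = enc.forward(x), enc.forward(x)
        assert z1.shape == (3, 7)
        assert np.array_equal(z1.data, z2.data)

    def test_small_patch_rejected(self, rng):
        enc = ImageEncoder(ImageEncoderConfig(1, 2, 4))
        with pytest.raises(ValueError, match="16"):
            enc.forward(rng.normal(size=(1, 8, 8)))


class TestAttention:
    def test_single_token_returns_value_row(self):
        out = attention(np.array([[2.0]]), np.array([[1.0]]), np.array([[3.0, 4.0]]), 1)
        assert np.allclose(out.data, [[3.0, 4.0]])

    def test_rows_are_convex_combinations(self, rng):
        Q = rng.normal(size=(4, 3))
        K = rng.normal(size=(4, 3))
        V = rng.normal(size=(4, 2))
        out = attention(Q, K, V, 3).data
        lo, hi = V.min(axis=0), V.max(axis=0)
        assert np.all(out >= lo - 1e-9) and np.all(out <= hi + 1e-9)

    def test_two_token_hand_fixture(self):
        """Binary Q/K/V with d_k=1: softmax weights are e/(e+1), 1/(e+1)."""
        Qm = np.array([[1.0], [0.0]])
        Km = np.array([[1.0], [0.0]])
        Vm = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = attention(Qm, Km, Vm, 1).data
        w = np.e / (np.e + 1.0)
        assert np.allclose(out, [[w, 1 - w], [0.5, 0.5]], atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimensions"):
            attention(np.ones((2, 3)), np.ones((2, 4)), np.ones((2, 2)), 3)


class TestGenomicEncoder:
    def test_output_dimension_and_determinism(self, rng):
        enc = GenomicEncoder(GenomicEncoderConfig(4, 16, 4, 2, 9, seed=5))
        g = rng.normal(size=(3, 10))
        z1, z2 = enc.forward(g), enc.forward(g)
        assert z1.shape == (3, 9)
        assert np.array_equal(z1.data, z2.data)

    def test_within_token_permutation_with_permuted_weights(self, rng):
        """Permuting features inside one token and permuting the projection
        rows identically leaves the embedding unchanged."""
        cfg = GenomicEncoderConfig(token_size=3, d_model=8, n_heads=2, n_layers=1, d_gen=5, seed=6)
        enc = GenomicEncoder(cfg)
        g = rng.normal(size=(2, 6))
        z_ref = enc.forward(g).data
        perm = [2, 0, 1]
        enc.params["tok_w"].data = enc.params["tok_w"].data[perm]
        g_perm = g.copy()
        g_perm[:, :3] = g[:, :3][:, perm]
        g_perm[:, 3:] = g[:, 3:][:, perm]
        assert np.allclose(enc.forward(g_perm).data, z_ref, atol=1e-12)

    def test_empty_vector_rejected(self):
        enc = GenomicEncoder(GenomicEncoderConfig(2, 8, 2, 1, 4))
        with pytest.raises(ValueError, match="empty"):
            enc.forward(np.zeros((2, 0)))


class TestFusionHead:
    def test_probability_range_and_zero_weights(self, rng):
        head = FusionHead(d_in=6, hidden=4, seed=0)
        z = Tensor(rng.normal(size=(5, 6)))
        p = head.forward(z).sigmoid().data
        assert np.all((p > 0) & (p < 1))
        for t in head.params.values():
            t.data[...] = 0.0
        assert np.allclose(head.forward(z).sigmoid().data, 0.5)

    def test_quantum_features_reach_the_logit(self, rng):
        head = FusionHead(d_in=2 + 2 + 2, hidden=4, seed=1)
        zi = Tensor(rng.normal(size=(1, 2)))
        zg = Tensor(rng.normal(size=(1, 2)))
        p1 = fuse_predict(zi, zg, Tensor([[0.5, -0.5]]), head).data
        p2 = fuse_predict(zi, zg, Tensor([[-0.5, 0.5]]), head).data
        assert p1 != p2

    def test_dimension_mismatch_rejected(self, rng):
        head = FusionHead(d_in=6, hidden=4)
        with pytest.raises(ValueError, match="dimension"):
            head.forward(Tensor(rng.normal(size=(2, 5))))


class TestHybridLoss:
    def test_lambda_zero_is_mean_cross_entropy(self, rng):
        p = rng.uniform(0.05, 0.95, 20)
        y = rng.integers(0, 2, 20)
        ce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert hybrid_loss(p, y, 0.0) == pytest.approx(ce, abs=1e-12)

    def test_half_probability_gives_ln2(self):
        assert hybrid_loss([0.5], [1], 0.0) == pytest.approx(np.log(2.0))

    def test_confident_correct_loss_vanishes(self):
        assert hybrid_loss([1.0 - 1e-7, 1e-7], [1, 0], 0.0) < 1e-6

    def test_extreme_probabilities_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            val = hybrid_loss([1.0], [0], 0.0)
        assert np.isfinite(val)

    def test_soft_ece_tracks_hard_ece(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            p = r.uniform(0.01, 0.99, 1000)
            y = (r.uniform(size=1000) < p).astype(int)
            gap = abs(soft_ece(p, y, 10) - expected_calibration_error(p, y, 10))
            assert gap < 0.02

    def test_loss_gradient_matches_finite_differences(self, rng):
        p = rng.uniform(0.2, 0.8, 12)
        y = rng.integers(0, 2, 12)
        t = Tensor(p, requires_grad=True)
        hybrid_loss_tensor(t, y, 0.4, 5).backward()
        for i in range(12):
            eps = 1e-6
            pp, pm = p.copy(), p.copy()
            pp[i] += eps
            pm[i] -= eps
            num = (hybrid_loss(pp, y, 0.4, 5) - hybrid_loss(pm, y, 0.4, 5)) / (2 * eps)
            assert t.grad[i] == pytest.approx(num, abs=1e-4, rel=1e-4)


class TestFusionModel:
    def test_checkpoint_roundtrip_identical_predictions(self, tiny_model, tmp_path):
        data = _tiny_data(6)
        ref = tiny_model.predict_proba(data.patches, data.gvec, data.angles)
        path = tmp_path / "ckpt.npz"
        tiny_model.save(path)
        back = FusionModel.load(path)
        again = back.predict_proba(data.patches, data.gvec, data.angles)
        assert np.allclose(again, ref, atol=1e-9)

    def test_parameter_count_reported(self, tiny_model):
        n = tiny_model.n_parameters()
        assert n == sum(p.data.size for p in tiny_model.classical_params()) + tiny_model.theta.size

    def test_distinct_patches_give_distinct_embeddings(self, tiny_model, rng):
        a = rng.normal(size=(1, 16, 16))
        b = a + 1.0
        za = tiny_model.image_encoder.forward(a).data
        zb = tiny_model.image_encoder.forward(b).data
        assert np.linalg.norm(za - zb) > 0


class TestTrainingLoop:
    def test_loss_decreases_and_history_recorded(self, tiny_model):
        data = _tiny_data(40, seed=1)
        val = _tiny_data(20, seed=2)
        cfg = TrainConfig(lambda_cal=0.1, max_epochs=4, patience=4, batch_size=20,
                          lr=0.02, seed=0)
        model, history = train(tiny_model, data, val, cfg)
        assert len(history) <= 4 and len(history) >= 1
        init_loss = history[0]["train_loss"]
        assert history[-1]["train_loss"] <= init_loss
        assert all(0.0 <= h["val_auc"] <= 1.0 for h in history)

    def test_deterministic_given_seed(self):
        outs = []
        for _ in range(2):
            model = FusionModel(
                ImageEncoderConfig(1, 2, 4, seed=1),
                GenomicEncoderConfig(3, 8, 2, 1, 4, seed=2),
                qenc.VqcConfig(Q=2, L=1, seed=3),
                head_hidden=4,
                seed=4,
            )
            data = _tiny_data(24, seed=5, q=2)
            val = _tiny_data(12, seed=6, q=2)
            cfg = TrainConfig(max_epochs=2, batch_size=12, seed=7)
            model, _ = train(model, data, val, cfg)
            outs.append(model.predict_proba(val.patches, val.gvec, val.angles))
        assert np.array_equal(outs[0], outs[1])

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            TrainData(np.zeros((0, 16, 16)), np.zeros((0, 3)), np.zeros((0, 2)), np.zeros(0))
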