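import numpy as np
import pytest

from ecgssl.contrastive import (
    ContrastiveBatchEmbedding,
    ContrastivePretrainer,
    EncoderConfig,
    ProjectionConfig,
    build_encoder,
    build_projection,
    cosine_sim,
    encoder_forward,
    load_weights,
    nt_xent_loss,
    projection_forward,
    save_weights,
)
from ecgssl.records import SegmentSet


def brute_force_nt_xent(Z, tau):
    """Independent oracle: explicit double loop over anchors and denominators."""
    M = Z.shape[0]
    U = Z / np.linalg.norm(Z, axis=1, keepdims=True)
    total = 0.0
    for i in range(M):
        p = i + 1 if i % 2 == 0 else i - 1
        num = np.exp(U[i] @ U[p] / tau)
        den = sum(np.exp(U[i] @ U[j] / tau) for j in range(M) if j != i)
        total += -np.log(num / den)
    return total / M


class TestEncoderConfig:
    def test_kernel_ordering_enforced(self):
        with pytest.raises(ValueError):
            EncoderConfig(input_length=1280, kernels=(8, 16, 32))

    def test_too_short_input_names_block(self):
        with pytest.raises(ValueError, match="block"):
            EncoderConfig(input_length=8, pool_size=4)

    def test_output_width_shape_arithmetic(self):
        cfg = EncoderConfig(input_length=2560)
        assert cfg.output_positions == 2560 // 64
        assert cfg.output_width == 40 * 80


class TestBuildEncoder:
    def test_layer_inventory(self):
        cfg = EncoderConfig(input_length=2560)
        enc = build_encoder(cfg, seed=0)
        names = [l.name for l in enc.layers]
        for i in (1, 2, 3):
            assert f"block{i}_conv" in names
            assert f"block{i}_pool" in names
            assert f"block{i}_dropout" in names
        assert "dense80" in names and "flatten" in names

    def test_deterministic_init(self):
        cfg = EncoderConfig(input_length=1280)
        w1 = build_encoder(cfg, seed=3).get_weights()
        w2 = build_encoder(cfg, seed=3).get_weights()
        assert all(np.array_equal(w1[k], w2[k]) for k in w1)

    def test_first_conv_kernel_shape(self):
        enc = build_encoder(EncoderConfig(input_length=1280), seed=0)
        W = enc.get_weights()["block1_conv/W"]
        assert W.shape == (1, 32, 32)  # (in-channels, taps, filters)


class TestEncoderForward:
    def test_eval_mode_deterministic(self):
        cfg = EncoderConfig(input_length=256, pool_size=2)
        enc = build_encoder(cfg, seed=1)
        X = np.random.default_rng(0).normal(size=(4, 256))
        assert np.array_equal(encoder_forward(enc, X), encoder_forward(enc, X))

    def test_zero_input_zero_output(self):
        cfg = EncoderConfig(input_length=256, pool_size=2)
        enc = build_encoder(cfg, seed=1)  # biases start at zero
        h = encoder_forward(enc, np.zeros((3, 256)))
        assert np.all(h == 0)

    def test_output_width_matches_config(self):
        cfg = EncoderConfig(input_length=1280)
        enc = build_encoder(cfg, seed=2)
        h = encoder_forward(enc, np.random.default_rng(1).normal(size=(2, 1280)))
        assert h.shape == (2, cfg.output_width)

    def test_length_mismatch_rejected(self):
        cfg = EncoderConfig(input_length=256, pool_size=2)
        enc = build_encoder(cfg, seed=1)
        with pytest.raises(Exception):
            encoder_forward(enc, np.zeros((2, 257)))
        # channel/shape errors surface from the first conv


class TestProjection:
    def test_softmax_variant_rows_on_simplex(self):
        p = build_projection(ProjectionConfig(activation="softmax"), 160, seed=0)
        h = np.random.default_rng(0).normal(size=(6, 160))
        emb = projection_forward(p, h, activation="softmax")
        assert np.allclose(emb.Z.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(emb.Z > 0) and np.all(emb.Z < 1)

    def test_softmax_preserves_logit_ranking(self):
        p = build_projection(ProjectionConfig(), 40, seed=1)
        h = np.random.default_rng(2).normal(size=(4, 40))
        logits = p.forward(h.astype(np.float32))
        emb = projection_forward(p, h, activation="softmax")
        assert np.array_equal(np.argsort(logits, axis=1), np.argsort(emb.Z, axis=1))


class TestCosineSim:
    def test_self_similarity_is_one(self):
        z = np.array([0.3, -1.2, 4.0])
        assert cosine_sim(z, z) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert cosine_sim([1.0, 0.0], [0.0, 5.0]) == pytest.approx(0.0)

    def test_closed_form_45_degrees(self):
        assert cosine_sim([1.0, 0.0], [1.0, 1.0]) == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_sim([0.0, 0.0], [1.0, 0.0])


class TestNtXent:
    def test_single_pair_loss_is_zero(self):
        Z = np.random.default_rng(0).normal(size=(2, 8))
        assert nt_xent_loss(Z, tau=0.5) == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            N = int(rng.integers(1, 9))
            d = int(rng.choice([4, 16]))
            tau = float(rng.choice([0.1, 0.5, 1.0]))
            Z = rng.normal(size=(2 * N, d))
            assert abs(nt_xent_loss(Z, tau) - brute_force_nt_xent(Z, tau)) < 1e-9

    def test_invariant_under_pair_permutation(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(12, 6))
        pairs = Z.reshape(6, 2, 6)
        perm = rng.permutation(6)
        Zp = pairs[perm].reshape(12, 6)
        assert nt_xent_loss(Z, 0.3) == pytest.approx(nt_xent_loss(Zp, 0.3), abs=1e-12)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(8, 5))
        tau = 0.4
        _, dZ = nt_xent_loss(Z, tau, return_grad=True)
        eps = 1e-6
        for i, j in [(0, 0), (3, 2), (7, 4)]:
            Zp, Zm = Z.copy(), Z.copy()
            Zp[i, j] += eps
            Zm[i, j] -= eps
            num = (nt_xent_loss(Zp, tau) - nt_xent_loss(Zm, tau)) / (2 * eps)
            assert abs(num - dZ[i, j]) < 1e-7

    def test_invalid_inputs_rejected(self):
        Z = np.random.default_rng(0).normal(size=(4, 3))
        with pytest.raises(ValueError):
            nt_xent_loss(Z, tau=0.0)
        with pytest.raises(ValueError):
            nt_xent_loss(np.ones((3, 3)), tau=0.5)

    def test_batch_embedding_container_validates(self):
        with pytest.raises(ValueError):
            ContrastiveBatchEmbedding(Z=np.ones((3, 4)))
        emb = ContrastiveBatchEmbedding(Z=np.ones((6, 4)))
        assert emb.N == 3


def _tiny_segments(n=48, L=256, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(L) / 256.0
    rows = [np.sin(2 * np.pi * (2 + (i % 3) * 4) * t) + 0.1 * rng.normal(size=L)
            for i in range(n)]
    return SegmentSet(
        segments=np.asarray(rows), labels=np.arange(n) % 3,
        subject_ids=np.array([f"s{i % 2}" for i in range(n)]), fs=256.0, window_s=1.0,
    )


@pytest.fixture(scope="module")
def tiny_pretrained():
    segs = _tiny_segments()
    est = ContrastivePretrainer(
        epochs=4, batch_size=16, pool_size=2, random_state=5
    ).fit(segs)
    return segs, est


class TestPretrainer:
    def test_loss_history_length_and_decrease(self, tiny_pretrained):
        _, est = tiny_pretrained
        assert len(est.loss_history_) == 4
        assert est.loss_history_[-1] < est.loss_history_[0]

    def test_labels_never_used(self):
        segs = _tiny_segments()
        shuffled = SegmentSet(
            segments=segs.segments,
            labels=np.random.default_rng(9).permutation(segs.labels),
            subject_ids=segs.subject_ids, fs=segs.fs, window_s=segs.window_s,
        )
        kw = dict(epochs=2, batch_size=16, pool_size=2, random_state=5)
        a = ContrastivePretrainer(**kw).fit(segs)
        b = ContrastivePretrainer(**kw).fit(shuffled)
        assert a.loss_history_ == b.loss_history_

    def test_transform_shape_and_determinism(self, tiny_pretrained):
        segs, est = tiny_pretrained
        h = est.transform(segs)
        assert h.shape == (len(segs), est.encoder_config_.output_width)
        assert np.array_equal(h, est.transform(segs))

    def test_weight_shapes_invariant_to_batch_and_augmentation(self):
        segs = _tiny_segments(n=24)
        kw = dict(epochs=1, pool_size=2, random_state=0)
        w1 = ContrastivePretrainer(batch_size=8, augmentation="negate", **kw).fit(segs).encoder_weights_
        w2 = ContrastivePretrainer(batch_size=12, augmentation="timewarp+scale", **kw).fit(segs).encoder_weights_
        assert {k: v.shape for k, v in w1.items()} == {k: v.shape for k, v in w2.items()}

    def test_batch_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            ContrastivePretrainer(batch_size=1).fit(_tiny_segments(n=8))

    def test_weights_roundtrip(self, tiny_pretrained, tmp_path):
        _, est = tiny_pretrained
        path = tmp_path / "w.npz"
        save_weights(est.encoder_weights_, path)
        back = load_weights(path)
        assert set(back) == set(est.encoder_weights_)
        assert all(np.array_equal(back[k], est.encoder_weights_[k]) for k in back)

    def test_sklearn_param_interface(self):
        est = ContrastivePretrainer()
        params = est.get_params()
        assert params["temperature"] == 0.1
        est.set_params(temperature=0.5)
        assert est.temperature == 0.5
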