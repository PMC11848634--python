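import numpy as np
import pytest

from contactseer.autodiff import Tensor
from contactseer.model import (
    ContactTransformer,
    ModelConfig,
    ReshapeSpec,
    extract_uppertri,
    focal_loss,
    make_reshape_spec,
    n_interactions,
    patchify,
    predict,
    reconstruct_symmetric,
    train,
    unpatchify,
)

DESK = dict(scale=0.125, lr=1e-3, batch_size=4, seed=0)


def tiny_model(K_R=128, K_h=6, **kw):
    cfg = ModelConfig(**{**DESK, **kw})
    spec = make_reshape_spec(K_R, np.zeros(K_R))
    return ContactTransformer(cfg, spec, K_h)


class TestReshapeSpec:
    def test_square_factorization(self):
        spec = make_reshape_spec(6400)
        assert (spec.K_used, spec.m, spec.n) == (6400, 10, 10)
        assert spec.input_shape == (80, 80)

    def test_prime_patch_size_degenerates_to_strip(self):
        spec = make_reshape_spec(6464)
        assert spec.K_used == 6464 and (spec.m, spec.n) == (1, 101)
        assert spec.input_shape == (8, 808)

    def test_truncation_drops_lowest_count_genes(self):
        totals = np.arange(6463, dtype=float)
        spec = make_reshape_spec(6463, totals)
        assert spec.K_used == 6400
        assert spec.dropped_gene_indices == list(range(63))

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            make_reshape_spec(63)


class TestPatchify:
    @pytest.mark.parametrize("m,n", [(1, 1), (2, 3), (4, 4)])
    def test_always_64_patches_and_inverse(self, m, n, rng):
        x = rng.normal(size=(8 * m, 8 * n))
        patches = patchify(x, m, n)
        assert patches.shape == (64, m * n)
        np.testing.assert_array_equal(unpatchify(patches, m, n), x)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            patchify(np.zeros((8, 9)), 1, 1)

    def test_patch_order_is_row_major(self):
        x = np.arange(64).reshape(8, 8).astype(float)  # m = n = 1
        patches = patchify(x, 1, 1)
        np.testing.assert_array_equal(patches.ravel(), np.arange(64))


class TestUpperTriCodec:
    def test_row_major_ordering(self):
        c = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        np.testing.assert_array_equal(extract_uppertri(c), [1, 2, 3])

    def test_single_bin_gives_empty_vector(self):
        assert extract_uppertri(np.zeros((1, 1))).size == 0

    @pytest.mark.parametrize("k", [1, 2, 5, 9])
    @pytest.mark.parametrize("diag", [False, True])
    def test_round_trip_exact(self, k, diag, rng):
        m = rng.poisson(3, size=(k, k)).astype(float)
        m = np.triu(m, 0 if diag else 1)
        m = m + np.triu(m, 1).T
        vec = extract_uppertri(m, diag)
        assert vec.size == n_interactions(k, diag)
        np.testing.assert_array_equal(reconstruct_symmetric(vec, k, diag), m)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            extract_uppertri(np.zeros((2, 3)))


class TestFocalLoss:
    def test_gamma_zero_reduces_to_mean_sse(self, rng):
        pred = rng.normal(size=(5, 7))
        target = rng.normal(size=(5, 7))
        loss = focal_loss(Tensor(pred), target, gamma=0.0)
        expected = ((pred - target) ** 2).sum(axis=1).mean()
        assert float(loss.data) == pytest.approx(expected, rel=1e-12)

    def test_perfect_prediction_gives_zero(self):
        x = np.ones((3, 4))
        assert float(focal_loss(Tensor(x), x, 2.0).data) == 0.0

    def test_unit_sse_gamma_two_value(self):
        # one sample with squared-error sum exactly 1
        pred = np.array([[1.0]])
        target = np.array([[0.0]])
        loss = float(focal_loss(Tensor(pred), target, 2.0).data)
        assert loss == pytest.approx((1 - np.exp(-1)) ** 2, abs=1e-9)

    def test_focal_never_exceeds_plain_loss(self, rng):
        for _ in range(1000):
            pred = rng.normal(size=(3, 5))
            target = rng.normal(size=(3, 5))
            plain = float(focal_loss(Tensor(pred), target, 0.0).data)
            focal = float(focal_loss(Tensor(pred), target, 2.0).data)
            assert focal <= plain + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(Tensor(np.zeros((2, 3))), np.zeros((3, 2)), 1.0)


class TestForward:
    def test_output_length_matches_codec(self):
        model = tiny_model(K_h=6)
        out = model.forward(np.zeros(128))
        assert out.shape == (1, 15)

    def test_deterministic_eval(self, rng):
        model = tiny_model()
        g = rng.poisson(5, 128).astype(float)
        a = model.forward(g).data
        b = model.forward(g).data
        np.testing.assert_array_equal(a, b)

    def test_wrong_input_length_rejected(self):
        model = tiny_model()
        with pytest.raises(ValueError):
            model.forward(np.zeros(100))

    def test_softplus_head_is_nonnegative(self, rng):
        model = tiny_model()
        out = model.forward(rng.normal(size=128)).data
        assert (out >= 0).all()

    def test_permuting_within_patch_changes_output(self, rng):
        model = tiny_model()
        g = rng.poisson(5, 128).astype(float)
        g2 = g.copy()
        g2[[0, 1]] = g2[[1, 0]]  # both genes live in patch 0 (m*n = 2)
        if np.array_equal(g, g2):
            g2[0] += 1
        assert not np.array_equal(model.forward(g).data, model.forward(g2).data)


class TestTraining:
    def make_dataset(self, rng, n=8, K_R=128, K_h=5):
        ds = []
        for _ in range(n):
            g = rng.poisson(5, K_R).astype(float)
            c = rng.poisson(2, (K_h, K_h)).astype(float)
            c = np.triu(c, 1) + np.triu(c, 1).T
            ds.append((g, c))
        return ds

    def test_same_seed_reproduces_loss_history(self, rng):
        ds = self.make_dataset(rng)
        cfg = ModelConfig(**DESK)
        _, h1 = train(ds, cfg, epochs=2)
        _, h2 = train(ds, cfg, epochs=2)
        assert h1 == h2

    def test_inconsistent_shapes_rejected_before_training(self, rng):
        ds = self.make_dataset(rng)
        ds.append((np.zeros(64), ds[0][1]))
        with pytest.raises(ValueError):
            train(ds, ModelConfig(**DESK), epochs=1)

    def test_one_step_decreases_loss_on_fixed_batch(self, rng):
        from contactseer.autodiff import Adam
        from contactseer.model import extract_uppertri, focal_loss

        ds = self.make_dataset(rng, n=4)
        cfg = ModelConfig(**DESK, )
        model, _ = train(ds, cfg, epochs=0 or 1)
        x = np.stack([model.prepare_input(g) for g, _ in ds])
        t = np.stack([extract_uppertri(c) for _, c in ds])
        opt = Adam(model.parameters(), lr=1e-4)
        before = float(focal_loss(model.forward(x), t, cfg.gamma).data)
        loss = focal_loss(model.forward(x), t, cfg.gamma)
        opt.zero_grad()
        loss.backward()
        opt.step()
        after = float(focal_loss(model.forward(x), t, cfg.gamma).data)
        assert after < before

    def test_checkpoint_round_trip(self, tmp_path, rng):
        ds = self.make_dataset(rng)
        model, _ = train(ds, ModelConfig(**DESK), epochs=1)
        model.save(tmp_path / "m.npz")
        back = ContactTransformer.load(tmp_path / "m.npz")
        g = ds[0][0]
        np.testing.assert_array_equal(model.forward(g).data,
                                      back.forward(g).data)

    def test_predict_shapes_and_symmetry(self, rng):
        ds = self.make_dataset(rng)
        model, _ = train(ds, ModelConfig(**DESK), epochs=1)
        stack = predict(model, np.stack([g for g, _ in ds]))
        assert stack.n_cells == len(ds)
        for i in range(stack.n_cells):
            m = stack.dense(i)
            np.testing.assert_array_equal(m, m.T)
            assert np.diag(m).sum() == 0


class TestConfig:
    def test_scale_shrinks_widths_to_head_multiples(self):
        cfg = ModelConfig(scale=0.125).scaled()
        assert cfg.encoder_dim == 128 and cfg.encoder_dim % 8 == 0
        assert cfg.decoder_dim == 64
        assert cfg.latent_dim == 128
        assert cfg.encoder_mlp_dim % 8 == 0

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(scale=0.0)
        with pytest.raises(ValueError):
            ModelConfig(gamma=-1)
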