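"""NT-Xent loss (closed forms, oracle, gradients, invariances) and pre-training."""

import numpy as np
import pytest

from tffusion.contrastive import (ContrastiveEncoder, nt_xent_batch,
                                  nt_xent_batch_with_grad, nt_xent_pair)
from tffusion.data import generate_dataset


def double_loop_oracle(Za, Zb, tau):
    """Brute-force O(N^2) evaluation of the symmetrized batch loss."""
    Z = np.vstack([Za, Zb])
    U = Z / np.linalg.norm(Z, axis=1, keepdims=True)
    M = len(Z)
    N = len(Za)

    def pair(i, j):
        num = np.exp(U[i] @ U[j] / tau)
        den = sum(np.exp(U[i] @ U[k] / tau) for k in range(M) if k != i)
        return -np.log(num / den)

    return np.mean([0.5 * (pair(i, i + N) + pair(i + N, i)) for i in range(N)])


class TestLossValues:
    def test_single_pair_identical_projections_loss_zero(self):
        z = np.array([[0.3, -0.7]])
        assert nt_xent_batch(z, z.copy(), 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_two_pair_closed_form(self):
        # pool {e, e, e', e'}: every pair loss is log(1 + 2/e) at tau = 1
        e = np.array([1.0, 0.0])
        ep = np.array([0.0, 1.0])
        va = np.stack([e, ep])
        vb = np.stack([e, ep])
        want = np.log(1 + 2 / np.e)
        assert nt_xent_batch(va, vb, 1.0) == pytest.approx(want, abs=1e-12)
        Z = np.vstack([va, vb])
        assert nt_xent_pair(Z, 0, 2, 1.0) == pytest.approx(want, abs=1e-12)

    def test_all_identical_projections_give_log_2N_minus_1(self):
        for N in (2, 5, 8):
            z = np.tile([0.6, 0.8], (N, 1))
            assert nt_xent_batch(z, z.copy(), 0.2) == pytest.approx(
                np.log(2 * N - 1), abs=1e-9)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(123)
        Za = rng.normal(size=(8, 5))
        Zb = rng.normal(size=(8, 5))
        assert nt_xent_batch(Za, Zb, 0.3) == pytest.approx(
            double_loop_oracle(Za, Zb, 0.3), abs=1e-9)

    def test_loss_decreases_as_positive_similarity_increases(self):
        anchor = np.array([1.0, 0.0])
        negs = np.array([[0.0, 1.0], [-1.0, 0.5]])
        losses = []
        for angle in (1.2, 0.8, 0.4, 0.0):
            pos = np.array([np.cos(angle), np.sin(angle)])
            Z = np.vstack([anchor, negs[0], pos, negs[1]])
            losses.append(nt_xent_pair(Z, 0, 2, 0.5))
        assert (np.diff(losses) < 0).all()

    def test_zero_norm_vector_rejected(self):
        Z = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            nt_xent_pair(Z, 0, 1, 1.0)

    def test_invalid_temperature_rejected(self):
        z = np.ones((2, 2))
        with pytest.raises(ValueError):
            nt_xent_batch(z, z, 0.0)


class TestLossInvariances:
    def test_rotation_invariance(self):
        rng = np.random.default_rng(7)
        Za, Zb = rng.normal(size=(2, 6, 4))
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        assert nt_xent_batch(Za, Zb, 0.4) == pytest.approx(
            nt_xent_batch(Za @ Q, Zb @ Q, 0.4), abs=1e-10)

    def test_joint_pair_permutation_invariance(self):
        rng = np.random.default_rng(8)
        Za, Zb = rng.normal(size=(2, 7, 3))
        perm = rng.permutation(7)
        assert nt_xent_batch(Za, Zb, 0.5) == pytest.approx(
            nt_xent_batch(Za[perm], Zb[perm], 0.5), abs=1e-10)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(9)
        Za = rng.normal(size=(4, 3))
        Zb = rng.normal(size=(4, 3))
        _, ga, gb = nt_xent_batch_with_grad(Za, Zb, 0.25)
        eps = 1e-6
        for arr, g in ((Za, ga), (Zb, gb)):
            for idx in np.ndindex(arr.shape):
                arr[idx] += eps
                fp = nt_xent_batch(Za, Zb, 0.25)
                arr[idx] -= 2 * eps
                fm = nt_xent_batch(Za, Zb, 0.25)
                arr[idx] += eps
                assert np.isclose(g[idx], (fp - fm) / (2 * eps), atol=1e-7)


@pytest.fixture(scope="module")
def tiny_pretrain_data():
    return generate_dataset(n_per_class=20, n_classes=3, window=32,
                            noise_sd=1.0, seed=42)


def tiny_encoder(mode, seed=0, epochs=8):
    return ContrastiveEncoder(mode=mode, batch_size=30, epochs=epochs,
                              learning_rate=1e-3, channels=(4, 8, 16),
                              embed_dim=16, proj_dim=8, fusion_components=16,
                              random_state=seed)


class TestPretrain:
    @pytest.mark.parametrize("mode", ["tf-fc", "time-only", "freq-only"])
    def test_loss_history_has_epoch_length_and_decreases(self, mode,
                                                         tiny_pretrain_data):
        enc = tiny_encoder(mode, epochs=10).fit(tiny_pretrain_data)
        assert len(enc.loss_history_) == 10
        assert enc.loss_history_[-1] < enc.loss_history_[0]

    def test_same_seed_gives_identical_history_and_embeddings(self,
                                                              tiny_pretrain_data):
        a = tiny_encoder("tf-fc", seed=3, epochs=4).fit(tiny_pretrain_data)
        b = tiny_encoder("tf-fc", seed=3, epochs=4).fit(tiny_pretrain_data)
        assert a.loss_history_ == b.loss_history_
        assert np.array_equal(a.transform(tiny_pretrain_data),
                              b.transform(tiny_pretrain_data))

    def test_unknown_mode_rejected(self, tiny_pretrain_data):
        with pytest.raises(ValueError):
            tiny_encoder("wavelet").fit(tiny_pretrain_data)

    def test_too_few_windows_rejected(self, tiny_pretrain_data):
        enc = ContrastiveEncoder(batch_size=1000)
        with pytest.raises(ValueError):
            enc.fit(tiny_pretrain_data)

    def test_transform_before_fit_raises(self, tiny_pretrain_data):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            ContrastiveEncoder().transform(tiny_pretrain_data)


def test_pretraining_beats_random_encoder_linear_probe():
    """A logistic probe on frozen pre-trained embeddings outperforms the
    same probe on a randomly initialized encoder, averaged over 3 seeds."""
    from sklearn.linear_model import LogisticRegression

    from tffusion.benchmark import BENCHMARK, benchmark_splits
    from tffusion.encoder import EncoderConfig, build_encoder

    def probe(emb_tr, ytr, emb_te, yte):
        clf = LogisticRegression(max_iter=2000).fit(emb_tr, ytr)
        return clf.score(emb_te, yte)

    gains = []
    for seed in (1, 2, 3):
        pre, fin, test = benchmark_splits(seed)
        enc = ContrastiveEncoder(
            mode="tf-fc", batch_size=BENCHMARK["pretrain_batch"],
            epochs=15, learning_rate=BENCHMARK["pretrain_lr"],
            channels=BENCHMARK["channels"], embed_dim=BENCHMARK["embed_dim"],
            proj_dim=BENCHMARK["proj_dim"], random_state=seed).fit(pre)
        cfg = EncoderConfig(channels=BENCHMARK["channels"],
                            embed_dim=BENCHMARK["embed_dim"],
                            proj_dim=BENCHMARK["proj_dim"], in_channels=1)
        rand = build_encoder(cfg, np.random.default_rng(seed))
        trained = probe(enc.transform(fin), fin.y, enc.transform(test), test.y)
        random_ = probe(rand.forward(fin.X), fin.y, rand.forward(test.X), test.y)
        gains.append(trained - random_)
    assert np.mean(gains) > 0
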