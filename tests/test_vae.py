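import numpy as np
import pytest
from scipy.stats import multivariate_normal

from lipocomplex.table import DescriptorTable
from lipocomplex.vae import (LatentStats, VAEArchitecture,
                             VAEOversampler, VAETrainConfig,
                             balance_with_vae, decode, encode, generate_pool,
                             init_vae, kl_divergence, reparameterize,
                             train_vae, vae_loss)

ARCH = VAEArchitecture(input_dim=46)


class TestInit:
    def test_biases_exactly_zero(self):
        model = init_vae(ARCH, seed=0)
        for name, p in model.params.items():
            if name.endswith("b"):
                assert np.all(p == 0.0), name

    def test_he_variance_of_sampled_weights(self):
        """Sample variance of a fan-in-25 layer's weights is within 10%
        of 2/25 (Monte-Carlo check over ~10,000 draws)."""
        arch = VAEArchitecture(input_dim=25, encoder_hidden=(400,),
                               latent_dim=2)
        model = init_vae(arch, seed=1)
        w = model.params["enc_W0"]  # 25 x 400 = 10,000 weights
        assert w.size == 10_000
        assert w.var() == pytest.approx(2.0 / 25.0, rel=0.10)
        assert abs(w.mean()) < 0.01

    def test_same_seed_identical_parameters(self):
        a, b = init_vae(ARCH, seed=5), init_vae(ARCH, seed=5)
        assert all(np.array_equal(a.params[k], b.params[k])
                   for k in a.params)

    def test_symmetric_decoder_by_default(self):
        assert ARCH.decoder_hidden == (25, 50)

    def test_non_positive_layer_rejected(self):
        with pytest.raises(ValueError):
            VAEArchitecture(input_dim=10, encoder_hidden=(0,))


class TestEncodeDecode:
    def test_encode_returns_finite_latent_pair(self, rng):
        model = init_vae(ARCH, seed=0)
        stats = encode(model, rng.uniform(0, 1, 46))
        assert stats.mu.shape == (1, 2)
        assert stats.logvar.shape == (1, 2)

    def test_encode_deterministic(self, rng):
        model = init_vae(ARCH, seed=0)
        x = rng.uniform(0, 1, 46)
        a, b = encode(model, x), encode(model, x)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.logvar, b.logvar)

    def test_encode_full_training_batch(self, normalized_splits):
        _, norm_train, _ = normalized_splits
        model = init_vae(ARCH, seed=0)
        stats = encode(model, norm_train.features)
        assert stats.mu.shape == (272, 2)

    def test_encode_dimension_mismatch(self):
        model = init_vae(ARCH, seed=0)
        with pytest.raises(ValueError):
            encode(model, np.zeros(10))

    def test_decode_outputs_strictly_inside_unit_interval(self, rng):
        model = init_vae(ARCH, seed=0)
        out = decode(model, rng.standard_normal((20, 2)))
        assert out.shape == (20, 46)
        assert np.all((out > 0) & (out < 1))

    def test_zero_weight_model_decodes_to_half(self):
        model = init_vae(ARCH, seed=0)
        for k in model.params:
            model.params[k] = np.zeros_like(model.params[k])
        out = decode(model, np.zeros(2))
        assert np.allclose(out, 0.5)

    def test_decode_dimension_mismatch(self):
        model = init_vae(ARCH, seed=0)
        with pytest.raises(ValueError):
            decode(model, np.zeros(3))


class TestReparameterize:
    def test_degenerate_variance_returns_mean(self):
        stats = LatentStats(mu=np.array([1.5, -2.0]),
                            logvar=np.array([-50.0, -50.0]))
        z = reparameterize(stats, seed=0)
        assert np.allclose(z, stats.mu, atol=1e-9)

    def test_monte_carlo_moments(self):
        stats = LatentStats(mu=np.array([0.7, -1.2]),
                            logvar=np.array([0.3, -0.8]))
        rng = np.random.default_rng(4)
        draws = np.vstack([reparameterize(stats, rng)
                           for _ in range(100_000)])
        var = np.exp(stats.logvar).ravel()
        se_mean = np.sqrt(var / 100_000)
        assert np.all(np.abs(draws.mean(0) - stats.mu.ravel())
                      < 3 * se_mean)
        se_var = var * np.sqrt(2 / 100_000)
        assert np.all(np.abs(draws.var(0) - var) < 3 * se_var)

    def test_fixed_seed_reproducible(self):
        stats = LatentStats(mu=np.zeros(2), logvar=np.zeros(2))
        assert np.array_equal(reparameterize(stats, 7),
                              reparameterize(stats, 7))


class TestLoss:
    def test_kl_zero_at_standard_normal_posterior(self):
        stats = LatentStats(mu=np.zeros(2), logvar=np.zeros(2))
        assert kl_divergence(stats) == 0.0

    def test_kl_closed_form_hand_value(self):
        stats = LatentStats(mu=np.array([1.0, 0.0]),
                            logvar=np.array([0.0, 0.0]))
        assert kl_divergence(stats) == pytest.approx(0.5)

    def test_kl_matches_monte_carlo(self):
        """Closed form against a 100,000-sample MC estimate of
        KL(q || N(0, I))."""
        rng = np.random.default_rng(10)
        mu = rng.normal(0, 1.5, 3)
        logvar = rng.normal(0, 0.7, 3)
        stats = LatentStats(mu=mu, logvar=logvar)
        n = 100_000
        sd = np.exp(logvar / 2)
        z = mu + sd * rng.standard_normal((n, 3))
        log_q = multivariate_normal(mu, np.diag(sd ** 2)).logpdf(z)
        log_p = multivariate_normal(np.zeros(3), np.eye(3)).logpdf(z)
        samples = log_q - log_p
        se = samples.std(ddof=1) / np.sqrt(n)
        assert abs(kl_divergence(stats) - samples.mean()) < 3 * se

    def test_kl_nonnegative_property(self, rng):
        for _ in range(200):
            stats = LatentStats(mu=rng.normal(0, 2, 2),
                                logvar=rng.normal(0, 2, 2))
            assert kl_divergence(stats) >= 0.0

    def test_total_combines_weighted_recon_and_kl(self, rng):
        x = rng.uniform(0, 1, 46)
        x_hat = rng.uniform(0.01, 0.99, 46)
        stats = LatentStats(mu=rng.normal(size=2), logvar=np.zeros(2))
        total, recon, kl = vae_loss(x, x_hat, stats, recon_weight=1000.0)
        assert total == pytest.approx(1000.0 * recon + kl)

    def test_loss_invariant_under_consistent_feature_permutation(self, rng):
        x = rng.uniform(0, 1, 46)
        x_hat = rng.uniform(0.01, 0.99, 46)
        stats = LatentStats(mu=np.ones(2), logvar=np.zeros(2))
        perm = rng.permutation(46)
        a = vae_loss(x, x_hat, stats, 1000.0)
        b = vae_loss(x[perm], x_hat[perm], stats, 1000.0)
        assert a == pytest.approx(b)

    def test_out_of_range_target_rejected(self):
        stats = LatentStats(mu=np.zeros(2), logvar=np.zeros(2))
        with pytest.raises(ValueError):
            vae_loss(np.array([1.5]), np.array([0.5]), stats, 1.0)


class TestTraining:
    def test_training_reduces_smoothed_loss(self, trained_vae):
        _, hist = trained_vae
        assert len(hist["total"]) == 5000
        early = hist["total"][:100].mean()
        late = hist["total"][-100:].mean()
        assert late < early

    def test_bit_reproducible_histories(self, normalized_splits):
        _, norm_train, _ = normalized_splits
        cfg = VAETrainConfig(iterations=300, seed=21)
        _, h1 = train_vae(norm_train, config=cfg)
        _, h2 = train_vae(norm_train, config=cfg)
        for key in ("total", "recon", "kl"):
            assert np.array_equal(h1[key], h2[key])

    def test_rejects_unnormalized_input(self, default_dataset):
        with pytest.raises(ValueError):
            train_vae(default_dataset.train,
                      config=VAETrainConfig(iterations=1))

    def test_training_improves_reconstruction(self, trained_vae,
                                              normalized_splits):
        """Round-trip error through the trained autoencoder is far below
        that of a freshly initialized one."""
        model, _ = trained_vae
        _, norm_train, _ = normalized_splits
        X = norm_train.features

        def recon_err(m):
            stats = encode(m, X)
            z = reparameterize(stats, seed=0)
            return float(np.mean((decode(m, z) - X) ** 2))

        untrained = init_vae(ARCH, seed=99)
        assert recon_err(model) < 0.5 * recon_err(untrained)

    def test_latent_classes_form_separated_clusters(self, trained_vae,
                                                    normalized_splits):
        """Posterior means of the two classes cluster apart (silhouette
        above zero), mirroring a well-trained latent space."""
        from sklearn.metrics import silhouette_score
        model, _ = trained_vae
        _, norm_train, _ = normalized_splits
        stats = encode(model, norm_train.features)
        assert silhouette_score(stats.mu, norm_train.labels) > 0.0


class TestGeneration:
    def test_pool_size_and_range(self, trained_vae, normalized_splits):
        model, _ = trained_vae
        _, norm_train, _ = normalized_splits
        minority = norm_train.features[norm_train.labels == 0]
        pool = generate_pool(model, minority, 500, seed=7)
        assert pool.shape == (500, 46)
        assert np.all((pool > 0) & (pool < 1))

    def test_empty_pool_request_rejected(self, trained_vae,
                                         normalized_splits):
        model, _ = trained_vae
        _, norm_train, _ = normalized_splits
        minority = norm_train.features[norm_train.labels == 0]
        with pytest.raises(ValueError):
            generate_pool(model, minority, 0, seed=7)
        with pytest.raises(ValueError):
            generate_pool(model, minority[:0], 10, seed=7)

    def test_pool_rows_have_minority_nearest_neighbors(
            self, trained_vae, normalized_splits):
        """Synthetic rows land in minority territory: at least 80% have
        a minority-class nearest neighbor among original rows."""
        from sklearn.neighbors import NearestNeighbors
        model, _ = trained_vae
        _, norm_train, _ = normalized_splits
        minority = norm_train.features[norm_train.labels == 0]
        pool = generate_pool(model, minority, 500, seed=7)
        nn = NearestNeighbors(n_neighbors=1).fit(norm_train.features)
        idx = nn.kneighbors(pool, return_distance=False).ravel()
        assert np.mean(norm_train.labels[idx] == 0) >= 0.80


class TestBalance:
    def test_paper_counts_balanced_to_358(self, trained_vae,
                                          normalized_splits):
        model, _ = trained_vae
        _, norm_train, _ = normalized_splits
        balanced = balance_with_vae(norm_train, model, 500, seed=7)
        assert balanced.n_samples == 358
        assert balanced.class_counts().as_tuple() == (179, 179)

    def test_original_rows_preserved_verbatim(self, trained_vae,
                                              normalized_splits):
        model, _ = trained_vae
        _, norm_train, _ = normalized_splits
        balanced = balance_with_vae(norm_train, model, 500, seed=7)
        assert np.array_equal(balanced.features[:272], norm_train.features)
        assert np.array_equal(balanced.labels[:272], norm_train.labels)

    def test_already_balanced_returns_input(self, trained_vae):
        model, _ = trained_vae
        X = np.full((6, 46), 0.5)
        t = DescriptorTable(X, [0, 1, 0, 1, 0, 1],
                            [f"f{i}" for i in range(46)])
        out = balance_with_vae(t, model, 10, seed=0)
        assert out.n_samples == 6
        assert np.array_equal(out.features, t.features)

    def test_pool_smaller_than_gap_rejected(self, trained_vae):
        model, _ = trained_vae
        X = np.full((7, 46), 0.5)
        t = DescriptorTable(X, [1, 1, 1, 1, 1, 0, 0],
                            [f"f{i}" for i in range(46)])
        with pytest.raises(ValueError):
            balance_with_vae(t, model, 2, seed=0)  # pool 2 < gap 3


def test_oversampler_estimator_round_trip(normalized_splits):
    _, norm_train, _ = normalized_splits
    est = VAEOversampler(iterations=400, random_state=0)
    X_res, y_res = est.fit_resample(norm_train.features, norm_train.labels)
    assert X_res.shape == (358, 46)
    assert int((y_res == 0).sum()) == int((y_res == 1).sum()) == 179
    assert est.transform_latent(norm_train.features).shape == (272, 2)
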