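"""Variational autoencoder for minority-class augmentation of descriptor
tables.

The VAE maps min-max-normalized descriptor rows through a fully connected
encoder (hidden sizes 50, 25 by default) to a 2-dimensional Gaussian
latent space parameterized by a mean and a log-variance, and decodes
latent samples back through a symmetric decoder with a logistic output so
reconstructions stay in (0, 1).  Hidden layers use ReLU; weights are
He-normal initialized and biases start at zero.

Training minimizes  recon_weight * reconstruction + KL(q(z|x) || N(0, I))
with Adam; an iteration is one step on a shuffled mini-batch of 32 (set
batch_size=None for full-batch steps).  The reconstruction term is
element-summed binary
cross-entropy by default (the data lives in [0,1] and the output is
logistic, making BCE the consistent likelihood); squared error is
available as a config switch.

To balance an imbalanced training split, a pool of synthetic minority
rows is generated by encoding randomly drawn minority rows, sampling
their latent posteriors, and decoding; the class gap is then filled by
drawing from the pool without replacement.  Generated rows always carry
the minority label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from ._nn import Adam, bce_sum, he_normal, relu, relu_grad, sigmoid
from .table import DescriptorTable, concat_tables


@dataclass
class VAEArchitecture:
    input_dim: int
    encoder_hidden: tuple[int, ...] = (50, 25)
    latent_dim: int = 2
    decoder_hidden: tuple[int, ...] | None = None  # default: reversed encoder

    def __post_init__(self) -> None:
        self.encoder_hidden = tuple(int(h) for h in self.encoder_hidden)
        if self.decoder_hidden is None:
            self.decoder_hidden = tuple(reversed(self.encoder_hidden))
        else:
            self.decoder_hidden = tuple(int(h) for h in self.decoder_hidden)
        sizes = (self.input_dim, *self.encoder_hidden, self.latent_dim,
                 *self.decoder_hidden)
        if any(s <= 0 for s in sizes):
            raise ValueError(f"non-positive layer size in {sizes}")


@dataclass
class VAETrainConfig:
    """Training schedule.  An iteration is one Adam step on a shuffled
    mini-batch (batch_size None = full batch)."""

    recon_weight: float = 1000.0
    learning_rate: float = 0.001
    iterations: int = 5000
    batch_size: int | None = 32
    recon_loss: str = "bce"  # or "mse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.recon_weight <= 0:
            raise ValueError("recon_weight must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1 or None")
        if self.recon_loss not in ("bce", "mse"):
            raise ValueError(f"unknown recon_loss {self.recon_loss!r}")


@dataclass
class LatentStats:
    """Posterior mean and log-variance; row-wise for batched input."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.logvar = np.atleast_2d(np.asarray(self.logvar, dtype=float))
        if self.mu.shape != self.logvar.shape:
            raise ValueError("mu and logvar shapes differ")
        if not (np.isfinite(self.mu).all() and np.isfinite(self.logvar).all()):
            raise ValueError("non-finite latent statistics")


@dataclass
class VAEModel:
    arch: VAEArchitecture
    params: dict[str, np.ndarray] = field(default_factory=dict)

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def init_vae(arch: VAEArchitecture, seed: int) -> VAEModel:
    """He-normal weights, exactly-zero biases, deterministic per seed."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    d = arch.input_dim
    for i, h in enumerate(arch.encoder_hidden):
        params[f"enc_W{i}"] = he_normal(rng, d, h)
        params[f"enc_b{i}"] = np.zeros(h)
        d = h
    params["mu_W"] = he_normal(rng, d, arch.latent_dim)
    params["mu_b"] = np.zeros(arch.latent_dim)
    params["lv_W"] = he_normal(rng, d, arch.latent_dim)
    params["lv_b"] = np.zeros(arch.latent_dim)
    d = arch.latent_dim
    for i, h in enumerate(arch.decoder_hidden):
        params[f"dec_W{i}"] = he_normal(rng, d, h)
        params[f"dec_b{i}"] = np.zeros(h)
        d = h
    params["out_W"] = he_normal(rng, d, arch.input_dim)
    params["out_b"] = np.zeros(arch.input_dim)
    return VAEModel(arch=arch, params=params)


def _encode_forward(model: VAEModel, X: np.ndarray):
    p = model.params
    pre, post = [], []
    h = X
    for i in range(len(model.arch.encoder_hidden)):
        a = h @ p[f"enc_W{i}"] + p[f"enc_b{i}"]
        pre.append(a)
        h = relu(a)
        post.append(h)
    mu = h @ p["mu_W"] + p["mu_b"]
    lv = h @ p["lv_W"] + p["lv_b"]
    return mu, lv, pre, post


def _decode_forward(model: VAEModel, Z: np.ndarray):
    p = model.params
    pre, post = [], []
    h = Z
    for i in range(len(model.arch.decoder_hidden)):
        a = h @ p[f"dec_W{i}"] + p[f"dec_b{i}"]
        pre.append(a)
        h = relu(a)
        post.append(h)
    logits = h @ p["out_W"] + p["out_b"]
    return sigmoid(logits), pre, post


def encode(model: VAEModel, x: np.ndarray) -> LatentStats:
    """Posterior statistics for one row or a batch of rows."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != model.arch.input_dim:
        raise ValueError(
            f"input has {X.shape[1]} features, model expects "
            f"{model.arch.input_dim}"
        )
    mu, lv, _, _ = _encode_forward(model, X)
    return LatentStats(mu=mu, logvar=lv)


def reparameterize(stats: LatentStats,
                   seed: int | np.random.Generator) -> np.ndarray:
    """z = mu + exp(logvar / 2) * eps with standard-normal eps."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    eps = rng.standard_normal(stats.mu.shape)
    return stats.mu + np.exp(stats.logvar / 2.0) * eps


def decode(model: VAEModel, z: np.ndarray) -> np.ndarray:
    """Reconstruction in (0, 1) for one latent row or a batch."""
    Z = np.atleast_2d(np.asarray(z, dtype=float))
    if Z.shape[1] != model.arch.latent_dim:
        raise ValueError(
            f"latent input has {Z.shape[1]} dims, model expects "
            f"{model.arch.latent_dim}"
        )
    xhat, _, _ = _decode_forward(model, Z)
    return xhat


def kl_divergence(stats: LatentStats) -> float:
    """Closed-form KL(q || N(0, I)) summed over latent dims and rows:
    -1/2 sum_j (1 + logvar_j - mu_j^2 - exp(logvar_j))."""
    return float(-0.5 * np.sum(
        1.0 + stats.logvar - stats.mu ** 2 - np.exp(stats.logvar)
    ))


def vae_loss(x: np.ndarray, x_hat: np.ndarray, stats: LatentStats,
             recon_weight: float, recon_loss: str = "bce",
             ) -> tuple[float, float, float]:
    """(total, reconstruction, KL) for a single example or a summed batch."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("vae_loss expects normalized targets in [0, 1]")
    if recon_loss == "bce":
        recon = bce_sum(x, x_hat)
    else:
        recon = float(np.sum((x - x_hat) ** 2))
    kl = kl_divergence(stats)
    return recon_weight * recon + kl, recon, kl


def train_vae(train: DescriptorTable | np.ndarray,
              arch: VAEArchitecture | None = None,
              config: VAETrainConfig | None = None,
              ) -> tuple[VAEModel, dict[str, np.ndarray]]:
    """Adam training for exactly ``config.iterations`` steps, each on a
    freshly shuffled mini-batch (or the full batch if
    ``config.batch_size`` is None).

    Returns the trained model and per-iteration loss history with keys
    ``total``, ``recon``, ``kl`` (per-sample averages over the step's
    batch).  Bit-reproducible under a fixed config seed.
    """
    X = train.features if isinstance(train, DescriptorTable) else np.asarray(train, float)
    if np.any(X < 0) or np.any(X > 1):
        raise ValueError("train_vae expects min-max normalized input in [0, 1]")
    if config is None:
        config = VAETrainConfig()
    if arch is None:
        arch = VAEArchitecture(input_dim=X.shape[1])
    seq = np.random.SeedSequence(config.seed)
    init_seed, noise_seed = seq.spawn(2)
    model = init_vae(arch, int(init_seed.generate_state(1)[0] % 2**31))
    noise_rng = np.random.default_rng(noise_seed)
    opt = Adam(model.params, config.learning_rate)
    n_total = X.shape[0]
    batch = (n_total if config.batch_size is None
             else min(config.batch_size, n_total))
    w = config.recon_weight
    hist = {k: np.empty(config.iterations) for k in ("total", "recon", "kl")}
    p = model.params
    n_enc = len(arch.encoder_hidden)
    n_dec = len(arch.decoder_hidden)
    order = noise_rng.permutation(n_total)
    pos = 0
    for it in range(config.iterations):
        if pos + batch > n_total:
            order = noise_rng.permutation(n_total)
            pos = 0
        Xb = X[order[pos:pos + batch]]
        pos += batch
        n = Xb.shape[0]
        mu, lv, enc_pre, enc_post = _encode_forward(model, Xb)
        eps = noise_rng.standard_normal(mu.shape)
        Z = mu + np.exp(lv / 2.0) * eps
        xhat, dec_pre, dec_post = _decode_forward(model, Z)

        stats = LatentStats(mu=mu, logvar=lv)
        total, recon, kl = vae_loss(Xb, xhat, stats, w, config.recon_loss)
        hist["total"][it] = total / n
        hist["recon"][it] = recon / n
        hist["kl"][it] = kl / n

        # --- backward (gradients of the per-sample mean loss) ---
        grads: dict[str, np.ndarray] = {}
        if config.recon_loss == "bce":
            d_logits = (w / n) * (xhat - Xb)
        else:
            d_logits = (w / n) * 2.0 * (xhat - Xb) * xhat * (1.0 - xhat)
        h_last = dec_post[-1] if n_dec else Z
        grads["out_W"] = h_last.T @ d_logits
        grads["out_b"] = d_logits.sum(axis=0)
        dh = d_logits @ p["out_W"].T
        for i in range(n_dec - 1, -1, -1):
            da = dh * relu_grad(dec_pre[i])
            h_in = dec_post[i - 1] if i > 0 else Z
            grads[f"dec_W{i}"] = h_in.T @ da
            grads[f"dec_b{i}"] = da.sum(axis=0)
            dh = da @ p[f"dec_W{i}"].T
        dZ = dh
        d_mu = dZ + mu / n
        d_lv = dZ * eps * 0.5 * np.exp(lv / 2.0) + 0.5 * (np.exp(lv) - 1.0) / n
        h_enc = enc_post[-1] if n_enc else Xb
        grads["mu_W"] = h_enc.T @ d_mu
        grads["mu_b"] = d_mu.sum(axis=0)
        grads["lv_W"] = h_enc.T @ d_lv
        grads["lv_b"] = d_lv.sum(axis=0)
        dh = d_mu @ p["mu_W"].T + d_lv @ p["lv_W"].T
        for i in range(n_enc - 1, -1, -1):
            da = dh * relu_grad(enc_pre[i])
            h_in = enc_post[i - 1] if i > 0 else Xb
            grads[f"enc_W{i}"] = h_in.T @ da
            grads[f"enc_b{i}"] = da.sum(axis=0)
            dh = da @ p[f"enc_W{i}"].T
        opt.step(grads)
    return model, hist


def generate_pool(model: VAEModel, minority: np.ndarray, n_pool: int,
                  seed: int | np.random.Generator) -> np.ndarray:
    """Synthetic minority rows: encode a uniformly drawn minority row,
    sample its latent posterior, decode.  Values lie in (0, 1)."""
    minority = np.atleast_2d(np.asarray(minority, dtype=float))
    if minority.shape[0] == 0:
        raise ValueError("minority set is empty")
    if n_pool < 1:
        raise ValueError("n_pool must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    idx = rng.integers(0, minority.shape[0], size=n_pool)
    stats = encode(model, minority[idx])
    z = reparameterize(stats, rng)
    return decode(model, z)


def balance_with_vae(train: DescriptorTable, model: VAEModel, n_pool: int,
                     seed: int | np.random.Generator) -> DescriptorTable:
    """Append pool-drawn synthetic minority rows until the classes are
    equal.  Original rows are never modified; drawing from the pool is
    uniform without replacement."""
    counts = train.class_counts()
    gap = counts.gap
    if gap == 0:
        return train.subset(np.arange(train.n_samples))
    if n_pool < gap:
        raise ValueError(
            f"pool of {n_pool} cannot fill a class gap of {gap}"
        )
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    minority_label = train.minority_label()
    minority_rows = train.features[train.labels == minority_label]
    pool = generate_pool(model, minority_rows, n_pool, rng)
    chosen = rng.choice(n_pool, size=gap, replace=False)
    synthetic = DescriptorTable(
        features=pool[chosen],
        labels=np.full(gap, minority_label, dtype=int),
        feature_names=list(train.feature_names),
        feature_groups=dict(train.feature_groups),
    )
    return concat_tables(train, synthetic)


class VAEOversampler(BaseEstimator):
    """Scikit-learn-style resampler: fit a VAE on the (normalized)
    training matrix, then balance classes with posterior-sampled
    synthetic minority rows.

    Parameters mirror the training schedule used throughout this package:
    reconstruction weight 1000, learning rate 0.001, 5000 full-batch Adam
    iterations, a 500-row generation pool.
    """

    def __init__(self, encoder_hidden=(50, 25), latent_dim=2,
                 recon_weight=1000.0, learning_rate=0.001, iterations=5000,
                 batch_size=32, pool_size=500, recon_loss="bce",
                 random_state=0):
        self.encoder_hidden = encoder_hidden
        self.latent_dim = latent_dim
        self.recon_weight = recon_weight
        self.learning_rate = learning_rate
        self.iterations = iterations
        self.batch_size = batch_size
        self.pool_size = pool_size
        self.recon_loss = recon_loss
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        arch = VAEArchitecture(input_dim=X.shape[1],
                               encoder_hidden=tuple(self.encoder_hidden),
                               latent_dim=self.latent_dim)
        config = VAETrainConfig(recon_weight=self.recon_weight,
                                learning_rate=self.learning_rate,
                                iterations=self.iterations,
                                batch_size=self.batch_size,
                                recon_loss=self.recon_loss,
                                seed=self.random_state)
        self.model_, history = train_vae(X, arch, config)
        self.loss_history_ = history
        self.n_features_in_ = X.shape[1]
        return self

    def transform_latent(self, X) -> np.ndarray:
        """Posterior means (n, latent_dim), e.g. for latent scatter plots."""
        return encode(self.model_, np.asarray(X, float)).mu

    def fit_resample(self, X, y):
        """Train on X, then return a class-balanced (X, y)."""
        y = np.asarray(y, dtype=int)
        self.fit(X, y)
        table = DescriptorTable(
            features=np.asarray(X, float), labels=y,
            feature_names=[f"f{i}" for i in range(self.n_features_in_)],
        )
        # sampling seed decoupled from the training seed
        rng = np.random.default_rng(
            np.random.SeedSequence((self.random_state, 1)))
        balanced = balance_with_vae(table, self.model_, self.pool_size, rng)
        return balanced.features, balanced.labels
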