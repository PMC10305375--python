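"""Skip-connected multi-layer 1-D CNN for binary complexation prediction.

The reduced descriptor vector (length 10 after PCA by default) enters as a
single-channel sequence and passes through three 1-D convolutions with
kernel size and stride 1 whose channel widths grow 8 -> 16 -> 32.  The
feature maps of the first convolution are concatenated channel-wise with
those of the third (a skip connection preserving low-level information),
max-pooled with window 2, passed through one more convolution (width 32),
pooled again, flattened, and mapped by a dense layer with a logistic
output to the probability that the drug-phospholipid complex forms.

Training is Adam on binary cross-entropy, 2500 iterations at learning
rate 0.001 by default, where an iteration is one optimizer step on a
shuffled mini-batch of 32 (batch_size=None gives full-batch steps);
bit-reproducible under a fixed seed.
With the default topology the model has 2081 trainable parameters
(16 + 144 + 544 + 1312 + 65 across the five weight layers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._nn import Adam, he_normal, relu, relu_grad, sigmoid
from .table import DescriptorTable


@dataclass
class CNNArchitecture:
    input_length: int = 10
    input_channels: int = 1
    conv_channels: tuple[int, ...] = (8, 16, 32)
    kernel_size: int = 1
    stride: int = 1
    pool_size: int = 2
    post_skip_conv_channels: int = 32
    pooling: str = "max"  # or "average"

    def __post_init__(self) -> None:
        self.conv_channels = tuple(int(c) for c in self.conv_channels)
        if self.kernel_size < 1 or self.pool_size < 1 or self.stride < 1:
            raise ValueError("kernel_size, stride and pool_size must be >= 1")
        if any(b <= a for a, b in zip(self.conv_channels,
                                      self.conv_channels[1:])):
            raise ValueError("conv_channels must be strictly increasing")
        if self.pooling not in ("max", "average"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        self.sequence_trace()  # validates feasibility

    def _conv_out(self, length: int) -> int:
        out = (length - self.kernel_size) // self.stride + 1
        if out < 1:
            raise ValueError(
                f"sequence of length {length} too short for kernel "
                f"{self.kernel_size} / stride {self.stride}"
            )
        return out

    def sequence_trace(self) -> list[int]:
        """Sequence lengths after each stage:
        [input, conv1..conv3, pool1, conv4, pool2]."""
        trace = [self.input_length]
        for _ in self.conv_channels:
            trace.append(self._conv_out(trace[-1]))
        if len(self.conv_channels) >= 3 and trace[1] != trace[3]:
            raise ValueError(
                "skip connection requires conv-1 and conv-3 outputs of "
                f"equal length, got {trace[1]} and {trace[3]}"
            )
        pooled1 = trace[-1] // self.pool_size
        if pooled1 < 1:
            raise ValueError("input_length too short for first pooling")
        trace.append(pooled1)
        trace.append(self._conv_out(pooled1))
        pooled2 = trace[-1] // self.pool_size
        if pooled2 < 1:
            raise ValueError("input_length too short for two poolings")
        trace.append(pooled2)
        return trace

    @property
    def flatten_dim(self) -> int:
        return self.post_skip_conv_channels * self.sequence_trace()[-1]


@dataclass
class ClassifierTrainConfig:
    """An iteration is one Adam step on a shuffled mini-batch
    (batch_size None = full batch)."""

    learning_rate: float = 0.001
    iterations: int = 2500
    batch_size: int | None = 32
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1 or None")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class CNNModel:
    arch: CNNArchitecture
    params: dict[str, np.ndarray] = field(default_factory=dict)

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def build_cnn(arch: CNNArchitecture, seed: int) -> tuple[CNNModel, int]:
    """He-normal weights (fan_in = in_channels * kernel), zero biases,
    deterministic per seed.  Returns the model and its parameter count."""
    rng = np.random.default_rng(seed)
    k = arch.kernel_size
    params: dict[str, np.ndarray] = {}
    c_in = arch.input_channels
    for i, c_out in enumerate(arch.conv_channels):
        fan_in = c_in * k
        params[f"conv_W{i}"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k))
        params[f"conv_b{i}"] = np.zeros(c_out)
        c_in = c_out
    concat_ch = arch.conv_channels[0] + arch.conv_channels[-1]
    fan_in = concat_ch * k
    params["post_W"] = rng.normal(
        0.0, np.sqrt(2.0 / fan_in),
        size=(arch.post_skip_conv_channels, concat_ch, k))
    params["post_b"] = np.zeros(arch.post_skip_conv_channels)
    params["dense_W"] = he_normal(rng, arch.flatten_dim, 1)
    params["dense_b"] = np.zeros(1)
    model = CNNModel(arch=arch, params=params)
    return model, model.parameter_count()


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int):
    """x (n, C_in, L), W (C_out, C_in, k) -> (y, patches, idx)."""
    k = W.shape[2]
    if k == 1 and stride == 1:
        # pointwise convolution: a per-position channel mix
        y = np.tensordot(x, W[:, :, 0], axes=([1], [1])).transpose(0, 2, 1)
        return y + b[None, :, None], x, None
    L = x.shape[2]
    L_out = (L - k) // stride + 1
    idx = (np.arange(L_out) * stride)[None, :] + np.arange(k)[:, None]
    patches = x[:, :, idx]  # (n, C_in, k, L_out)
    y = np.einsum("nckl,ock->nol", patches, W) + b[None, :, None]
    return y, patches, idx


def _conv_backward(dy, patches, idx, x_shape, W):
    if idx is None:  # kernel 1, stride 1 fast path; patches is x itself
        W0 = W[:, :, 0]
        dW = np.einsum("nol,ncl->oc", dy, patches)[:, :, None]
        db = dy.sum(axis=(0, 2))
        dx = np.tensordot(dy, W0, axes=([1], [0])).transpose(0, 2, 1)
        return dx, dW, db
    dW = np.einsum("nol,nckl->ock", dy, patches)
    db = dy.sum(axis=(0, 2))
    dpatches = np.einsum("nol,ock->nckl", dy, W)
    dx = np.zeros(x_shape)
    np.add.at(dx, (slice(None), slice(None), idx), dpatches)
    return dx, dW, db


def _pool_forward(x: np.ndarray, p: int, mode: str):
    n, c, L = x.shape
    L_out = L // p
    xr = x[:, :, : L_out * p].reshape(n, c, L_out, p)
    if mode == "max":
        arg = xr.argmax(axis=3)
        return xr.max(axis=3), (arg, x.shape, p)
    return xr.mean(axis=3), (None, x.shape, p)


def _pool_backward(dy: np.ndarray, cache, mode: str) -> np.ndarray:
    arg, x_shape, p = cache
    n, c, L = x_shape
    L_out = L // p
    dxr = np.zeros((n, c, L_out, p))
    if mode == "max":
        np.put_along_axis(dxr, arg[..., None], dy[..., None], axis=3)
    else:
        dxr[:] = dy[..., None] / p
    dx = np.zeros(x_shape)
    dx[:, :, : L_out * p] = dxr.reshape(n, c, L_out * p)
    return dx


def _forward_batch(model: CNNModel, X: np.ndarray, cache: bool = False):
    """X (n, input_length) -> probabilities (n,); optionally returns the
    intermediate tensors needed for backprop."""
    arch, p = model.arch, model.params
    n = X.shape[0]
    x = X.reshape(n, arch.input_channels, -1)
    if x.shape[2] != arch.input_length:
        raise ValueError(
            f"input length {x.shape[2]} != expected {arch.input_length}"
        )
    caches = {}
    h = x
    conv_outs = []
    for i in range(len(arch.conv_channels)):
        a, patches, idx = _conv_forward(
            h, p[f"conv_W{i}"], p[f"conv_b{i}"], arch.stride)
        hi = relu(a)
        caches[f"conv{i}"] = (a, patches, idx, h.shape)
        conv_outs.append(hi)
        h = hi
    concat = np.concatenate([conv_outs[0], conv_outs[-1]], axis=1)
    pooled1, pc1 = _pool_forward(concat, arch.pool_size, arch.pooling)
    a4, patches4, idx4 = _conv_forward(pooled1, p["post_W"], p["post_b"],
                                       arch.stride)
    h4 = relu(a4)
    pooled2, pc2 = _pool_forward(h4, arch.pool_size, arch.pooling)
    flat = pooled2.reshape(n, -1)
    logits = (flat @ p["dense_W"] + p["dense_b"]).ravel()
    probs = sigmoid(logits)
    if not cache:
        return probs
    caches.update(concat_shape=concat.shape, pc1=pc1,
                  conv4=(a4, patches4, idx4, pooled1.shape),
                  pc2=pc2, flat=flat, pooled2_shape=pooled2.shape)
    return probs, caches


def forward(model: CNNModel, x: np.ndarray) -> float | np.ndarray:
    """Probability of complex formation for one reduced feature vector,
    or a vector of probabilities for a 2-D batch."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return float(_forward_batch(model, x[None, :])[0])
    return _forward_batch(model, x)


def _backward_batch(model: CNNModel, probs, caches, y: np.ndarray):
    """Gradients of mean BCE w.r.t. all parameters."""
    arch, p = model.arch, model.params
    n = y.shape[0]
    grads: dict[str, np.ndarray] = {}
    d_logits = (probs - y) / n
    flat = caches["flat"]
    grads["dense_W"] = flat.T @ d_logits[:, None]
    grads["dense_b"] = np.array([d_logits.sum()])
    d_flat = d_logits[:, None] @ p["dense_W"].T
    d_pooled2 = d_flat.reshape(caches["pooled2_shape"])
    d_h4 = _pool_backward(d_pooled2, caches["pc2"], arch.pooling)
    a4, patches4, idx4, pooled1_shape = caches["conv4"]
    d_a4 = d_h4 * relu_grad(a4)
    d_pooled1, grads["post_W"], grads["post_b"] = _conv_backward(
        d_a4, patches4, idx4, pooled1_shape, p["post_W"])
    d_concat = _pool_backward(d_pooled1, caches["pc1"], arch.pooling)
    c0 = arch.conv_channels[0]
    d_skip_h0 = d_concat[:, :c0]
    d_h_last = d_concat[:, c0:]
    # walk conv blocks backwards; conv-1 output also feeds the skip
    d_h = d_h_last
    n_conv = len(arch.conv_channels)
    for i in range(n_conv - 1, -1, -1):
        if i == 0:
            d_h = d_h + d_skip_h0
        a, patches, idx, x_shape = caches[f"conv{i}"]
        d_a = d_h * relu_grad(a)
        d_h, grads[f"conv_W{i}"], grads[f"conv_b{i}"] = _conv_backward(
            d_a, patches, idx, x_shape, p[f"conv_W{i}"])
    return grads


def train_classifier(model: CNNModel, train: DescriptorTable | tuple,
                     config: ClassifierTrainConfig,
                     ) -> tuple[CNNModel, dict[str, np.ndarray]]:
    """Exactly ``config.iterations`` Adam steps on mean binary
    cross-entropy, each over a freshly shuffled mini-batch; returns the
    model and per-iteration loss/accuracy (measured on the step's
    batch).  Seed-reproducible."""
    if isinstance(train, DescriptorTable):
        X, y = train.features, train.labels
    else:
        X, y = train
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not set(np.unique(y).tolist()) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    y = y.astype(float)
    opt = Adam(model.params, config.learning_rate)
    hist = {"loss": np.empty(config.iterations),
            "accuracy": np.empty(config.iterations)}
    eps = 1e-12
    n_total = X.shape[0]
    batch = (n_total if config.batch_size is None
             else min(config.batch_size, n_total))
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, 1)))
    order = shuffle_rng.permutation(n_total)
    pos = 0
    for it in range(config.iterations):
        if pos + batch > n_total:
            order = shuffle_rng.permutation(n_total)
            pos = 0
        idx = order[pos:pos + batch]
        pos += batch
        Xb, yb = X[idx], y[idx]
        probs, caches = _forward_batch(model, Xb, cache=True)
        pc = np.clip(probs, eps, 1 - eps)
        hist["loss"][it] = float(
            -np.mean(yb * np.log(pc) + (1 - yb) * np.log(1 - pc)))
        hist["accuracy"][it] = float(
            np.mean((probs >= config.threshold) == (yb == 1)))
        grads = _backward_batch(model, probs, caches, yb)
        opt.step(grads)
    return model, hist


def predict(model: CNNModel, table: DescriptorTable | np.ndarray,
            threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """(labels, probabilities); label 1 iff probability >= threshold."""
    X = (table.features if isinstance(table, DescriptorTable)
         else np.asarray(table, dtype=float))
    probs = _forward_batch(model, X)
    return (probs >= threshold).astype(int), probs


class CNNClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn-style wrapper around the skip-connected 1-D CNN."""

    def __init__(self, conv_channels=(8, 16, 32), kernel_size=1, stride=1,
                 pool_size=2, post_skip_conv_channels=32, pooling="max",
                 learning_rate=0.001, iterations=2500, batch_size=32,
                 threshold=0.5, random_state=0):
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.pool_size = pool_size
        self.post_skip_conv_channels = post_skip_conv_channels
        self.pooling = pooling
        self.learning_rate = learning_rate
        self.iterations = iterations
        self.batch_size = batch_size
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        arch = CNNArchitecture(
            input_length=X.shape[1],
            conv_channels=tuple(self.conv_channels),
            kernel_size=self.kernel_size, stride=self.stride,
            pool_size=self.pool_size,
            post_skip_conv_channels=self.post_skip_conv_channels,
            pooling=self.pooling)
        model, self.parameter_count_ = build_cnn(arch, self.random_state)
        config = ClassifierTrainConfig(
            learning_rate=self.learning_rate, iterations=self.iterations,
            batch_size=self.batch_size, threshold=self.threshold,
            seed=self.random_state)
        self.model_, history = train_classifier(model, (X, y), config)
        self.loss_history_ = history["loss"]
        self.accuracy_history_ = history["accuracy"]
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        p1 = _forward_batch(self.model_, np.asarray(X, dtype=float))
        return np.column_stack([1.0 - p1, p1])

    def decision_scores(self, X) -> np.ndarray:
        """Probability of the positive (complex-formed) class."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return (self.decision_scores(X) >= self.threshold).astype(int)
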