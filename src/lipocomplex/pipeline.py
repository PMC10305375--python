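"""End-to-end complexation-prediction pipeline and the resampling
comparison harness.

The canonical order is: min-max normalize (fit on train only) ->
balance the classes (VAE pool by default; SMOTE / ENN / SMOTE-ENN /
no-op as comparison arms) -> PCA fitted on the balanced training set,
keeping 10 components by default -> skip-connected 1-D CNN.  Test data
passes through the identical fitted normalizer and projection, never
through resampling.  Ablation switches (resampler="none",
use_pca=False) reproduce the with/without-stage comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .cnn import CNNClassifier
from .datasets import GeneratedDataset
from .metrics import MetricsReport, evaluate
from .pca import PCAReducer
from .preprocessing import MinMaxNormalizer
from .resampling import (ENNResampler, IdentityResampler, SMOTEENNResampler,
                         SMOTEResampler)
from .vae import VAEOversampler

RESAMPLERS = ("none", "vae", "smote", "enn", "smote_enn")


class ComplexationPipeline(ClassifierMixin, BaseEstimator):
    """Normalize -> resample -> (PCA) -> CNN, as one sklearn estimator.

    Parameters follow the study-default training schedule: VAE with a
    500-row pool, reconstruction weight 1000 and 5000 Adam iterations;
    PCA keeping 10 components; CNN trained 2500 iterations; both
    learners at learning rate 0.001.
    """

    def __init__(self, resampler="vae", use_pca=True, n_components=10,
                 cumulative_threshold=0.85, pool_size=500,
                 recon_weight=1000.0, vae_iterations=5000,
                 cnn_iterations=2500, learning_rate=0.001, batch_size=32,
                 latent_dim=2, encoder_hidden=(50, 25), smote_k=5, enn_k=3,
                 threshold=0.5, random_state=0):
        self.resampler = resampler
        self.use_pca = use_pca
        self.n_components = n_components
        self.cumulative_threshold = cumulative_threshold
        self.pool_size = pool_size
        self.recon_weight = recon_weight
        self.vae_iterations = vae_iterations
        self.cnn_iterations = cnn_iterations
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.latent_dim = latent_dim
        self.encoder_hidden = encoder_hidden
        self.smote_k = smote_k
        self.enn_k = enn_k
        self.threshold = threshold
        self.random_state = random_state

    def _make_resampler(self, seed: int):
        if self.resampler == "vae":
            return VAEOversampler(
                encoder_hidden=tuple(self.encoder_hidden),
                latent_dim=self.latent_dim,
                recon_weight=self.recon_weight,
                learning_rate=self.learning_rate,
                iterations=self.vae_iterations,
                batch_size=self.batch_size,
                pool_size=self.pool_size, random_state=seed)
        if self.resampler == "smote":
            return SMOTEResampler(k=self.smote_k, random_state=seed)
        if self.resampler == "enn":
            return ENNResampler(k=self.enn_k)
        if self.resampler == "smote_enn":
            return SMOTEENNResampler(smote_k=self.smote_k, enn_k=self.enn_k,
                                     random_state=seed)
        if self.resampler == "none":
            return IdentityResampler()
        raise ValueError(
            f"unknown resampler {self.resampler!r}; expected one of "
            f"{RESAMPLERS}"
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        seq = np.random.SeedSequence(self.random_state)
        seeds = [int(s.generate_state(1)[0] % 2**31) for s in seq.spawn(2)]

        self.normalizer_ = MinMaxNormalizer().fit(X)
        X_norm = self.normalizer_.transform(X)

        self.resampler_ = self._make_resampler(seeds[0])
        X_bal, y_bal = self.resampler_.fit_resample(X_norm, y)
        self.resampled_class_counts_ = (int((y_bal == 1).sum()),
                                        int((y_bal == 0).sum()))

        if self.use_pca:
            self.pca_ = PCAReducer(
                n_components=self.n_components,
                cumulative_threshold=self.cumulative_threshold,
            ).fit(X_bal)
            self.n_components_ = self.pca_.n_components_
            X_red = self.pca_.transform(X_bal)
        else:
            self.pca_ = None
            self.n_components_ = X_bal.shape[1]
            X_red = X_bal

        self.cnn_ = CNNClassifier(
            learning_rate=self.learning_rate,
            iterations=self.cnn_iterations,
            batch_size=self.batch_size,
            threshold=self.threshold,
            random_state=seeds[1]).fit(X_red, y_bal)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def _reduce(self, X):
        X_norm = self.normalizer_.transform(np.asarray(X, dtype=float))
        return self.pca_.transform(X_norm) if self.pca_ is not None else X_norm

    def decision_scores(self, X) -> np.ndarray:
        return self.cnn_.decision_scores(self._reduce(X))

    def predict_proba(self, X):
        return self.cnn_.predict_proba(self._reduce(X))

    def predict(self, X):
        return (self.decision_scores(X) >= self.threshold).astype(int)

    def evaluate(self, X, y) -> MetricsReport:
        scores = self.decision_scores(X)
        return evaluate(np.asarray(y, int),
                        (scores >= self.threshold).astype(int), scores)


def compare_sampling(dataset: GeneratedDataset,
                     methods: list[str] | tuple[str, ...] = RESAMPLERS,
                     random_state: int = 0,
                     **pipeline_params) -> pd.DataFrame:
    """Fit the identical downstream pipeline once per resampling arm and
    report the train/test metric suite, one row per (method, split)."""
    rows = []
    for method in methods:
        pipe = ComplexationPipeline(resampler=method,
                                    random_state=random_state,
                                    **pipeline_params)
        pipe.fit(dataset.train.features, dataset.train.labels)
        for split_name, table in (("train", dataset.train),
                                  ("test", dataset.test)):
            report = pipe.evaluate(table.features, table.labels)
            rows.append({"method": method, "split": split_name,
                         "n_resampled": sum(pipe.resampled_class_counts_),
                         **report.as_dict()})
    return pd.DataFrame(rows)
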