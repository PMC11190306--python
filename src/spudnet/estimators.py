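"""Scikit-learn style estimators wrapping the network and SVM baselines.

``ResNet1DClassifier`` and ``SpectrumSVC`` follow the sklearn estimator
contract (``fit``/``predict``/``get_params``/``set_params``, fitted
attributes with a trailing underscore) so they compose with pipelines and
model selection; the procedural operations in :mod:`spudnet.protocol` and
:mod:`spudnet.svm_baseline` are thin wrappers over them.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .nn import (
    ArchitectureSpec,
    ResNet1D,
    TrainConfig,
    baseline_spec,
    forward_logits,
    resolve_modified_spec,
    softmax,
    train_network,
)

__all__ = ["ResNet1DClassifier", "SpectrumSVC"]


def _check_Xy(X, y=None):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D (n_samples, n_wavelengths) array")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if y is None:
        return X
    y = np.asarray(y)
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y have inconsistent lengths")
    return X, y


class ResNet1DClassifier(ClassifierMixin, BaseEstimator):
    """1-D residual network classifier for transmission spectra.

    Parameters
    ----------
    variant : {'modified', 'baseline'}
        'baseline' is the reference 1-D ResNet-18; 'modified' adds
        depthwise-separable convolutions and efficient channel attention in
        the wide stages (the frozen resolved configuration).
    spec : ArchitectureSpec, optional
        Explicit architecture overriding ``variant`` (its class count is
        adjusted to the training data).
    standardize : bool
        Standardize each wavelength on calibration statistics before the
        network (transmission counts vary by orders of magnitude across the
        grid, which otherwise dominates early training).
    """

    def __init__(
        self,
        variant: str = "modified",
        spec: ArchitectureSpec | None = None,
        epochs: int = 100,
        learning_rate: float = 0.01,
        weight_decay: float = 1e-4,
        batch_size: int = 256,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.variant = variant
        self.spec = spec
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.standardize = standardize
        self.random_state = random_state

    def _base_spec(self) -> ArchitectureSpec:
        if self.spec is not None:
            return self.spec
        if self.variant == "baseline":
            return baseline_spec()
        if self.variant == "modified":
            return resolve_modified_spec()
        raise ValueError(f"unknown variant '{self.variant}'")

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.n_features_in_ = X.shape[1]
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            self.scale_ = X.std(axis=0)
            self.scale_[self.scale_ == 0] = 1.0
        spec = replace(self._base_spec(), n_classes=len(self.classes_))
        self.spec_ = spec
        # single precision: the usual arithmetic for CNN training, and
        # roughly twice the GEMM throughput of double
        self.network_ = ResNet1D(spec, seed=self.random_state, dtype=np.float32)
        cfg = TrainConfig(
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.random_state,
        )
        self.history_ = train_network(self.network_, self._transform(X), y_idx, cfg)
        return self

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.standardize:
            X = (X - self.mean_) / self.scale_
        return X

    def decision_function(self, X):
        X = _check_Xy(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} wavelengths; model was fit with {self.n_features_in_}"
            )
        return forward_logits(self.network_, self._transform(X))

    def predict_proba(self, X):
        return softmax(self.decision_function(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


class SpectrumSVC(ClassifierMixin, BaseEstimator):
    """RBF-kernel support-vector baseline (C=1, gamma='scale').

    Spectra are standardized per wavelength before the kernel machine (RBF
    distances are scale-sensitive); the multi-class strategy is the kernel
    machine's native one-vs-one.
    """

    def __init__(self, C: float = 1.0, gamma: str | float = "scale",
                 standardize: bool = True, random_state: int = 0):
        self.C = C
        self.gamma = gamma
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.n_features_in_ = X.shape[1]
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            self.scale_ = X.std(axis=0)
            self.scale_[self.scale_ == 0] = 1.0
            X = (X - self.mean_) / self.scale_
        self.svc_ = SVC(C=self.C, kernel="rbf", gamma=self.gamma,
                        random_state=self.random_state)
        self.svc_.fit(X, y)
        return self

    def predict(self, X):
        X = _check_Xy(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} wavelengths; model was fit with {self.n_features_in_}"
            )
        if self.standardize:
            X = (X - self.mean_) / self.scale_
        return self.svc_.predict(X)
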