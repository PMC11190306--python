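"""Procedural wrappers for the support-vector comparison classifier."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import SpectrumSVC

__all__ = ["SvmConfig", "fit_svm", "predict_svm"]


@dataclass(frozen=True)
class SvmConfig:
    C: float = 1.0
    gamma: str | float = "scale"
    seed: int = 0

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be > 0")


def fit_svm(features: np.ndarray, labels, cfg: SvmConfig = SvmConfig()) -> SpectrumSVC:
    """Fit the RBF maximum-margin classifier; deterministic given the data."""
    clf = SpectrumSVC(C=cfg.C, gamma=cfg.gamma, random_state=cfg.seed)
    return clf.fit(features, labels)


def predict_svm(classifier: SpectrumSVC, features: np.ndarray):
    """One grade per feature row."""
    return classifier.predict(features)
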