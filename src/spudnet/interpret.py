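"""Model interpretability: 1-D Grad-CAM++ saliency, per-layer t-SNE
embeddings, and PCA score analysis of spectral datasets.

Grad-CAM++ weights each spatial location of a convolutional layer's
activation by coefficients derived from higher-order derivatives of the
class score. With the exponentiated-score identity those coefficients have
a closed form in the first derivatives g = dS/dA:

    alpha = g^2 / (2 g^2 + sum_l A_l * g^3),      (alpha := 0 where g = 0)
    w_k   = sum_l alpha_kl * relu(g_kl),
    map   = relu(sum_k w_k A_k),

after which the map is linearly interpolated onto the wavelength grid and
max-normalized to [0, 1]. The normalization makes the map approximately
(not exactly) invariant to positive rescaling of the final linear layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .estimators import ResNet1DClassifier
from .nn import FEATURE_LAYERS, ResNet1D, extract_features, forward_logits
from .synthetic import SpectralDataset, WavelengthGrid

__all__ = [
    "SaliencyMap",
    "LayerEmbedding",
    "grad_campp_1d",
    "saliency_band_hit_rate",
    "tsne_layers",
    "pca_scores",
]


@dataclass
class SaliencyMap:
    """Per-wavelength importance in [0, 1] for one spectrum and class."""

    grid: WavelengthGrid
    importance: np.ndarray
    target_class: int
    source_layer: str
    degenerate: bool = False

    def __post_init__(self):
        imp = np.asarray(self.importance, dtype=float)
        if imp.shape != (len(self.grid),):
            raise ValueError("importance must align with the grid")
        if imp.min() < 0 or imp.max() > 1:
            raise ValueError("importance values must lie in [0, 1]")
        self.importance = imp

    @property
    def argmax_wavelength(self) -> float:
        return float(self.grid.values[int(np.argmax(self.importance))])


@dataclass
class LayerEmbedding:
    """2-D t-SNE coordinates of one layer's features, with grade labels."""

    layer: str
    coordinates: np.ndarray
    labels: np.ndarray
    silhouette: float


def _net_of(model) -> ResNet1D:
    if isinstance(model, ResNet1DClassifier):
        return model.network_
    # duck-typed: anything exposing forward / backward_to / activations
    if all(hasattr(model, a) for a in ("forward", "backward_to", "activations")):
        return model
    raise TypeError("expected a fitted ResNet1DClassifier or a network object")


def _prepare(model, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if isinstance(model, ResNet1DClassifier):
        X = model._transform(X)
    return X[:, None, :]


def grad_campp_1d(
    model,
    spectra: np.ndarray,
    target_class: int,
    grid: WavelengthGrid,
    layer: str = "layer4",
) -> list[SaliencyMap]:
    """Grad-CAM++ saliency over wavelengths for each input spectrum.

    ``target_class`` is a class index into the network's output scores.
    Degenerate maps (zero gradient everywhere, e.g. a constant logit) come
    back all-zero with ``degenerate=True``.
    """
    net = _net_of(model)
    if layer not in FEATURE_LAYERS or layer == "avgpool":
        raise KeyError(f"saliency layer must be a convolutional layer, got '{layer}'")
    x = _prepare(model, spectra)
    was_training = net.training
    net.eval()
    try:
        logits = net.forward(x)
        if not 0 <= target_class < logits.shape[1]:
            raise ValueError(f"target_class {target_class} out of range")
        dlogits = np.zeros_like(logits)
        dlogits[:, target_class] = 1.0
        net.zero_grad()
        g = net.backward_to(dlogits, upto=layer)  # (N, C, L) dS/dA
        A = net.activations[layer]
    finally:
        net.train(was_training)

    g2 = g * g
    denom = 2.0 * g2 + A.sum(axis=2, keepdims=True) * g2 * g
    alpha = np.divide(g2, denom, out=np.zeros_like(g2), where=np.abs(denom) > 1e-30)
    weights = (alpha * np.maximum(g, 0.0)).sum(axis=2)  # (N, C)
    raw = np.maximum(np.einsum("nc,ncl->nl", weights, A), 0.0)

    lam = grid.values
    centers = lam[0] + (np.arange(raw.shape[1]) + 0.5) / raw.shape[1] * (lam[-1] - lam[0])
    maps = []
    for i in range(raw.shape[0]):
        imp = np.interp(lam, centers, raw[i])
        peak = imp.max()
        degenerate = peak <= 0.0
        imp = np.zeros(len(grid)) if degenerate else imp / peak
        maps.append(
            SaliencyMap(
                grid=grid,
                importance=np.clip(imp, 0.0, 1.0),
                target_class=int(target_class),
                source_layer=layer,
                degenerate=degenerate,
            )
        )
    return maps


def saliency_band_hit_rate(maps, band: tuple[float, float]) -> float:
    """Fraction of maps whose argmax wavelength lies inside [lo, hi]."""
    maps = list(maps)
    if not maps:
        raise ValueError("empty saliency collection")
    lo, hi = band
    hits = sum(1 for m in maps if lo <= m.argmax_wavelength <= hi)
    return hits / len(maps)


def tsne_layers(
    model,
    X: np.ndarray,
    labels,
    layers=FEATURE_LAYERS,
    perplexity: float = 30.0,
    seed: int = 0,
) -> list[LayerEmbedding]:
    """2-D t-SNE of the pooled activations of each requested layer.

    Deterministic given ``seed``; the silhouette score against the grade
    labels quantifies how separated the classes are at each depth.
    """
    net = _net_of(model)
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] <= 3 * perplexity:
        raise ValueError(
            f"need more than {int(3 * perplexity)} samples for perplexity {perplexity}"
        )
    Xp = _prepare(model, X)[:, 0, :]
    out = []
    for layer in layers:
        feats = extract_features(net, Xp, layer)
        emb = TSNE(
            n_components=2,
            perplexity=perplexity,
            random_state=seed,
            init="pca",
            method="exact" if X.shape[0] <= 1500 else "barnes_hut",
        ).fit_transform(feats)
        sil = float(silhouette_score(emb, labels))
        out.append(LayerEmbedding(layer=layer, coordinates=emb, labels=labels, silhouette=sil))
    return out


def pca_scores(ds: SpectralDataset | np.ndarray, n_components: int = 3):
    """Mean-centered principal-component scores and cumulative explained
    variance percentages (non-decreasing, <= 100)."""
    X = ds.intensities if isinstance(ds, SpectralDataset) else np.asarray(ds, float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least two spectra")
    k = min(n_components, n - 1, X.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    cumulative = np.cumsum(pca.explained_variance_ratio_) * 100.0
    return scores, cumulative
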