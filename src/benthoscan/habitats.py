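"""Unsupervised seafloor habitat classification from image features.

Each image is encoded as a fixed-length feature vector, the collection is
clustered with K-means into substrate classes, and the feature space is
projected with PCA for visual inspection. Semantic naming of the clusters
remains a human step; the module supplies exemplar images per cluster
(nearest-to-centroid first) to support it.

The default feature extractor is deterministic and hand-crafted (colour
statistics, grey-level co-occurrence texture summaries averaged over
orientations, and a downsampled intensity grid). Deep-network embeddings can
be plugged in through the same registry without changing anything downstream;
features never depend on how images are batched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix, graycoprops
from skimage.transform import resize
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

_GLCM_LEVELS = 32
_GLCM_DISTANCES = (1, 3)
_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
_GLCM_PROPS = ("contrast", "correlation", "energy", "homogeneity")
_GRID = 8
_QUANTILES = (0.1, 0.25, 0.5, 0.75, 0.9)


def _handcrafted(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = image[:, :, None]
    chans = [image[..., c] for c in range(image.shape[2])]
    stats = []
    for ch in chans:
        stats += [ch.mean(), ch.std(), *np.quantile(ch, _QUANTILES)]
    grey = image.mean(axis=2)
    q = np.clip((grey * _GLCM_LEVELS).astype(int), 0, _GLCM_LEVELS - 1).astype(np.uint8)
    glcm = graycomatrix(q, distances=_GLCM_DISTANCES, angles=_GLCM_ANGLES,
                        levels=_GLCM_LEVELS, symmetric=True, normed=True)
    texture = []
    for prop in _GLCM_PROPS:
        vals = graycoprops(glcm, prop)  # (n_distances, n_angles)
        texture += list(vals.mean(axis=1))  # orientation-averaged: 90-deg rotation invariant
    grid = resize(grey, (_GRID, _GRID), anti_aliasing=True).ravel()
    return np.concatenate([stats, texture, grid])


_EXTRACTORS = {"handcrafted": _handcrafted}


def register_extractor(name: str, fn) -> None:
    """Plug in an alternative feature extractor (e.g. a CNN embedding)."""
    _EXTRACTORS[name] = fn


def extract_features(image: np.ndarray, extractor: str = "handcrafted") -> np.ndarray:
    """Encode one image (values in [0,1]) as a fixed-length feature vector."""
    if extractor not in _EXTRACTORS:
        raise ValueError(f"unknown extractor {extractor!r}; known: {sorted(_EXTRACTORS)}")
    return _EXTRACTORS[extractor](image)


@dataclass
class FeatureMatrix:
    image_ids: list
    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if not np.isfinite(self.vectors).all():
            raise ValueError("feature matrix contains non-finite entries")
        if len(self.image_ids) != self.vectors.shape[0]:
            raise ValueError("one feature row per image required")


def extract_collection(image_ids, images, extractor: str = "handcrafted") -> FeatureMatrix:
    vectors = np.stack([extract_features(img, extractor) for img in images])
    return FeatureMatrix(image_ids=list(image_ids), vectors=vectors)


@dataclass
class ClusterModel:
    k: int
    image_ids: list
    labels: np.ndarray
    centroids: np.ndarray
    objective: float  # within-cluster sum of squares
    selection_curve: list = field(default_factory=list)  # (k, silhouette, wcss)
    _distances: np.ndarray | None = None  # distance of each image to its centroid


def _standardised(X: np.ndarray) -> np.ndarray:
    # equalise feature scales so no block (e.g. the intensity grid) dominates
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def select_k(features: FeatureMatrix, k_range=range(2, 21), seed: int = 0):
    """Pick the class count maximising the mean silhouette over ``k_range``.

    The raw K-means objective (WCSS) decreases monotonically in k and cannot
    itself select k; the silhouette criterion is used instead, and the full
    (k, silhouette, WCSS) curve is returned so an elbow rule can be applied
    by eye. Returns (best_k, curve).
    """
    X = _standardised(features.vectors)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 images to select k")
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("k_range out of bounds for this collection")
    curve = []
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(X)
        # silhouette undefined if a cluster emptied out (k-means keeps k, but guard)
        sil = silhouette_score(X, km.labels_) if len(set(km.labels_)) > 1 else -1.0
        curve.append((k, float(sil), float(km.inertia_)))
    best = max(curve, key=lambda t: t[1])[0]
    return best, curve


def cluster(features: FeatureMatrix, k: int, seed: int = 0, n_init: int = 10) -> ClusterModel:
    """K-means on standardised features, multiple restarts, seed-deterministic.

    Centroids and per-image centroid distances are reported in the original
    feature space (class means); the objective is the within-cluster sum of
    squares of the standardised space the algorithm ran in.
    """
    X = features.vectors
    if not 2 <= k <= X.shape[0]:
        raise ValueError(f"k={k} out of range for {X.shape[0]} images")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(_standardised(X))
    centroids = np.stack([X[km.labels_ == c].mean(axis=0) for c in range(k)])
    dist = np.linalg.norm(X - centroids[km.labels_], axis=1)
    return ClusterModel(
        k=k,
        image_ids=features.image_ids,
        labels=km.labels_,
        centroids=centroids,
        objective=float(km.inertia_),
        _distances=dist,
    )


def project_pca(features: FeatureMatrix, n_components: int = 2) -> pd.DataFrame:
    """Centred linear projection onto the top principal axes."""
    X = features.vectors
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("feature matrix has zero variance")
    n_components = min(n_components, X.shape[1], X.shape[0])
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(X)
    df = pd.DataFrame(coords, index=features.image_ids,
                      columns=[f"pc{i+1}" for i in range(coords.shape[1])])
    df.attrs["explained_variance"] = pca.explained_variance_.tolist()
    return df


def sample_exemplars(model: ClusterModel, n_per_cluster: int = 5, seed: int = 0) -> dict:
    """Up to n image ids per cluster, nearest-to-centroid first.

    Ties in distance are broken by a seeded shuffle so exemplar sets are
    reproducible.
    """
    if n_per_cluster < 1:
        raise ValueError("n_per_cluster must be >= 1")
    rng = np.random.default_rng(seed)
    ids = np.asarray(model.image_ids, dtype=object)
    out = {}
    for c in range(model.k):
        mask = np.flatnonzero(model.labels == c)
        order = rng.permutation(mask)  # random tie-break ...
        order = order[np.argsort(model._distances[order], kind="stable")]  # ... then by distance
        out[c] = list(ids[order[:n_per_cluster]])
    return out
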