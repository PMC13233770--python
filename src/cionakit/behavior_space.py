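"""Behavioral-space clustering, embedding, label propagation, occupancy.

Frames are clustered in eigenciona feature space (the five static EC
scores): a balanced discovery subset is drawn across conditions, a
density-based (HDBSCAN) noise scan locates a stable clustering regime,
Gaussian mixtures over a K range are compared by AIC/BIC (K = 16 on the
reference data), labels are propagated to the remaining frames by
k-nearest-neighbor majority vote, and occupancy is summarized per
condition as 2-d KDEs over the UMAP embedding plus per-animal dwell
times per cluster.  The UMAP embedding is visualization only — cluster
assignment always happens in feature space.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.cluster import HDBSCAN
from sklearn.mixture import GaussianMixture

__all__ = [
    "ClusterModel", "Embedding", "balanced_subset", "hdbscan_noise_scan",
    "select_gmm", "embed_umap", "propagate_labels", "occupancy_maps",
]


@dataclass
class ClusterModel:
    K: int
    mixture: GaussianMixture
    selection_table: pd.DataFrame          # columns: K, aic, bic
    discovery_indices: np.ndarray
    noise_scan: pd.DataFrame | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.mixture.predict(np.asarray(features, dtype=float))


@dataclass
class Embedding:
    coords: np.ndarray
    neighbors: int = 50
    min_dist: float = 0.7
    seed: int = 0


def balanced_subset(condition_labels: np.ndarray, target: int = 120_000,
                    seed: int = 0) -> np.ndarray:
    """Equal-per-condition discovery indices, without replacement.

    Conditions with fewer frames than their share contribute everything
    they have; the shortfall is redistributed over the remaining
    conditions until the target (or the dataset) is exhausted.
    """
    labels = np.asarray(condition_labels)
    rng = np.random.default_rng(seed)
    groups = {}
    for cond in pd.unique(labels):
        idx = np.nonzero(labels == cond)[0]
        if len(idx) == 0:
            warnings.warn(f"condition {cond!r} has no frames; skipped")
            continue
        groups[cond] = idx
    if target >= len(labels):
        return np.arange(len(labels))
    quota = {c: 0 for c in groups}
    remaining = dict(groups)
    budget = target
    while budget > 0 and remaining:
        share = budget // len(remaining)
        if share == 0:
            # hand out the last few frames one by one, deterministically
            for c in sorted(remaining, key=str)[:budget]:
                quota[c] += 1
            break
        done = []
        for c, idx in remaining.items():
            take = min(share, len(idx) - quota[c])
            quota[c] += take
            budget -= take
            if quota[c] == len(idx):
                done.append(c)
        if not done and all(quota[c] >= len(remaining[c]) or share == 0
                            for c in remaining):
            break
        if not done:
            continue
        for c in done:
            del remaining[c]
    chosen = [rng.choice(groups[c], size=quota[c], replace=False)
              for c in groups if quota[c] > 0]
    return np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=int)


def hdbscan_noise_scan(features: np.ndarray,
                       min_cluster_sizes=(50, 100, 200, 400),
                       min_samples=(5, 10, 20)) -> pd.DataFrame:
    """Noise fraction across an HDBSCAN parameter grid.

    The "stable regime" is the contiguous region of the grid where the
    noise fraction varies little; the table is returned for the caller to
    pick a plausible cluster-count range from.
    """
    X = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    grid = [(int(mcs), int(ms)) for mcs in min_cluster_sizes for ms in min_samples]
    if not grid:
        raise ValueError("empty parameter grid")
    rows = []
    for mcs, ms in grid:
        labels = HDBSCAN(min_cluster_size=mcs, min_samples=ms).fit_predict(X)
        rows.append({"min_cluster_size": mcs, "min_samples": ms,
                     "n_clusters": int(len(set(labels)) - (1 if -1 in labels else 0)),
                     "noise_fraction": float(np.mean(labels == -1))})
    return pd.DataFrame(rows)


def select_gmm(features: np.ndarray, k_range=range(1, 21), *,
               n_restarts: int = 5, seed: int = 0,
               covariance_type: str = "full",
               discovery_indices: np.ndarray | None = None) -> ClusterModel:
    """Fit GMMs over ``k_range``; keep the K minimizing BIC (AIC reported).

    Each K uses multiple EM restarts with the best likelihood kept; the
    selected model is refit at that K with the same seeds.
    """
    X = np.asarray(features, dtype=float)
    rows, models = [], {}
    for K in k_range:
        try:
            gm = GaussianMixture(n_components=K, covariance_type=covariance_type,
                                 n_init=n_restarts, random_state=seed,
                                 reg_covar=1e-6).fit(X)
        except Exception as exc:  # EM failure at this K: record and skip
            warnings.warn(f"GMM fit failed at K={K}: {exc}")
            continue
        rows.append({"K": K, "aic": gm.aic(X), "bic": gm.bic(X),
                     "log_likelihood": gm.score(X) * len(X)})
        models[K] = gm
    if not rows:
        raise RuntimeError("no GMM converged over the requested K range")
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["bic"].idxmin(), "K"])
    return ClusterModel(K=best_k, mixture=models[best_k], selection_table=table,
                        discovery_indices=(discovery_indices
                                           if discovery_indices is not None
                                           else np.arange(len(X))))


def embed_umap(features: np.ndarray, neighbors: int = 50,
               min_dist: float = 0.7, seed: int = 0) -> Embedding:
    """2-d UMAP embedding (visualization only; assignment is in feature space)."""
    X = np.asarray(features, dtype=float)
    if len(X) <= neighbors:
        raise ValueError("need more points than UMAP neighbors")
    import umap  # deferred: numba compilation is slow at import time

    coords = umap.UMAP(n_neighbors=neighbors, min_dist=min_dist,
                       n_components=2, random_state=seed).fit_transform(X)
    return Embedding(coords=np.asarray(coords, dtype=float),
                     neighbors=neighbors, min_dist=min_dist, seed=seed)


def propagate_labels(discovery_features: np.ndarray,
                     discovery_labels: np.ndarray,
                     query_features: np.ndarray, k: int = 15) -> np.ndarray:
    """kNN majority vote in feature space; ties go to the smallest label."""
    D = np.asarray(discovery_features, dtype=float)
    labels = np.asarray(discovery_labels)
    if k > len(D):
        raise ValueError("k exceeds the discovery set size")
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k).fit(D)
    _, idx = nn.kneighbors(np.asarray(query_features, dtype=float))
    votes = labels[idx]
    n_labels = int(labels.max()) + 1
    out = np.empty(len(votes), dtype=int)
    for i, row in enumerate(votes):
        out[i] = int(np.argmax(np.bincount(row, minlength=n_labels)))
    return out


def occupancy_maps(embedding_coords: np.ndarray, cluster_labels: np.ndarray,
                   animal_ids: np.ndarray, conditions: np.ndarray,
                   fps: float, grid_size: int = 80) -> dict:
    """Per-condition KDE over the embedding plus per-animal dwell times.

    Returns ``{condition: {"kde": (xx, yy, density), "dwell": DataFrame}}``
    where the dwell table is animal × cluster in seconds (rows sum to each
    animal's labeled recording duration).
    """
    emb = np.asarray(embedding_coords, dtype=float)
    labels = np.asarray(cluster_labels)
    n_clusters = int(labels.max()) + 1
    out = {}
    for cond in pd.unique(np.asarray(conditions)):
        sel = np.asarray(conditions) == cond
        if not np.any(sel):
            warnings.warn(f"condition {cond!r} empty; skipped")
            continue
        pts = emb[sel]
        kde = None
        if len(pts) > 2 and np.linalg.matrix_rank(np.cov(pts.T)) == 2:
            density = gaussian_kde(pts.T)  # Scott's rule bandwidth
            xx, yy = np.meshgrid(
                np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid_size),
                np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid_size))
            kde = (xx, yy, density(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape))
        rows = {}
        for animal in pd.unique(np.asarray(animal_ids)[sel]):
            a_sel = sel & (np.asarray(animal_ids) == animal)
            counts = np.bincount(labels[a_sel], minlength=n_clusters)
            rows[animal] = counts / fps
        dwell = pd.DataFrame(rows).T
        dwell.columns = [f"cluster_{c}" for c in range(n_clusters)]
        out[cond] = {"kde": kde, "dwell": dwell}
    return out
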