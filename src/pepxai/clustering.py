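"""Per-event-kind k-means clustering with silhouette-based model selection.

Each event family (increasing, decreasing, local_max, local_min) is pooled
across all instances, standardized per dimension, and partitioned with
k-means for every k in a configured range; the k with the highest mean
silhouette score wins, ties going to the smallest k. Standardization matters
because event parameters are on incommensurate scales — start times span
tens to hundreds of steps while average gradients are order one — and
unscaled Euclidean k-means would cluster on time alone. Centroids are stored
back in original units so that rules can be rendered in signal terms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import ConfigError, UndefinedSilhouetteError
from .events import EVENT_KINDS, InstanceEvents, event_vector

__all__ = [
    "ClusteringConfig",
    "ClusterModel",
    "flatten_events",
    "mean_silhouette",
    "fit_cluster_model",
    "fit_all_cluster_models",
]


@dataclass
class ClusteringConfig:
    """Knobs for the k-sweep.

    k_min/k_max bound the candidate cluster counts, n_restarts is the number
    of seeded k-means initializations kept by best inertia, scale_features
    toggles per-dimension standardization before clustering.
    """

    k_min: int = 2
    k_max: int = 10
    n_restarts: int = 10
    seed: int = 0
    scale_features: bool = True

    def __post_init__(self) -> None:
        if not (2 <= self.k_min <= self.k_max):
            raise ConfigError(f"need 2 <= k_min <= k_max, got [{self.k_min}, {self.k_max}]")
        if self.n_restarts < 1:
            raise ConfigError("n_restarts must be >= 1")


@dataclass
class ClusterModel:
    """A fitted partition of one event family's parameter space.

    ``centroids`` are in ORIGINAL units; ``scale_offsets`` / ``scale_factors``
    map original to the standardized space clustering ran in
    (``z = (x - offset) / factor``). ``k == 0`` flags an absent family (no
    events anywhere); ``k == 1`` is the degenerate single-centroid fallback.
    """

    kind: str
    k: int
    centroids: np.ndarray
    scale_offsets: np.ndarray
    scale_factors: np.ndarray
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    n_events_fit: int = 0

    def standardize(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (points - self.scale_offsets) / self.scale_factors

    @property
    def centroids_std(self) -> np.ndarray:
        """Centroids in the standardized space used for assignment."""
        return self.standardize(self.centroids)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "scale_offsets": self.scale_offsets.tolist(),
            "scale_factors": self.scale_factors.tolist(),
            "silhouette_by_k": {str(k): v for k, v in self.silhouette_by_k.items()},
            "n_events_fit": self.n_events_fit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterModel":
        return cls(
            kind=d["kind"],
            k=int(d["k"]),
            centroids=np.asarray(d["centroids"], dtype=float),
            scale_offsets=np.asarray(d["scale_offsets"], dtype=float),
            scale_factors=np.asarray(d["scale_factors"], dtype=float),
            silhouette_by_k={int(k): float(v) for k, v in d["silhouette_by_k"].items()},
            n_events_fit=int(d["n_events_fit"]),
        )

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "ClusterModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def flatten_events(
    all_events: list[InstanceEvents], kind: str
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Pool one event family over all instances into a point matrix.

    Returns the ``(n_events, n_params)`` matrix plus back-pointers
    ``(instance_id, within-instance index)`` for each row. An empty pool
    yields a 0-row matrix with the family's correct column count.
    """
    if kind not in EVENT_KINDS:
        raise ConfigError(f"unknown event kind {kind!r}")
    dim = 3 if kind in ("increasing", "decreasing") else 2
    rows, back = [], []
    for inst in all_events:
        for j, ev in enumerate(inst.events.get(kind, [])):
            rows.append(event_vector(ev))
            back.append((inst.instance_id, j))
    if not rows:
        return np.empty((0, dim)), []
    return np.vstack(rows), back


def mean_silhouette(points: np.ndarray, assignment) -> float:
    """Mean silhouette score of a partition (Euclidean; singletons score 0)."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(assignment)
    n_clusters = np.unique(labels).size
    if n_clusters < 2:
        raise UndefinedSilhouetteError(
            f"silhouette needs >= 2 clusters, got {n_clusters}"
        )
    if points.shape[0] < 3:
        raise UndefinedSilhouetteError("silhouette needs >= 3 points")
    return float(silhouette_score(points, labels, metric="euclidean"))


def _standardize_fit(points: np.ndarray, scale: bool) -> tuple[np.ndarray, np.ndarray]:
    dim = points.shape[1]
    if not scale:
        return np.zeros(dim), np.ones(dim)
    offsets = points.mean(axis=0)
    factors = points.std(axis=0)
    factors[factors == 0] = 1.0  # constant dimension: leave as-is
    return offsets, factors


def fit_cluster_model(points: np.ndarray, cfg: ClusteringConfig, kind: str) -> ClusterModel:
    """Sweep k over [k_min, k_max], choose by max mean silhouette.

    Degenerate pools (fewer than ``k_min + 1`` points, or all points
    identical) fall back to a single centroid at the pool mean (k=1). An
    empty pool returns a model with k=0 and no centroids, signalling that
    the event family is absent from the data.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ConfigError("points must be a 2-d matrix")
    n, dim = points.shape

    if n == 0:
        return ClusterModel(
            kind=kind,
            k=0,
            centroids=np.empty((0, dim)),
            scale_offsets=np.zeros(dim),
            scale_factors=np.ones(dim),
            n_events_fit=0,
        )

    offsets, factors = _standardize_fit(points, cfg.scale_features)
    z = (points - offsets) / factors
    n_distinct = np.unique(z, axis=0).shape[0]

    k_hi = min(cfg.k_max, n - 1, n_distinct)
    if n < cfg.k_min + 1 or n_distinct == 1 or k_hi < cfg.k_min:
        return ClusterModel(
            kind=kind,
            k=1,
            centroids=points.mean(axis=0, keepdims=True),
            scale_offsets=offsets,
            scale_factors=factors,
            n_events_fit=n,
        )

    silhouette_by_k: dict[int, float] = {}
    centroids_by_k: dict[int, np.ndarray] = {}
    for k in range(cfg.k_min, k_hi + 1):
        km = KMeans(
            n_clusters=k,
            n_init=cfg.n_restarts,
            random_state=cfg.seed,
            algorithm="lloyd",
        ).fit(z)
        if np.unique(km.labels_).size < 2:
            continue
        silhouette_by_k[k] = mean_silhouette(z, km.labels_)
        centroids_by_k[k] = km.cluster_centers_

    if not silhouette_by_k:
        return ClusterModel(
            kind=kind,
            k=1,
            centroids=points.mean(axis=0, keepdims=True),
            scale_offsets=offsets,
            scale_factors=factors,
            n_events_fit=n,
        )

    best = max(silhouette_by_k.values())
    chosen_k = min(k for k, s in silhouette_by_k.items() if s == best)
    centroids = centroids_by_k[chosen_k] * factors + offsets
    return ClusterModel(
        kind=kind,
        k=chosen_k,
        centroids=centroids,
        scale_offsets=offsets,
        scale_factors=factors,
        silhouette_by_k=silhouette_by_k,
        n_events_fit=n,
    )


def fit_all_cluster_models(
    all_events: list[InstanceEvents], cfg: ClusteringConfig
) -> dict[str, ClusterModel]:
    """Fit one ClusterModel per event family, in the canonical kind order."""
    models = {}
    for kind in EVENT_KINDS:
        points, _ = flatten_events(all_events, kind)
        models[kind] = fit_cluster_model(points, cfg, kind)
    return models
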