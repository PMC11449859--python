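"""Event attribution: turn clustered events into per-instance count features.

For each event family the fitted cluster model partitions parameter space;
each extracted event is assigned to its nearest centroid (Euclidean, in the
model's standardized space, ties to the smallest cluster index) and the
feature value D[i, j] is the number of instance i's events landing in
cluster j — a count, not a presence/absence bit, so instances with several
same-cluster events remain distinguishable from instances with one. The four
per-family tables are concatenated in the canonical kind order to form the
surrogate's training table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import ClusterModel
from .errors import AlignmentError, ConfigError, NoClustersError
from .events import EVENT_KINDS, InstanceEvents, event_vector

__all__ = [
    "FeatureMeta",
    "AttributionTable",
    "assign_event",
    "attribute",
    "attribute_all",
    "combine",
]


@dataclass(frozen=True)
class FeatureMeta:
    """What one count column means: an event family, a cluster, its centroid."""

    kind: str
    cluster: int
    centroid: tuple

    @property
    def name(self) -> str:
        return f"{self.kind}_c{self.cluster}"

    def to_dict(self) -> dict:
        return {"kind": self.kind, "cluster": self.cluster, "centroid": list(self.centroid)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureMeta":
        return cls(kind=d["kind"], cluster=int(d["cluster"]), centroid=tuple(d["centroid"]))


@dataclass
class AttributionTable:
    """Instances x cluster-count matrix with per-column metadata."""

    counts: np.ndarray
    feature_meta: list[FeatureMeta]
    instance_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2:
            raise ConfigError("counts must be 2-d")
        if self.counts.shape[1] != len(self.feature_meta):
            raise AlignmentError(
                f"{self.counts.shape[1]} columns vs {len(self.feature_meta)} feature_meta entries"
            )
        if self.counts.shape[0] != len(self.instance_ids):
            raise AlignmentError(
                f"{self.counts.shape[0]} rows vs {len(self.instance_ids)} instance ids"
            )
        if (self.counts < 0).any():
            raise ConfigError("counts must be non-negative")

    @property
    def column_names(self) -> list[str]:
        return [m.name for m in self.feature_meta]

    @property
    def n_instances(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, columns=self.column_names, index=self.instance_ids)

    def to_csv(self, path: str, meta_path: str | None = None) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path)
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump([m.to_dict() for m in self.feature_meta], fh, indent=2, sort_keys=True)


def assign_event(event, model: ClusterModel) -> int:
    """Nearest-centroid cluster index for one event (ties -> smallest j).

    Assignment happens in the model's standardized space, which extends
    cluster membership consistently to events never seen at fit time — the
    robustness metric re-attributes perturbed series through frozen models.
    """
    if model.k == 0:
        raise NoClustersError(f"cluster model for {model.kind!r} has no clusters")
    vec = event_vector(event)
    if vec.size != model.centroids.shape[1]:
        raise ConfigError(
            f"event of kind {event.kind!r} does not match model kind {model.kind!r}"
        )
    z = model.standardize(vec)[0]
    d2 = ((model.centroids_std - z) ** 2).sum(axis=1)
    return int(np.argmin(d2))  # argmin returns the first (smallest) index on ties


def attribute(all_events: list[InstanceEvents], model: ClusterModel) -> AttributionTable:
    """Count events per cluster for one event family.

    Instances with no events of the family yield an all-zero row; a k=0
    model (family absent at fit time) yields a 0-column table.
    """
    ids = [inst.instance_id for inst in all_events]
    if model.k == 0:
        return AttributionTable(
            counts=np.zeros((len(ids), 0), dtype=int), feature_meta=[], instance_ids=ids
        )
    meta = [
        FeatureMeta(kind=model.kind, cluster=j, centroid=tuple(model.centroids[j]))
        for j in range(model.k)
    ]
    counts = np.zeros((len(ids), model.k), dtype=int)
    for i, inst in enumerate(all_events):
        for ev in inst.events.get(model.kind, []):
            counts[i, assign_event(ev, model)] += 1
    return AttributionTable(counts=counts, feature_meta=meta, instance_ids=ids)


def attribute_all(
    all_events: list[InstanceEvents], models: dict[str, ClusterModel]
) -> dict[str, AttributionTable]:
    """One attribution table per event family, in canonical kind order."""
    tables = {}
    for kind in EVENT_KINDS:
        if kind not in models:
            raise ConfigError(f"no cluster model for event kind {kind!r}")
        tables[kind] = attribute(all_events, models[kind])
    return tables


def combine(tables) -> AttributionTable:
    """Column-wise concatenation of per-family tables into one feature table.

    Accepts a list (taken in order) or a kind-keyed mapping (taken in the
    canonical kind order). All tables must share instance ids and row order.
    """
    if isinstance(tables, dict):
        tables = [tables[k] for k in EVENT_KINDS if k in tables]
    tables = list(tables)
    if not tables:
        raise ConfigError("no tables to combine")
    ids = tables[0].instance_ids
    for t in tables[1:]:
        if t.instance_ids != ids:
            raise AlignmentError("tables have mismatched instance ids or row order")
    return AttributionTable(
        counts=np.hstack([t.counts for t in tables]),
        feature_meta=[m for t in tables for m in t.feature_meta],
        instance_ids=list(ids),
    )
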