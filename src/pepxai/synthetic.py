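"""Synthetic 2-class (or k-class) series with planted, class-discriminative
event motifs, plus transparent stub "black boxes".

The generator emulates the regime of short univariate classification
benchmarks (ECG-like heartbeat traces: length ~96-500, a few hundred to a
few thousand instances, two classes): each instance is a baseline (flat or
random walk) plus the sum of its class's motifs plus i.i.d. Gaussian noise.
Motifs are Gaussian-shaped bumps/troughs and linear ramps — exactly the
shapes the event vocabulary (runs and local extrema) can pick up, so planted
structure has a known event-space signature and pipeline recovery can be
asserted against ground truth.

Stub black boxes are deterministic rules over the raw series (peak over a
window exceeds a threshold, window mean exceeds a threshold, or the
generator's own labels), so a perfect-fidelity surrogate exists by
construction and failures localize to pipeline defects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets_io import BlackBoxPredictor, TimeSeriesDataset
from .errors import ConfigError

__all__ = [
    "MotifSpec",
    "SyntheticConfig",
    "GroundTruth",
    "generate",
    "make_stub_blackbox",
]

_MOTIFS = ("bump", "trough", "ramp_up", "ramp_down")


@dataclass(frozen=True)
class MotifSpec:
    """One planted shape: where, how wide, how tall, and how much it jitters.

    ``width`` is the motif's full temporal support; a bump is a Gaussian
    pulse with sigma = width/4 (so +-2 sigma spans the width) peaking at
    ``amplitude``; a ramp rises (falls) linearly by ``amplitude`` over the
    width and holds. ``jitter`` shifts the center uniformly in
    [-jitter, +jitter] per instance.
    """

    motif: str
    center: int
    width: int
    amplitude: float
    jitter: int = 0

    def __post_init__(self) -> None:
        if self.motif not in _MOTIFS:
            raise ConfigError(f"unknown motif {self.motif!r}")
        if self.width < 1:
            raise ConfigError("width must be >= 1")
        if self.amplitude == 0:
            raise ConfigError("amplitude must be nonzero")
        if self.jitter < 0:
            raise ConfigError("jitter must be >= 0")

    def check_bounds(self, series_length: int) -> None:
        lo = self.center - self.jitter - self.width // 2
        hi = self.center + self.jitter + self.width // 2
        if lo < 0 or hi > series_length - 1:
            raise ConfigError(
                f"motif {self.motif} at center {self.center} (width {self.width}, "
                f"jitter {self.jitter}) leaves [0, {series_length - 1}]"
            )


@dataclass
class SyntheticConfig:
    n_instances: int = 200
    series_length: int = 96
    class_motifs: dict = field(default_factory=dict)
    noise_sd: float = 0.1
    baseline: str = "flat"
    seed: int = 0
    class_proportions: dict | None = None
    random_walk_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_instances < 4:
            raise ConfigError("n_instances must be >= 4")
        if self.series_length < 2:
            raise ConfigError("series_length must be >= 2")
        if len(self.class_motifs) < 2:
            raise ConfigError("need at least 2 classes in class_motifs")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.baseline not in ("flat", "random_walk"):
            raise ConfigError(f"unknown baseline {self.baseline!r}")
        for motifs in self.class_motifs.values():
            for m in motifs:
                m.check_bounds(self.series_length)
        if self.class_proportions is not None:
            if set(self.class_proportions) != set(self.class_motifs):
                raise ConfigError("class_proportions keys must match class_motifs")
            if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
                raise ConfigError("class_proportions must sum to 1")


@dataclass
class GroundTruth:
    """Per-instance record of what was actually planted (post-jitter)."""

    labels: list
    motifs: list  # per instance: list of dicts with realized center etc.

    def to_dict(self) -> dict:
        return {"labels": self.labels, "motifs": self.motifs}


def _motif_signal(spec: MotifSpec, center: int, length: int) -> np.ndarray:
    t = np.arange(length, dtype=float)
    half = spec.width / 2.0
    if spec.motif in ("bump", "trough"):
        sigma = max(spec.width / 4.0, 0.5)
        shape = np.exp(-0.5 * ((t - center) / sigma) ** 2)
        return spec.amplitude * shape if spec.motif == "bump" else -abs(spec.amplitude) * shape
    # ramps: 0 before the support, linear over it, held after
    frac = np.clip((t - (center - half)) / spec.width, 0.0, 1.0)
    return spec.amplitude * frac if spec.motif == "ramp_up" else -spec.amplitude * frac


def _allocate_classes(cfg: SyntheticConfig) -> list:
    classes = sorted(cfg.class_motifs, key=str)
    if cfg.class_proportions is None:
        props = {c: 1.0 / len(classes) for c in classes}
    else:
        props = cfg.class_proportions
    counts = {c: int(round(props[c] * cfg.n_instances)) for c in classes}
    # fix rounding drift on the last class
    drift = cfg.n_instances - sum(counts.values())
    counts[classes[-1]] += drift
    labels = []
    for c in classes:
        labels += [c] * counts[c]
    return labels


def generate(cfg: SyntheticConfig) -> tuple[TimeSeriesDataset, GroundTruth]:
    """Deterministically generate a labeled dataset and its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    labels = _allocate_classes(cfg)
    n, length = cfg.n_instances, cfg.series_length

    values = np.zeros((n, length))
    gt_motifs: list[list[dict]] = []
    for i, label in enumerate(labels):
        if cfg.baseline == "flat":
            base = np.zeros(length)
        else:
            base = np.cumsum(rng.normal(0.0, cfg.random_walk_sd, size=length))
        row = base.copy()
        realized = []
        for spec in cfg.class_motifs[label]:
            center = spec.center
            if spec.jitter > 0:
                center += int(rng.integers(-spec.jitter, spec.jitter + 1))
            row += _motif_signal(spec, center, length)
            realized.append(
                {
                    "motif": spec.motif,
                    "center": center,
                    "width": spec.width,
                    "amplitude": spec.amplitude,
                }
            )
        if cfg.noise_sd > 0:
            row = row + rng.normal(0.0, cfg.noise_sd, size=length)
        values[i] = row
        gt_motifs.append(realized)

    ds = TimeSeriesDataset(
        values=values,
        labels=labels,
        instance_ids=[f"s{i}" for i in range(n)],
    )
    return ds, GroundTruth(labels=list(labels), motifs=gt_motifs)


def make_stub_blackbox(kind: str, params: dict) -> BlackBoxPredictor:
    """Build a deterministic stand-in classifier.

    * ``peak_threshold``: class 1 iff max over window [a, b] exceeds tau;
    * ``window_mean``: class 1 iff mean over [a, b] exceeds tau;
    * ``label_oracle``: returns the generator's true labels, matching query
      series to the reference dataset by nearest row (exact for unperturbed
      rows) — used for fidelity-ceiling tests.
    """
    if kind in ("peak_threshold", "window_mean"):
        a, b, tau = int(params["a"]), int(params["b"]), float(params["tau"])
        if a < 0 or b < a:
            raise ConfigError(f"bad window [{a}, {b}]")
        cls0 = params.get("class0", 0)
        cls1 = params.get("class1", 1)

        def predict_fn(X: np.ndarray):
            if b >= X.shape[1]:
                raise ConfigError(
                    f"window [{a}, {b}] outside series of length {X.shape[1]}"
                )
            window = X[:, a : b + 1]
            stat = window.max(axis=1) if kind == "peak_threshold" else window.mean(axis=1)
            return [cls1 if s > tau else cls0 for s in stat]

        return BlackBoxPredictor(predict_fn=predict_fn, classes=(cls0, cls1))

    if kind == "label_oracle":
        ref = params["dataset"]
        ref_values = np.asarray(
            ref.values if isinstance(ref, TimeSeriesDataset) else ref, dtype=float
        )
        labels = list(params["labels"])
        if len(labels) != ref_values.shape[0]:
            raise ConfigError("label_oracle labels must align with its reference dataset")

        def predict_fn(X: np.ndarray):
            out = []
            for row in X:
                d2 = ((ref_values - row) ** 2).sum(axis=1)
                out.append(labels[int(np.argmin(d2))])
            return out

        return BlackBoxPredictor(predict_fn=predict_fn, classes=tuple(sorted(set(labels), key=str)))

    raise ConfigError(f"unknown stub black-box kind {kind!r}")
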