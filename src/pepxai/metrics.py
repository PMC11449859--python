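"""Objective evaluation of the rule-based explanation.

Four quantities characterize an explanation:

* accuracy A = c/N — surrogate vs GROUND TRUTH labels on held-out rows;
* fidelity F = a/N — surrogate vs BLACK BOX labels (how faithfully the rules
  imitate the model);
* complexity — tree depth and total node count;
* robustness R — fraction of instances whose surrogate label survives a
  small input perturbation delta that leaves the black-box label unchanged:
  R = sum_n [g(x_n) = g(x_n + delta)] / N.

Robustness perturbs in RAW series space: delta is i.i.d. Gaussian per time
step with standard deviation epsilon * std(series), rejection-sampled until
the black box keeps its label (up to max_retries draws); g(.) then means the
full frozen transform — event extraction, nearest-centroid attribution with
the fitted cluster models, tree descent. Instances for which no admissible
delta is found are excluded from N and reported, never silently dropped.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass

import numpy as np

from .datasets_io import BlackBoxPredictor, TimeSeriesDataset
from .errors import ConfigError, EmptyEvaluationError, RobustnessUndefinedError

__all__ = [
    "PerturbationConfig",
    "EvaluationReport",
    "accuracy",
    "fidelity",
    "complexity",
    "robustness",
]


@dataclass
class PerturbationConfig:
    """Perturbation family for robustness: epsilon scales the noise to each
    series' own standard deviation (epsilon = 0 degenerates to the zero
    perturbation); max_retries bounds the rejection sampling; n_eval
    optionally caps how many instances are evaluated."""

    epsilon: float = 0.05
    max_retries: int = 20
    seed: int = 0
    n_eval: int | None = None

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ConfigError("epsilon must be >= 0")
        if self.max_retries < 1:
            raise ConfigError("max_retries must be >= 1")


@dataclass
class EvaluationReport:
    """The Table-style summary row: A, F, depth, #nodes, R plus bookkeeping."""

    accuracy: float
    fidelity: float
    depth: int
    n_nodes: int
    robustness: float
    n_test: int = 0
    n_robustness_evaluated: int = 0
    n_robustness_skipped: int = 0

    def __post_init__(self) -> None:
        for name in ("accuracy", "fidelity", "robustness"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_nodes < self.depth + 1:
            raise ConfigError("node count inconsistent with depth")

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "fidelity": self.fidelity,
            "depth": self.depth,
            "n_nodes": self.n_nodes,
            "robustness": self.robustness,
            "n_test": self.n_test,
            "n_robustness_evaluated": self.n_robustness_evaluated,
            "n_robustness_skipped": self.n_robustness_skipped,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_csv_row(self) -> str:
        """One-row CSV in the conventional Acc/Fidelity/#Depth/#Node/Rob layout."""
        header = "Acc,Fidelity,#Depth,#Node,Rob"
        row = (
            f"{self.accuracy:.4f},{self.fidelity:.4f},{self.depth},"
            f"{self.n_nodes},{self.robustness:.4f}"
        )
        return header + "\n" + row + "\n"


def _agreement(u, v) -> float:
    u, v = list(u), list(v)
    if len(u) != len(v):
        raise ConfigError(f"label vectors of lengths {len(u)} and {len(v)}")
    if not u:
        raise EmptyEvaluationError("no instances to evaluate")
    return sum(a == b for a, b in zip(u, v)) / len(u)


def accuracy(surrogate_labels, truth_labels) -> float:
    """A = c/N: proportion of surrogate labels matching the ground truth."""
    return _agreement(surrogate_labels, truth_labels)


def fidelity(surrogate_labels, blackbox_labels) -> float:
    """F = a/N: proportion of instances where surrogate and black box agree."""
    return _agreement(surrogate_labels, blackbox_labels)


def complexity(tree) -> tuple[int, int]:
    """(depth, total node count) of the surrogate tree."""
    return tree.depth, tree.n_nodes


def _instance_rng(seed: int, instance_id: str) -> np.random.Generator:
    # keyed by instance id, not row position, so evaluation is order-invariant
    key = zlib.crc32(str(instance_id).encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def robustness(
    ds: TimeSeriesDataset,
    predictor: BlackBoxPredictor,
    explain_fn,
    cfg: PerturbationConfig,
) -> tuple[float, int, int]:
    """R over label-preserving Gaussian perturbations.

    ``explain_fn`` is the frozen surrogate pipeline g(.): raw series matrix
    in, surrogate labels out. Returns (R, n_evaluated, n_skipped).
    """
    X = ds.values
    n = X.shape[0] if cfg.n_eval is None else min(cfg.n_eval, X.shape[0])
    base_f = predictor.predict(X[:n])
    base_g = list(explain_fn(X[:n]))

    agreements = 0
    evaluated = 0
    skipped = 0
    for i in range(n):
        x = X[i]
        scale = cfg.epsilon * float(x.std())
        rng = _instance_rng(cfg.seed, ds.instance_ids[i])
        delta = None
        if scale == 0.0:
            delta = np.zeros_like(x)  # degenerate epsilon -> 0 draw
        else:
            for _ in range(cfg.max_retries):
                cand = rng.normal(0.0, scale, size=x.shape)
                if predictor.predict((x + cand)[None])[0] == base_f[i]:
                    delta = cand
                    break
        if delta is None:
            skipped += 1
            continue
        evaluated += 1
        if explain_fn((x + delta)[None])[0] == base_g[i]:
            agreements += 1

    if evaluated == 0:
        raise RobustnessUndefinedError(
            f"no admissible perturbation found for any of {n} instances"
        )
    return agreements / evaluated, evaluated, skipped
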