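"""Pruned decision-tree surrogate and centroid-based rule rendering.

The surrogate is a CART tree (Gini impurity) fit on the event-count table
against the BLACK BOX's predicted labels — never the ground truth — so the
tree imitates the model, and its rules explain the model's behavior. The
table is split 70/30 (stratified on the predicted label when possible); the
cost-complexity pruning strength alpha is chosen automatically by
cross-validated agreement with the black box on the training part, with ties
going to the largest alpha because a shallower tree is the more readable
explanation.

Each internal node tests a cluster-count feature against a threshold
(counts are integers, so learned thresholds sit at half-integers); the
``<=`` branch goes left. Rules are root-to-leaf paths rendered through the
cluster centroid each feature stands for, e.g.::

    increases from time 70 to 71 with average value 0.79 <= 12.5
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier, export_graphviz

from .attribution import AttributionTable, FeatureMeta
from .datasets_io import PredictionSet
from .errors import ConfigError, SchemaError
from .events import RUN_KINDS

__all__ = [
    "SurrogateConfig",
    "SurrogateTree",
    "Condition",
    "Rule",
    "RuleSet",
    "split_train_test",
    "fit_surrogate",
    "predict_surrogate",
    "extract_rules",
    "render_condition",
    "render_rule",
]


@dataclass
class SurrogateConfig:
    train_fraction: float = 0.70
    stratify: bool = True
    ccp_alpha: float | str = "auto"
    cv_folds: int = 5
    seed: int = 0
    max_depth: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.ccp_alpha != "auto" and float(self.ccp_alpha) < 0:
            raise ConfigError("ccp_alpha must be >= 0 or 'auto'")


def split_train_test(
    table: AttributionTable, preds: PredictionSet, cfg: SurrogateConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 70/30 row split, stratified by the predicted label.

    Stratification silently degrades to a plain shuffled split (with a
    warning) when some predicted class has a single instance or the split is
    too small to hold every class on both sides.
    """
    n = table.n_instances
    if len(preds) != n:
        raise ConfigError(f"{len(preds)} predictions for {n} table rows")
    idx = np.arange(n)
    y = np.asarray(preds.labels, dtype=object)

    strat = y if cfg.stratify else None
    try:
        train_idx, test_idx = train_test_split(
            idx,
            train_size=cfg.train_fraction,
            random_state=cfg.seed,
            shuffle=True,
            stratify=strat,
        )
    except ValueError as exc:
        if strat is None:
            raise
        warnings.warn(
            f"stratified split failed ({exc}); falling back to unstratified",
            stacklevel=2,
        )
        train_idx, test_idx = train_test_split(
            idx, train_size=cfg.train_fraction, random_state=cfg.seed, shuffle=True
        )
    return np.sort(train_idx), np.sort(test_idx)


def _cv_splitter(y: np.ndarray, cv_folds: int, seed: int):
    _, counts = np.unique(y, return_counts=True)
    folds = min(cv_folds, len(y))
    if counts.min() >= 2:
        return StratifiedKFold(
            n_splits=min(folds, int(counts.min())), shuffle=True, random_state=seed
        )
    return KFold(n_splits=max(2, folds), shuffle=True, random_state=seed)


def _select_ccp_alpha(X: np.ndarray, y: np.ndarray, cfg: SurrogateConfig) -> float:
    """Pick alpha on the minimal-cost-complexity path by CV agreement.

    Ties (within 1e-12) go to the LARGEST alpha: the simplest tree that
    matches the black box as well as any other wins.
    """
    base = DecisionTreeClassifier(
        criterion="gini", random_state=cfg.seed, max_depth=cfg.max_depth
    )
    path = base.cost_complexity_pruning_path(X, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    if alphas.size <= 1:
        return float(alphas[0]) if alphas.size else 0.0

    splitter = _cv_splitter(y, cfg.cv_folds, cfg.seed)
    scores = np.zeros(alphas.size)
    for tr, va in splitter.split(X, y):
        for a_i, alpha in enumerate(alphas):
            tree = DecisionTreeClassifier(
                criterion="gini",
                random_state=cfg.seed,
                max_depth=cfg.max_depth,
                ccp_alpha=float(alpha),
            ).fit(X[tr], y[tr])
            scores[a_i] += float(np.mean(tree.predict(X[va]) == y[va]))
    best = scores.max()
    return float(alphas[np.nonzero(scores >= best - 1e-12)[0][-1]])


@dataclass
class SurrogateTree:
    """A fitted, pruned CART surrogate plus everything needed to explain it."""

    estimator: DecisionTreeClassifier
    feature_meta: list[FeatureMeta]
    chosen_alpha: float
    classes_: list
    train_indices: np.ndarray | None = None
    test_indices: np.ndarray | None = None

    @property
    def feature_names(self) -> list[str]:
        return [m.name for m in self.feature_meta]

    @property
    def depth(self) -> int:
        return int(self.estimator.get_depth())

    @property
    def n_nodes(self) -> int:
        return int(self.estimator.tree_.node_count)

    def _matrix_for(self, table) -> np.ndarray:
        if isinstance(table, AttributionTable):
            cols = {name: j for j, name in enumerate(table.column_names)}
            missing = [n for n in self.feature_names if n not in cols]
            if missing:
                raise SchemaError(f"table lacks surrogate features: {missing}")
            return table.counts[:, [cols[n] for n in self.feature_names]]
        X = np.atleast_2d(np.asarray(table, dtype=float))
        if X.shape[1] != len(self.feature_meta):
            raise SchemaError(
                f"expected {len(self.feature_meta)} feature columns, got {X.shape[1]}"
            )
        return X

    def predict(self, table) -> list:
        codes = self.estimator.predict(self._matrix_for(table))
        return [self.classes_[int(c)] for c in codes]

    def to_dot(self) -> str:
        return export_graphviz(
            self.estimator,
            feature_names=self.feature_names,
            class_names=[str(c) for c in self.classes_],
            filled=False,
            impurity=True,
        )


def fit_surrogate(
    train_counts: np.ndarray,
    train_labels,
    feature_meta: list[FeatureMeta],
    cfg: SurrogateConfig,
) -> SurrogateTree:
    """Fit the pruned CART surrogate on the training part of the table."""
    X = np.asarray(train_counts, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ConfigError("training table must have at least one feature column")
    if X.shape[0] < 2:
        raise ConfigError("need at least 2 training instances")
    if X.shape[1] != len(feature_meta):
        raise SchemaError(
            f"{X.shape[1]} columns vs {len(feature_meta)} feature_meta entries"
        )
    labels_list = list(train_labels)
    # labels may be arbitrary hashables; CART sees stable integer codes
    classes = sorted(set(labels_list), key=str)
    code = {c: j for j, c in enumerate(classes)}
    y = np.array([code[l] for l in labels_list], dtype=int)

    if cfg.ccp_alpha == "auto":
        alpha = _select_ccp_alpha(X, y, cfg) if len(classes) > 1 else 0.0
    else:
        alpha = float(cfg.ccp_alpha)

    est = DecisionTreeClassifier(
        criterion="gini",
        random_state=cfg.seed,
        max_depth=cfg.max_depth,
        ccp_alpha=alpha,
    ).fit(X, y)
    return SurrogateTree(
        estimator=est,
        feature_meta=list(feature_meta),
        chosen_alpha=alpha,
        classes_=classes,
    )


def predict_surrogate(tree: SurrogateTree, table) -> PredictionSet:
    """Apply the surrogate g(.) to a count table: one label per row."""
    return PredictionSet(labels=tree.predict(table), source="live_predictor")


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Condition:
    """One split on a root-to-leaf path, carrying its cluster centroid."""

    kind: str
    cluster: int
    centroid: tuple
    relation: str  # "≤" (left branch) or ">" (right branch)
    threshold: float

    def holds(self, count: float) -> bool:
        return count <= self.threshold if self.relation == "≤" else count > self.threshold

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "cluster": self.cluster,
            "centroid": list(self.centroid),
            "relation": "<=" if self.relation == "≤" else ">",
            "threshold": self.threshold,
        }


@dataclass
class Rule:
    conditions: list[Condition]
    predicted_class: object
    n_train: int = 0


@dataclass
class RuleSet:
    """One rule per leaf; jointly exhaustive and mutually exclusive."""

    rules: list[Rule]
    feature_meta: list[FeatureMeta] = field(default_factory=list)

    def predict_row(self, counts_by_name: dict) -> object:
        for rule in self.rules:
            if all(
                c.holds(counts_by_name[f"{c.kind}_c{c.cluster}"]) for c in rule.conditions
            ):
                return rule.predicted_class
        raise SchemaError("no rule matched; rule set is not exhaustive for this row")

    def predict(self, table: AttributionTable) -> list:
        names = table.column_names
        return [
            self.predict_row(dict(zip(names, row))) for row in table.counts
        ]

    def matching_rules(self, counts_by_name: dict) -> list[int]:
        return [
            r_i
            for r_i, rule in enumerate(self.rules)
            if all(
                c.holds(counts_by_name[f"{c.kind}_c{c.cluster}"]) for c in rule.conditions
            )
        ]

    def to_json(self, path: str) -> None:
        payload = [
            {
                "conditions": [c.to_dict() for c in r.conditions],
                "predicted_class": r.predicted_class,
                "n_train": r.n_train,
            }
            for r in self.rules
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def extract_rules(tree: SurrogateTree, feature_meta: list[FeatureMeta] | None = None) -> RuleSet:
    """Enumerate root-to-leaf paths depth-first (left branch first).

    Consecutive conditions on the same feature are kept verbatim in path
    order, never merged.
    """
    meta = feature_meta if feature_meta is not None else tree.feature_meta
    t = tree.estimator.tree_
    classes = tree.classes_  # est.classes_ are the codes 0..K-1, in this order
    rules: list[Rule] = []

    def walk(node: int, conds: list[Condition]) -> None:
        if t.children_left[node] == -1:  # leaf
            pred = classes[int(np.argmax(t.value[node][0]))]
            rules.append(
                Rule(
                    conditions=list(conds),
                    predicted_class=pred,
                    n_train=int(t.n_node_samples[node]),
                )
            )
            return
        m = meta[int(t.feature[node])]
        thr = float(t.threshold[node])
        walk(
            int(t.children_left[node]),
            conds + [Condition(m.kind, m.cluster, m.centroid, "≤", thr)],
        )
        walk(
            int(t.children_right[node]),
            conds + [Condition(m.kind, m.cluster, m.centroid, ">", thr)],
        )

    walk(0, [])
    return RuleSet(rules=rules, feature_meta=list(meta))


def _fmt_threshold(thr: float) -> str:
    return format(thr, "g")


def render_condition(cond: Condition, style: str = "narrative", article: bool = False) -> str:
    """Render one condition through its centroid.

    narrative style for run events reads
    ``{increases|decreases} from time {t} to {t+dura} with average value
    {v:.2f} {<=|>} {threshold}`` (``article=True`` inserts "an" before
    "average value"); extrema read ``local {maximum|minimum} at time {t}
    with value {v:.2f} {<=|>} {threshold}``. technical style is
    ``count({kind}_c{j}) {<=|>} {threshold}``.
    """
    if style == "technical":
        return f"count({cond.kind}_c{cond.cluster}) {cond.relation} {_fmt_threshold(cond.threshold)}"
    if style != "narrative":
        raise ConfigError(f"unknown rendering style {style!r}")
    if cond.kind in RUN_KINDS:
        verb = "increases" if cond.kind == "increasing" else "decreases"
        t0 = int(round(cond.centroid[0]))
        t1 = int(round(cond.centroid[0] + cond.centroid[1]))
        art = "an " if article else ""
        return (
            f"{verb} from time {t0} to {t1} with {art}average value "
            f"{cond.centroid[2]:.2f} {cond.relation} {_fmt_threshold(cond.threshold)}"
        )
    word = "maximum" if cond.kind == "local_max" else "minimum"
    t = int(round(cond.centroid[0]))
    return (
        f"local {word} at time {t} with value {cond.centroid[1]:.2f} "
        f"{cond.relation} {_fmt_threshold(cond.threshold)}"
    )


def render_rule(rule: Rule, style: str = "narrative", article: bool = False) -> str:
    """Render a whole rule: conditions joined by "and", then the class."""
    if not rule.conditions:
        return f"always ⇒ {rule.predicted_class}"
    body = " and ".join(render_condition(c, style=style, article=article) for c in rule.conditions)
    return f"{body} ⇒ {rule.predicted_class}"


def render_ruleset(rules: RuleSet, style: str = "narrative", article: bool = False) -> str:
    return "\n".join(render_rule(r, style=style, article=article) for r in rules.rules)
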