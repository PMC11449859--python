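"""scikit-learn-style estimators composing the full explanation pipeline.

:class:`PEPFeaturizer` is a transformer: raw series matrix in, event-cluster
count table out (fit learns the four cluster models, transform re-extracts
events and attributes them to frozen centroids). :class:`SurrogateTreeClassifier`
is a classifier over count tables targeting the black box's predicted labels,
with automatic cost-complexity pruning. :class:`PEPExplainer` chains the two,
handles the internal 70/30 surrogate split, and exposes rules and the
evaluation report. All three follow sklearn conventions (``get_params`` /
``set_params``, trailing-underscore fitted attributes) and compose with
sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .attribution import AttributionTable, attribute_all, combine
from .clustering import ClusteringConfig, fit_all_cluster_models
from .datasets_io import BlackBoxPredictor, PredictionSet, TimeSeriesDataset
from .errors import ConfigError
from .events import extract_all
from .metrics import (
    EvaluationReport,
    PerturbationConfig,
    accuracy,
    complexity,
    fidelity,
    robustness,
)
from .surrogate import (
    RuleSet,
    SurrogateConfig,
    extract_rules,
    fit_surrogate,
    render_ruleset,
    split_train_test,
)

__all__ = ["PEPFeaturizer", "SurrogateTreeClassifier", "PEPExplainer"]


def _as_dataset(X) -> TimeSeriesDataset:
    if isinstance(X, TimeSeriesDataset):
        return X
    return TimeSeriesDataset(values=np.atleast_2d(np.asarray(X, dtype=float)))


class PEPFeaturizer(TransformerMixin, BaseEstimator):
    """Transform raw series into per-cluster event counts.

    Parameters mirror the clustering and extraction knobs: ``k_min`` /
    ``k_max`` bound the silhouette sweep, ``n_restarts`` seeds k-means,
    ``scale_features`` standardizes event parameters before clustering,
    ``min_dura`` / ``min_abs_grad`` filter runs (permissive by default).

    Fitted attributes: ``cluster_models_`` (kind -> ClusterModel),
    ``feature_meta_``, ``feature_names_out_``.
    """

    def __init__(
        self,
        k_min: int = 2,
        k_max: int = 10,
        n_restarts: int = 10,
        scale_features: bool = True,
        min_dura: int = 1,
        min_abs_grad: float = 0.0,
        random_state: int = 0,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.n_restarts = n_restarts
        self.scale_features = scale_features
        self.min_dura = min_dura
        self.min_abs_grad = min_abs_grad
        self.random_state = random_state

    def _clustering_config(self) -> ClusteringConfig:
        return ClusteringConfig(
            k_min=self.k_min,
            k_max=self.k_max,
            n_restarts=self.n_restarts,
            seed=self.random_state,
            scale_features=self.scale_features,
        )

    def fit(self, X, y=None):
        ds = _as_dataset(X)
        events = extract_all(ds, min_dura=self.min_dura, min_abs_grad=self.min_abs_grad)
        self.cluster_models_ = fit_all_cluster_models(events, self._clustering_config())
        # feature metadata comes from an attribution pass over the fit data
        table = combine(attribute_all(events, self.cluster_models_))
        self.feature_meta_ = table.feature_meta
        self.feature_names_out_ = table.column_names
        self.n_features_out_ = len(self.feature_meta_)
        return self

    def transform_table(self, X) -> AttributionTable:
        """Like transform, but returns the full AttributionTable."""
        check_is_fitted(self, "cluster_models_")
        ds = _as_dataset(X)
        events = extract_all(ds, min_dura=self.min_dura, min_abs_grad=self.min_abs_grad)
        return combine(attribute_all(events, self.cluster_models_))

    def transform(self, X) -> np.ndarray:
        return self.transform_table(X).counts

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_out_")
        return np.asarray(self.feature_names_out_, dtype=object)


class SurrogateTreeClassifier(ClassifierMixin, BaseEstimator):
    """Pruned CART surrogate over a count table, sklearn-classifier shaped.

    ``y`` passed to :meth:`fit` must be the black box's predicted labels.
    Fitted attributes: ``tree_`` (the SurrogateTree wrapper),
    ``chosen_alpha_``, ``classes_``, ``rules_``.
    """

    def __init__(
        self,
        ccp_alpha="auto",
        cv_folds: int = 5,
        max_depth: int | None = None,
        random_state: int = 0,
        feature_meta=None,
    ):
        self.ccp_alpha = ccp_alpha
        self.cv_folds = cv_folds
        self.max_depth = max_depth
        self.random_state = random_state
        self.feature_meta = feature_meta

    def _surrogate_config(self) -> SurrogateConfig:
        return SurrogateConfig(
            ccp_alpha=self.ccp_alpha,
            cv_folds=self.cv_folds,
            seed=self.random_state,
            max_depth=self.max_depth,
        )

    def fit(self, X, y):
        if isinstance(X, AttributionTable):
            meta = X.feature_meta
            counts = X.counts
        else:
            counts = np.asarray(X, dtype=float)
            if self.feature_meta is None:
                raise ConfigError(
                    "feature_meta is required when fitting from a bare matrix"
                )
            meta = self.feature_meta
        self.tree_ = fit_surrogate(counts, y, meta, self._surrogate_config())
        self.chosen_alpha_ = self.tree_.chosen_alpha
        self.classes_ = np.asarray(self.tree_.classes_, dtype=object)
        self.rules_ = extract_rules(self.tree_)
        return self

    def predict(self, X):
        check_is_fitted(self, "tree_")
        return np.asarray(self.tree_.predict(X), dtype=object)

    @property
    def depth_(self) -> int:
        check_is_fitted(self, "tree_")
        return self.tree_.depth

    @property
    def n_nodes_(self) -> int:
        check_is_fitted(self, "tree_")
        return self.tree_.n_nodes


class PEPExplainer(BaseEstimator):
    """End-to-end global explainer: series + black-box labels in, rules out.

    ``fit(X, y)`` clusters events over ALL of X (the whole evaluation set is
    transformed, as the surrogate's feature space is defined globally), then
    splits the count table ``train_fraction``/rest stratified on the
    predicted label and fits the pruned surrogate on the training part.

    Fitted attributes include ``featurizer_``, ``surrogate_``, ``rules_``,
    ``train_indices_`` / ``test_indices_``.
    """

    def __init__(
        self,
        k_min: int = 2,
        k_max: int = 10,
        n_restarts: int = 10,
        scale_features: bool = True,
        min_dura: int = 1,
        min_abs_grad: float = 0.0,
        train_fraction: float = 0.70,
        stratify: bool = True,
        ccp_alpha="auto",
        cv_folds: int = 5,
        max_depth: int | None = None,
        random_state: int = 0,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.n_restarts = n_restarts
        self.scale_features = scale_features
        self.min_dura = min_dura
        self.min_abs_grad = min_abs_grad
        self.train_fraction = train_fraction
        self.stratify = stratify
        self.ccp_alpha = ccp_alpha
        self.cv_folds = cv_folds
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        """X: series matrix or TimeSeriesDataset; y: black-box labels."""
        ds = _as_dataset(X)
        preds = y if isinstance(y, PredictionSet) else PredictionSet(labels=list(y))
        if len(preds) != ds.n_instances:
            raise ConfigError(f"{len(preds)} labels for {ds.n_instances} instances")

        self.featurizer_ = PEPFeaturizer(
            k_min=self.k_min,
            k_max=self.k_max,
            n_restarts=self.n_restarts,
            scale_features=self.scale_features,
            min_dura=self.min_dura,
            min_abs_grad=self.min_abs_grad,
            random_state=self.random_state,
        ).fit(ds)
        table = self.featurizer_.transform_table(ds)
        self.table_ = table

        scfg = SurrogateConfig(
            train_fraction=self.train_fraction,
            stratify=self.stratify,
            ccp_alpha=self.ccp_alpha,
            cv_folds=self.cv_folds,
            seed=self.random_state,
            max_depth=self.max_depth,
        )
        train_idx, test_idx = split_train_test(table, preds, scfg)
        self.train_indices_ = train_idx
        self.test_indices_ = test_idx

        labels = np.asarray(preds.labels, dtype=object)
        self.surrogate_ = SurrogateTreeClassifier(
            ccp_alpha=self.ccp_alpha,
            cv_folds=self.cv_folds,
            max_depth=self.max_depth,
            random_state=self.random_state,
            feature_meta=table.feature_meta,
        ).fit(table.counts[train_idx], labels[train_idx])
        self.surrogate_.tree_.train_indices = train_idx
        self.surrogate_.tree_.test_indices = test_idx
        self.blackbox_labels_ = list(labels)
        self.rules_ = self.surrogate_.rules_
        self.classes_ = self.surrogate_.classes_
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "featurizer_")
        return self.featurizer_.transform(X)

    def predict(self, X):
        """g(.): raw series through the frozen transform and the tree."""
        check_is_fitted(self, "surrogate_")
        return self.surrogate_.predict(self.featurizer_.transform_table(X))

    def rules(self, style: str = "narrative", article: bool = False) -> str:
        check_is_fitted(self, "rules_")
        return render_ruleset(self.rules_, style=style, article=article)

    @property
    def ruleset_(self) -> RuleSet:
        check_is_fitted(self, "rules_")
        return self.rules_

    def evaluate(
        self,
        X,
        truth_labels,
        predictor: BlackBoxPredictor | None = None,
        perturbation: PerturbationConfig | None = None,
    ) -> EvaluationReport:
        """Compute the full report on the held-out part of the fit data.

        Accuracy and fidelity are measured on the internal test split of X
        (truth vs surrogate, black box vs surrogate). Robustness needs a live
        ``predictor`` for rejection sampling; when absent it degenerates to
        the zero-perturbation check (R = 1 by identity) over zero instances
        skipped.
        """
        check_is_fitted(self, "surrogate_")
        ds = _as_dataset(X)
        truth = list(truth_labels)
        if len(truth) != ds.n_instances:
            raise ConfigError("truth labels misaligned with X")
        test_idx = self.test_indices_
        g_all = list(self.predict(ds))
        g_test = [g_all[i] for i in test_idx]
        acc = accuracy(g_test, [truth[i] for i in test_idx])
        fid = fidelity(g_test, [self.blackbox_labels_[i] for i in test_idx])
        depth, n_nodes = complexity(self.surrogate_.tree_)

        if perturbation is None:
            perturbation = PerturbationConfig(seed=self.random_state)
        if predictor is not None:
            rob, n_eval, n_skip = robustness(
                ds, predictor, lambda M: list(self.predict(M)), perturbation
            )
        else:
            rob, n_eval, n_skip = 1.0, 0, 0
        return EvaluationReport(
            accuracy=acc,
            fidelity=fid,
            depth=depth,
            n_nodes=n_nodes,
            robustness=rob,
            n_test=len(test_idx),
            n_robustness_evaluated=n_eval,
            n_robustness_skipped=n_skip,
        )
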