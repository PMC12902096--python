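"""Two-stage model-combination search on the presence-absence matrix.

Stage 1 runs a feature-selection model (a tree ensemble ranked by impurity
importance, or a sparse linear model ranked by |coefficient| at a CV-chosen
penalty) to pinpoint candidate gene families.  Stage 2 fits a classifier on
the candidates: classifiers with embedded selection (sparse/importance-based)
take the whole candidate set, while unconstrained classifiers are evaluated
on incrementally growing top-k feature sets (batches of ``batch_size``) and
keep the k with the best mean stratified-CV accuracy.  Every combination in
one search is scored against identical fold assignments, so the leaderboard
is a paired comparison.  Saltwater is encoded as the positive class (1),
freshwater as 0; outgroup species never enter training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core_io import (
    AnalysisConfig,
    Habitat,
    PresenceAbsenceMatrix,
    SpeciesMetadata,
    ValidationError,
    logger,
)

ALGORITHMS = (
    "random_forest",
    "lasso",
    "ridge",
    "elastic_net",
    "linear_boosting",
    "svm_linear",
    "knn",
    "naive_bayes",
    "gradient_boosting",
    "decision_tree",
)

#: algorithms yielding sparse or importance-ranked fits (usable as selectors,
#: and fit directly on the candidate set when used as classifiers)
EMBEDDED = {
    "random_forest",
    "lasso",
    "elastic_net",
    "linear_boosting",
    "gradient_boosting",
    "decision_tree",
}

#: algorithms with signed per-feature weights (usable for weight categorization)
LINEAR = {"lasso", "ridge", "elastic_net", "linear_boosting", "svm_linear"}


@dataclass(frozen=True)
class ModelSpec:
    stage: str  # "selector" | "classifier"
    algorithm: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(f"unknown algorithm: {self.algorithm!r}")
        if self.stage == "selector" and not self.embedded_selection:
            raise ValidationError(
                f"{self.algorithm} cannot act as a selector (no embedded selection)"
            )
        if self.algorithm == "elastic_net":
            alpha = self.hyperparams.get("alpha", 0.5)
            if not 0 < alpha < 1:
                raise ValidationError("elastic_net mixing alpha must lie in (0, 1)")

    @property
    def embedded_selection(self) -> bool:
        return self.algorithm in EMBEDDED

    @property
    def label(self) -> str:
        if self.algorithm == "elastic_net":
            return f"elastic_net[{self.hyperparams.get('alpha', 0.5)}]"
        return self.algorithm


@dataclass
class ComboResult:
    selector: ModelSpec | None
    classifier: ModelSpec
    cv_accuracy: float
    fold_accuracies: np.ndarray
    n_features_used: int
    selected_families: list[str]
    weights: dict[str, float]


@dataclass(frozen=True)
class FeatureCategorization:
    salt_group: frozenset[str]
    fresh_group: frozenset[str]


class ComponentwiseLinearBoost(BaseEstimator, ClassifierMixin):
    """L2-boosting with componentwise linear base learners.

    At each step the single (centered) feature that best fits the current
    residual by least squares is chosen and its coefficient updated by a
    shrunken amount, yielding a sparse signed linear model in the style of
    boosted linear GLMs.
    """

    def __init__(self, n_steps: int = 150, learning_rate: float = 0.2):
        self.n_steps = n_steps
        self.learning_rate = learning_rate

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.classes_ = np.unique(y)
        target = np.where(y == self.classes_[-1], 1.0, -1.0)
        self._mean = X.mean(axis=0)
        xc = X - self._mean
        ss = (xc**2).sum(axis=0)
        coef = np.zeros(X.shape[1])
        self.intercept_ = target.mean()
        resid = target - self.intercept_
        usable = ss > 0
        for _ in range(self.n_steps):
            num = xc.T @ resid
            score = np.where(usable, num**2 / np.where(usable, ss, 1.0), -np.inf)
            j = int(np.argmax(score))
            if not np.isfinite(score[j]) or score[j] <= 0:
                break
            beta = num[j] / ss[j]
            coef[j] += self.learning_rate * beta
            resid -= self.learning_rate * beta * xc[:, j]
        self.coef_ = coef.reshape(1, -1)
        return self

    def decision_function(self, X):
        xc = np.asarray(X, dtype=float) - self._mean
        return self.intercept_ + xc @ self.coef_.ravel()

    def predict(self, X):
        pos = self.decision_function(X) >= 0
        return np.where(pos, self.classes_[-1], self.classes_[0])


def _make_estimator(spec: ModelSpec, seed: int, select_cv: bool = False):
    hp = spec.hyperparams
    algo = spec.algorithm
    if algo == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 200), random_state=seed, n_jobs=1
        )
    if algo == "lasso":
        if select_cv:
            return LogisticRegressionCV(
                l1_ratios=[1.0], solver="liblinear", Cs=[0.01, 0.1, 1.0, 10.0],
                cv=3, random_state=seed, max_iter=2000, scoring="accuracy",
                use_legacy_attributes=False,
            )
        return LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=hp.get("C", 1.0),
            random_state=seed, max_iter=2000,
        )
    if algo == "ridge":
        return LogisticRegression(l1_ratio=0.0, C=hp.get("C", 1.0), max_iter=2000)
    if algo == "elastic_net":
        alpha = hp.get("alpha", 0.5)
        if select_cv:
            return LogisticRegressionCV(
                solver="saga", l1_ratios=[alpha],
                Cs=[0.01, 0.1, 1.0, 10.0], cv=3, random_state=seed,
                max_iter=5000, scoring="accuracy", use_legacy_attributes=False,
            )
        return LogisticRegression(
            solver="saga", l1_ratio=alpha,
            C=hp.get("C", 1.0), max_iter=5000, random_state=seed,
        )
    if algo == "linear_boosting":
        return ComponentwiseLinearBoost(
            n_steps=hp.get("n_steps", 150),
            learning_rate=hp.get("learning_rate", 0.2),
        )
    if algo == "svm_linear":
        return SVC(kernel="linear", C=hp.get("C", 1.0), random_state=seed)
    if algo == "knn":
        return KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 5))
    if algo == "naive_bayes":
        return BernoulliNB()
    if algo == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=hp.get("n_estimators", 100), random_state=seed
        )
    if algo == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ValidationError(f"unknown algorithm: {algo!r}")


def habitat_labels(
    pam: PresenceAbsenceMatrix, meta: SpeciesMetadata
) -> tuple[pd.DataFrame, np.ndarray]:
    """Training matrix restricted to salt/fresh species and 0/1 labels."""
    rows, y = [], []
    for sp in pam.species_ids:
        hab = meta.habitat_of(sp)
        if hab == Habitat.SALTWATER:
            rows.append(sp)
            y.append(1)
        elif hab == Habitat.FRESHWATER:
            rows.append(sp)
            y.append(0)
    if len(set(y)) < 2:
        raise ValidationError("need both saltwater and freshwater species")
    return pam.values.loc[rows], np.asarray(y)


def build_registry(
    config: AnalysisConfig | None = None,
    selectors: Sequence[ModelSpec] | None = None,
    classifiers: Sequence[ModelSpec] | None = None,
    include_classifier_only: bool = True,
) -> list[tuple[ModelSpec | None, ModelSpec]]:
    """Deterministic ordered list of (selector, classifier) combinations.

    The default registry pairs every selector-capable algorithm (including
    elastic nets at mixing values 0.2/0.4/0.6/0.8) with every classifier,
    plus classifier-only entries with no pre-selection.
    """
    if selectors is None:
        selectors = [
            ModelSpec("selector", a)
            for a in ("random_forest", "lasso", "linear_boosting",
                      "gradient_boosting", "decision_tree")
        ] + [
            ModelSpec("selector", "elastic_net", {"alpha": a})
            for a in (0.2, 0.4, 0.6, 0.8)
        ]
    if classifiers is None:
        classifiers = [
            ModelSpec("classifier", a)
            for a in ("random_forest", "lasso", "ridge", "linear_boosting",
                      "svm_linear", "knn", "naive_bayes", "gradient_boosting",
                      "decision_tree")
        ] + [
            ModelSpec("classifier", "elastic_net", {"alpha": a})
            for a in (0.2, 0.4, 0.6, 0.8)
        ]
    registry: list[tuple[ModelSpec | None, ModelSpec]] = [
        (sel, clf) for sel in selectors for clf in classifiers
    ]
    if include_classifier_only:
        registry += [(None, clf) for clf in classifiers]
    logger.info("model registry holds %d combinations", len(registry))
    return registry


def stage1_select(
    pam: PresenceAbsenceMatrix,
    labels: np.ndarray,
    selector: ModelSpec,
    seed: int,
    X: pd.DataFrame | None = None,
) -> list[tuple[str, float]]:
    """Rank candidate families by the selector's importance.

    Tree ensembles keep families with impurity importance at or above the
    mean importance; sparse linear selectors keep nonzero coefficients at a
    CV-chosen penalty.  The returned list is ranked by descending score.
    """
    Xdf = pam.values if X is None else X
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("stage-1 selection needs two classes")
    est = _make_estimator(selector, seed, select_cv=True)
    est.fit(Xdf.to_numpy(float), y)
    if hasattr(est, "feature_importances_"):
        scores = np.asarray(est.feature_importances_, dtype=float)
        keep = scores >= scores.mean()
    else:
        scores = np.abs(np.asarray(est.coef_).ravel())
        keep = scores > 0
    order = np.lexsort((np.arange(len(scores)), -scores))
    families = list(Xdf.columns)
    return [(families[i], float(scores[i])) for i in order if keep[i]]


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, classifier: ModelSpec,
    folds: list[tuple[np.ndarray, np.ndarray]], seed: int,
) -> np.ndarray:
    accs = []
    for train, test in folds:
        est = _make_estimator(classifier, seed)
        est.fit(X[train], y[train])
        accs.append(float((est.predict(X[test]) == y[test]).mean()))
    return np.asarray(accs)


def _extract_weights(est, families: list[str]) -> tuple[dict[str, float], list[str]]:
    if hasattr(est, "coef_"):
        w = np.asarray(est.coef_).ravel()
    elif hasattr(est, "feature_importances_"):
        w = np.asarray(est.feature_importances_, dtype=float)
    else:
        w = np.zeros(len(families))
    weights = {f: float(v) for f, v in zip(families, w)}
    selected = [f for f, v in zip(families, w) if v != 0] or list(families)
    return weights, selected


def batch_grid(n_features: int, batch_size: int) -> list[int]:
    """k = batch, 2*batch, ... capped at n_features (which is always included)."""
    ks = list(range(batch_size, n_features + 1, batch_size))
    if not ks or ks[-1] != n_features:
        ks.append(n_features)
    return ks


def _fold_accuracy(
    Xdf: pd.DataFrame, y: np.ndarray, classifier: ModelSpec,
    folds, fold_features: list[list[str]], seed: int,
) -> np.ndarray:
    accs = []
    for (train, test), feats in zip(folds, fold_features):
        est = _make_estimator(classifier, seed)
        sub = Xdf[feats].to_numpy(float)
        est.fit(sub[train], y[train])
        accs.append(float((est.predict(sub[test]) == y[test]).mean()))
    return np.asarray(accs)


def stage2_evaluate(
    pam: PresenceAbsenceMatrix,
    labels: np.ndarray,
    ranking: list[tuple[str, float]],
    classifier: ModelSpec,
    cv_folds: int = 5,
    batch_size: int = 50,
    seed: int = 0,
    selector: ModelSpec | None = None,
    X: pd.DataFrame | None = None,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
    fold_rankings: list[list[tuple[str, float]]] | None = None,
) -> ComboResult:
    """Score one classifier on a stage-1 ranking with stratified CV.

    When ``fold_rankings`` (one ranking per fold, computed on that fold's
    training species only) are given, each fold's accuracy uses its own
    ranking, keeping the CV estimate free of selection leakage; the final
    reported model always uses the full-data ``ranking``.
    """
    if not ranking:
        raise ValidationError("empty stage-1 ranking")
    Xdf = pam.values if X is None else X
    y = np.asarray(labels)
    counts = np.bincount(y)
    if cv_folds > counts.min():
        raise ValidationError("cv_folds exceeds the smallest class count")
    if folds is None:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(np.zeros(len(y)), y))
    per_fold = (
        [[f for f, _ in r] for r in fold_rankings]
        if fold_rankings is not None
        else [[f for f, _ in ranking]] * len(folds)
    )
    if any(not r for r in per_fold):
        per_fold = [r if r else list(Xdf.columns) for r in per_fold]

    ranked_families = [f for f, _ in ranking]
    if classifier.embedded_selection:
        chosen = ranked_families
        fold_acc = _fold_accuracy(Xdf, y, classifier, folds, per_fold, seed)
    else:
        best = None
        for k in batch_grid(len(ranked_families), batch_size):
            feats = [r[: min(k, len(r))] for r in per_fold]
            acc = _fold_accuracy(Xdf, y, classifier, folds, feats, seed)
            mean = acc.mean()
            if best is None or mean > best[0] + 1e-12:
                best = (mean, k, acc)
        _, k, fold_acc = best
        chosen = ranked_families[:k]

    final = _make_estimator(classifier, seed)
    final.fit(Xdf[chosen].to_numpy(float), y)
    weights, selected = _extract_weights(final, chosen)
    return ComboResult(
        selector=selector,
        classifier=classifier,
        cv_accuracy=float(fold_acc.mean()),
        fold_accuracies=fold_acc,
        n_features_used=len(selected),
        selected_families=selected,
        weights={f: weights[f] for f in selected},
    )


def run_combination_search(
    pam: PresenceAbsenceMatrix,
    meta: SpeciesMetadata,
    registry: list[tuple[ModelSpec | None, ModelSpec]],
    config: AnalysisConfig,
) -> tuple[ComboResult, list[ComboResult]]:
    """Evaluate every combination against identical folds; return the best.

    Ties in CV accuracy are broken by fewer features used, then by registry
    order, so the leaderboard is fully deterministic.
    """
    if not registry:
        raise ValidationError("empty model registry")
    X, y = habitat_labels(pam, meta)
    if config.cv_folds > np.bincount(y).min():
        raise ValidationError("cv_folds exceeds the smallest class count")
    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed
    )
    folds = list(skf.split(np.zeros(len(y)), y))

    results: list[ComboResult] = []
    rank_cache: dict[str, tuple[list[tuple[str, float]],
                                list[list[tuple[str, float]]]]] = {}
    for selector, classifier in registry:
        if selector is None:
            ranking = [(f, 0.0) for f in X.columns]
            fold_rankings = None
        else:
            key = selector.label
            if key not in rank_cache:
                full = stage1_select(pam, y, selector, config.seed, X=X)
                per_fold = [
                    stage1_select(
                        pam, y[train], selector, config.seed,
                        X=X.iloc[train],
                    )
                    for train, _ in folds
                ]
                rank_cache[key] = (full, per_fold)
            ranking, fold_rankings = rank_cache[key]
            if not ranking:
                ranking = [(f, 0.0) for f in X.columns]
        results.append(
            stage2_evaluate(
                pam, y, ranking, classifier,
                cv_folds=config.cv_folds, batch_size=config.batch_size,
                seed=config.seed, selector=selector, X=X, folds=folds,
                fold_rankings=fold_rankings,
            )
        )
    best = min(
        range(len(results)),
        key=lambda i: (-results[i].cv_accuracy, results[i].n_features_used, i),
    )
    return results[best], results


def categorize_by_weight(
    best: ComboResult, positive_class: Habitat = Habitat.SALTWATER
) -> FeatureCategorization:
    """Split the best combo's families by the sign of their weights.

    Positive weights push toward the positive class (saltwater by default).
    Requires a final-stage model with signed coefficients.
    """
    if best.classifier.algorithm not in LINEAR:
        raise ValidationError(
            "weight categorization needs a linear final-stage classifier "
            f"(got {best.classifier.algorithm}); rerun with e.g. elastic_net"
        )
    pos = {f for f, w in best.weights.items() if w > 0}
    neg = {f for f, w in best.weights.items() if w < 0}
    if positive_class == Habitat.SALTWATER:
        return FeatureCategorization(frozenset(pos), frozenset(neg))
    return FeatureCategorization(frozenset(neg), frozenset(pos))


def leaderboard(results: list[ComboResult]) -> pd.DataFrame:
    """Flat leaderboard table of a combination search."""
    rows = []
    for r in results:
        rows.append(
            dict(
                selector=r.selector.label if r.selector else "none",
                classifier=r.classifier.label,
                n_features=r.n_features_used,
                cv_accuracy=r.cv_accuracy,
            )
        )
    return pd.DataFrame(rows).sort_values(
        ["cv_accuracy", "n_features"], ascending=[False, True], kind="stable"
    )
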