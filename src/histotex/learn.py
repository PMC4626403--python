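"""Ensemble classifiers and stratified cross-validation.

Bagging and AdaBoost are implemented here directly from their classical
pseudo-code on tree weak learners:

* **Bagging** — L bootstrap samples (with replacement, size N), one unpruned
  CART tree per sample, majority vote; per-class scores are vote fractions.
* **AdaBoost (M1-style, by resampling)** — weights start at 1/N; each round
  draws a weighted resample, fits a depth-limited tree, and computes the
  weighted error ε_k on the full training set.  Rounds with ε_k = 0 or
  ε_k ≥ 0.5 are discarded and the weights reset to 1/N; otherwise
  β_k = ε_k/(1−ε_k), misclassified weights are divided by β_k (via the
  normalized update w ∝ w·β^(1−l)), and the member votes with weight
  ln(1/β_k).  Class support μ_t(x) = Σ_{D_k(x)=t} ln(1/β_k).

Fisher (least-squares linear discriminant), linear SVM and a 50-tree random
forest are provided as baselines behind the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable


# ---------------------------------------------------------------------------
# ensembles

@dataclass
class EnsembleModel:
    members: list
    classes: np.ndarray
    member_weights: list[float] | None = None  # ln(1/β_k); None → majority vote
    vote_rule: str = "majority"

    def support(self, x: np.ndarray) -> np.ndarray:
        """Per-class score: vote fraction (majority) or Σ ln(1/β) (weighted)."""
        x = np.asarray(x)
        if not self.members:
            return np.zeros((x.shape[0], len(self.classes)))
        votes = np.stack([m.predict(x) for m in self.members])  # L × n
        scores = np.zeros((x.shape[0], len(self.classes)))
        weights = (self.member_weights if self.member_weights is not None
                   else [1.0] * len(self.members))
        for vote, w in zip(votes, weights):
            for t, cls in enumerate(self.classes):
                scores[:, t] += w * (vote == cls)
        if self.vote_rule == "majority":
            scores /= max(len(self.members), 1)
        return scores

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.support(x), axis=1)]


def _default_bagging_tree(seed: int):
    return DecisionTreeClassifier(random_state=seed)


def _default_boosting_tree(seed: int):
    return DecisionTreeClassifier(max_depth=3, random_state=seed)


def bagging_train(x, y, n_members: int = 50, seed: int = 0,
                  base_learner: Callable[[int], object] | None = None) -> EnsembleModel:
    """Bootstrap-aggregated trees with majority voting."""
    if n_members < 1:
        raise ValueError("ensemble size must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    base_learner = base_learner or _default_bagging_tree
    members = []
    n = len(y)
    for k in range(n_members):
        idx = rng.integers(0, n, size=n)
        clf = base_learner(int(rng.integers(2**31)))
        clf.fit(x[idx], y[idx])
        members.append(clf)
    return EnsembleModel(members, np.unique(y), None, "majority")


@dataclass
class BoostTrace:
    """Per-round diagnostics of AdaBoost training (weights before each round,
    the round's ε and β, and whether the member was retained)."""

    weights: list[np.ndarray] = field(default_factory=list)
    epsilons: list[float] = field(default_factory=list)
    betas: list[float] = field(default_factory=list)
    retained: list[bool] = field(default_factory=list)


def adaboost_train(x, y, n_members: int = 50, seed: int = 0,
                   base_learner: Callable[[int], object] | None = None,
                   max_attempts: int | None = None,
                   trace: BoostTrace | None = None) -> EnsembleModel:
    """Boosting by weighted resampling with the ε ∈ (0, 0.5) retention rule.

    ``max_attempts`` caps total rounds (default 5·L) so the discard/reset rule
    cannot loop forever on hard data; the ensemble may then hold fewer than L
    members.  If every round is discarded (e.g. ε = 0 throughout on trivially
    separable data), a single unweighted learner is fitted as a fallback.
    """
    if n_members < 1:
        raise ValueError("ensemble size must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    n = len(y)
    rng = np.random.default_rng(seed)
    base_learner = base_learner or _default_boosting_tree
    max_attempts = max_attempts or 5 * n_members
    w = np.full(n, 1.0 / n)
    members: list = []
    log_inv_beta: list[float] = []
    attempts = 0
    while len(members) < n_members and attempts < max_attempts:
        attempts += 1
        if trace is not None:
            trace.weights.append(w.copy())
        idx = rng.choice(n, size=n, replace=True, p=w)
        clf = base_learner(int(rng.integers(2**31)))
        clf.fit(x[idx], y[idx])
        miss = (clf.predict(x) != y).astype(float)
        eps = float((w * miss).sum())
        if trace is not None:
            trace.epsilons.append(eps)
        if eps == 0.0 or eps >= 0.5:
            w = np.full(n, 1.0 / n)
            if trace is not None:
                trace.betas.append(np.nan)
                trace.retained.append(False)
            continue
        beta = eps / (1.0 - eps)
        w = w * beta ** (1.0 - miss)
        w /= w.sum()
        members.append(clf)
        log_inv_beta.append(float(np.log(1.0 / beta)))
        if trace is not None:
            trace.betas.append(beta)
            trace.retained.append(True)
    if not members:
        # every round was discarded (ε = 0 on trivially separable data, or
        # ε ≥ 0.5 throughout); fall back to one unweighted learner so the
        # model stays usable rather than returning an empty ensemble
        clf = base_learner(int(rng.integers(2**31)))
        clf.fit(x, y)
        members, log_inv_beta = [clf], [1.0]
    return EnsembleModel(members, np.unique(y), log_inv_beta, "weighted_log")


# ---------------------------------------------------------------------------
# baselines

class FisherClassifier:
    """One-vs-rest least-squares linear discriminant on z-scored features.

    Each class fits w minimising ‖Xw − t‖² with targets ±1 and a small ridge
    term guarding singular scatter; prediction is the argmax discriminant.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        self.mean_ = x.mean(axis=0)
        std = x.std(axis=0)
        self.std_ = np.where(std > 0, std, 1.0)
        z = np.column_stack([(x - self.mean_) / self.std_, np.ones(len(x))])
        self.classes_ = np.unique(y)
        gram = z.T @ z + self.ridge * np.eye(z.shape[1])
        targets = np.stack([(y == c).astype(float) * 2 - 1 for c in self.classes_], axis=1)
        self.coef_ = np.linalg.solve(gram, z.T @ targets)
        return self

    def decision_function(self, x):
        x = np.asarray(x, dtype=float)
        z = np.column_stack([(x - self.mean_) / self.std_, np.ones(len(x))])
        scores = z @ self.coef_
        return scores[:, 1] if len(self.classes_) == 2 else scores

    def predict(self, x):
        scores = self.decision_function(x)
        if scores.ndim == 1:
            return np.where(scores > 0, self.classes_[1], self.classes_[0])
        return self.classes_[np.argmax(scores, axis=1)]


class _ZScoredLinearSVC:
    """Linear one-vs-rest SVM with internal feature standardization."""

    def __init__(self, seed: int = 0, C: float = 1.0):
        self._svc = LinearSVC(C=C, random_state=seed)

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        self.mean_ = x.mean(axis=0)
        std = x.std(axis=0)
        self.std_ = np.where(std > 0, std, 1.0)
        self._svc.fit((x - self.mean_) / self.std_, y)
        self.classes_ = self._svc.classes_
        return self

    def decision_function(self, x):
        return self._svc.decision_function((np.asarray(x, float) - self.mean_) / self.std_)

    def predict(self, x):
        return self._svc.predict((np.asarray(x, float) - self.mean_) / self.std_)


def baseline_train(x, y, kind: str, seed: int = 0, **params):
    """Fit one of the contracted baselines: fisher, svm_linear, random_forest."""
    if kind == "fisher":
        return FisherClassifier(**params).fit(x, y)
    if kind == "svm_linear":
        return _ZScoredLinearSVC(seed=seed, **params).fit(x, y)
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=params.pop("n_estimators", 50),
                                      random_state=seed, **params).fit(x, y)
    raise ValueError("kind must be one of: fisher, svm_linear, random_forest")


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class ClassifierSpec:
    """Classifier choice plus the preprocessing refit inside each fold."""

    kind: str = "bagging"  # bagging | adaboost | fisher | svm_linear | random_forest
    n_members: int = 50
    params: dict = field(default_factory=dict)
    reduce_threshold: float | None = None
    paper_mode: bool = False
    """True → fit the correlation filter once on all data (single global fit); False → refit inside each training fold."""


@dataclass
class CVResult:
    predictions: np.ndarray
    truth: np.ndarray
    scores: np.ndarray  # samples × classes
    classes: np.ndarray
    fold_assignment: np.ndarray
    seed: int

    @property
    def accuracy(self) -> float:
        return float((self.predictions == self.truth).mean())


def _fit_predict(spec: ClassifierSpec, x_tr, y_tr, x_te, seed: int):
    if spec.kind == "bagging":
        model = bagging_train(x_tr, y_tr, spec.n_members, seed, **spec.params)
    elif spec.kind == "adaboost":
        model = adaboost_train(x_tr, y_tr, spec.n_members, seed, **spec.params)
    else:
        model = baseline_train(x_tr, y_tr, spec.kind, seed, **spec.params)
    pred = model.predict(x_te)
    if hasattr(model, "support"):
        scores = model.support(x_te)
    elif hasattr(model, "predict_proba"):
        scores = model.predict_proba(x_te)
    else:
        scores = model.decision_function(x_te)
        if scores.ndim == 1:
            scores = np.column_stack([-scores, scores])
    return model, pred, scores


def cross_validate(table: FeatureTable, spec: ClassifierSpec,
                   folds: int = 10, seed: int = 0) -> CVResult:
    """Stratified k-fold CV; every sample is predicted exactly once.

    When ``spec.reduce_threshold`` is set, the correlation filter is fitted on
    the training rows of each fold (or once globally in paper mode) and
    applied to both splits before classification.
    """
    from .reduce import apply_filter, fit_correlation_filter

    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = table.labels
    classes = np.unique(y)
    if spec.reduce_threshold is not None and spec.paper_mode:
        table = apply_filter(table, fit_correlation_filter(table, spec.reduce_threshold))
    x_all = table.matrix
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=y.dtype)
    scores = np.zeros((len(y), len(classes)))
    fold_assignment = np.empty(len(y), dtype=int)
    col_index = {c: i for i, c in enumerate(table.feature_names)}
    rng = np.random.default_rng(seed)
    for fold, (tr, te) in enumerate(skf.split(x_all, y)):
        fold_assignment[te] = fold
        if spec.reduce_threshold is not None and not spec.paper_mode:
            sub = fit_correlation_filter(table.subset_rows(tr), spec.reduce_threshold)
            cols = [col_index[c] for c in sub.kept_features]
            x_tr, x_te = x_all[np.ix_(tr, cols)], x_all[np.ix_(te, cols)]
        else:
            x_tr, x_te = x_all[tr], x_all[te]
        _, p, s = _fit_predict(spec, x_tr, y[tr], x_te, int(rng.integers(2**31)))
        pred[te] = p
        # member classes may be a subset in degenerate folds; align columns
        fold_classes = np.unique(y[tr])
        for t, cls in enumerate(classes):
            j = np.flatnonzero(fold_classes == cls)
            if j.size and s.shape[1] == len(fold_classes):
                scores[te, t] = s[:, j[0]]
    return CVResult(pred, y.copy(), scores, classes, fold_assignment, seed)
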