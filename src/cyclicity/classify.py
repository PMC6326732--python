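"""Group classification protocols over lead-matrix features.

Runs Monte Carlo half-split classification: in every trial half of each
group's subjects (all their runs) form the training set and the other
half the test set.  Features are reduced either by PCA to 10 components
(fitted on the training half only), by whole-data Wilks-top-20 selection
(a documented double-dipping mode), or by within-trial Wilks stability
selection of the 10 most stable pairs.  Five classifiers are available:
linear/quadratic SVM, linear/quadratic discriminant analysis, and PLS-DA
with 20 latent components (classes coded ±1, decision threshold 0).

Confusion matrices follow the convention: rows are the true class,
columns the predicted class, entries row-normalized percentages averaged
over trials.  The overall accuracy is the class-size-weighted mean of the
per-class rates, which equals the plain fraction of test runs correct
when groups keep their natural sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.svm import SVC

from .core import DataError
from .features import CohortFeatures
from .selection import monte_carlo_stability, select_stable, select_top

__all__ = [
    "ClassificationProtocol",
    "ConfusionReport",
    "CLASSIFIERS",
    "split_half",
    "fit_predict",
    "monte_carlo_classification",
    "report",
    "weighted_overall",
]

CLASSIFIERS = ("linear_svm", "quadratic_svm", "lda", "qda", "plsda")
FEATURE_MODES = ("raw", "pca10", "wilks_top20_whole", "wilks_top10_stable")


@dataclass
class ClassificationProtocol:
    """One classification recipe: feature reduction, classifier, trial plan."""

    feature_mode: str = "pca10"
    classifier: str = "linear_svm"
    plsda_components: int = 20
    pca_components: int = 10
    balance_classes: bool = False
    n_trials: int = 100
    stability_trials: int = 1000  # inner Wilks trials for wilks_top10_stable
    stability_top_k: int = 20
    n_stable: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_mode not in FEATURE_MODES:
            raise ValueError(f"unknown feature mode {self.feature_mode!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")


@dataclass
class ConfusionReport:
    classes: list[str]
    matrix: np.ndarray  # 2x2 row-normalized percentages
    overall_accuracy: float  # percentage
    class_sizes: list[int]
    per_trial_counts: list[np.ndarray] = field(default_factory=list, repr=False)
    trial_seeds: list[int] = field(default_factory=list, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.classes, columns=self.classes)


def _subset(features: CohortFeatures, mask: np.ndarray) -> CohortFeatures:
    return CohortFeatures(
        features.meta[mask].reset_index(drop=True), features.X[mask], features.pair_index
    )


def split_half(
    features: CohortFeatures, balance: bool = False, seed: int = 0
) -> tuple[CohortFeatures, CohortFeatures]:
    """Subject-level half split; optionally subsample the majority training group.

    All of a subject's runs land on the same side, preventing identity
    leakage between train and test.
    """
    rng = np.random.default_rng(seed)
    sg = features.subject_group()
    groups = sorted(np.unique(sg.to_numpy()))
    train_subjects: list[str] = []
    for g in groups:
        subs = sorted(sg[sg == g].index)
        if len(subs) < 2:
            raise DataError(f"group {g!r} has fewer than 2 subjects")
        n_half = len(subs) // 2
        train_subjects.extend(rng.choice(subs, size=n_half, replace=False))
    train_set = set(train_subjects)
    if balance:
        by_group = {g: sorted(s for s in train_set if sg[s] == g) for g in groups}
        n_min = min(len(v) for v in by_group.values())
        train_set = set()
        for g in groups:
            train_set.update(rng.choice(by_group[g], size=n_min, replace=False))
    train_mask = features.meta["subject"].isin(train_set).to_numpy()
    # test = everything outside the training half (balancing only shrinks train)
    test_mask = ~features.meta["subject"].isin(set(train_subjects)).to_numpy()
    return _subset(features, train_mask), _subset(features, test_mask)


def _make_classifier(name: str, n_components: int):
    if name == "linear_svm":
        return SVC(kernel="linear", C=1.0)
    if name == "quadratic_svm":
        return SVC(kernel="poly", degree=2, coef0=1.0, C=1.0)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "qda":
        return QuadraticDiscriminantAnalysis()
    if name == "plsda":
        return PLSRegression(n_components=n_components)
    raise ValueError(name)


def _reduce(protocol: ClassificationProtocol, train: CohortFeatures, test: CohortFeatures, seed: int):
    """Column/projection reduction fitted on the training half only."""
    if protocol.feature_mode == "raw":
        return train.X, test.X
    if protocol.feature_mode == "pca10":
        n = min(protocol.pca_components, train.X.shape[0] - 1, train.X.shape[1])
        pca = PCA(n_components=n, svd_solver="full").fit(train.X)
        return pca.transform(train.X), pca.transform(test.X)
    if protocol.feature_mode == "wilks_top20_whole":
        raise RuntimeError("whole-data selection must be resolved before trials")
    if protocol.feature_mode == "wilks_top10_stable":
        ranking = monte_carlo_stability(
            train, n_trials=protocol.stability_trials,
            top_k=protocol.stability_top_k, seed=seed,
        )
        pairs = select_stable(ranking, protocol.n_stable)
        cols = [train.pair_index.index(p) for p in pairs]
        return train.X[:, cols], test.X[:, cols]
    raise ValueError(protocol.feature_mode)


def fit_predict(
    protocol: ClassificationProtocol,
    train: CohortFeatures,
    test: CohortFeatures,
    *,
    columns: list[int] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Train the protocol's classifier and label every test run.

    ``columns`` (if given) preselects feature columns and bypasses the
    protocol's reduction — used by the whole-data Wilks mode.
    """
    classes = sorted(np.unique(train.meta["group"]))
    if len(classes) != 2:
        raise DataError("classification requires exactly two groups")
    if columns is not None:
        xtr, xte = train.X[:, columns], test.X[:, columns]
    else:
        xtr, xte = _reduce(protocol, train, test, seed)
    ytr = (train.meta["group"].to_numpy() == classes[1]).astype(int)
    if protocol.classifier == "plsda":
        n_comp = min(protocol.plsda_components, xtr.shape[1], xtr.shape[0] - 1)
        model = _make_classifier("plsda", n_comp)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(xtr, 2.0 * ytr - 1.0)  # ±1 coding
            scores = model.predict(xte).ravel()
        pred = (scores > 0).astype(int)
    elif protocol.classifier == "qda":
        model = _make_classifier("qda", 0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(xtr, ytr)
                pred = model.predict(xte)
            except np.linalg.LinAlgError:
                model = QuadraticDiscriminantAnalysis(reg_param=0.1)
                model.fit(xtr, ytr)
                pred = model.predict(xte)
    else:
        model = _make_classifier(protocol.classifier, 0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(xtr, ytr)
            pred = model.predict(xte)
    return np.array([classes[p] for p in pred])


def _confusion_counts(true: np.ndarray, pred: np.ndarray, classes: list[str]) -> np.ndarray:
    counts = np.zeros((2, 2), dtype=int)
    for i, ci in enumerate(classes):
        for j, cj in enumerate(classes):
            counts[i, j] = int(np.sum((true == ci) & (pred == cj)))
    return counts


def weighted_overall(diag_percent: np.ndarray, class_sizes: list[int]) -> float:
    """Class-size-weighted mean of per-class correct rates (percentages)."""
    sizes = np.asarray(class_sizes, dtype=float)
    return float(np.sum(sizes * np.asarray(diag_percent)) / sizes.sum())


def report(
    counts: np.ndarray, class_sizes: list[int], classes: list[str] | None = None
) -> ConfusionReport:
    """Row-normalized percentage confusion matrix plus weighted overall accuracy."""
    counts = np.asarray(counts, dtype=float)
    row = counts.sum(axis=1, keepdims=True)
    if np.any(row == 0):
        raise DataError("empty confusion row: a class was never tested")
    matrix = 100.0 * counts / row
    overall = weighted_overall(np.diag(matrix), class_sizes)
    return ConfusionReport(
        classes=classes or [f"class{k}" for k in range(counts.shape[0])],
        matrix=matrix,
        overall_accuracy=overall,
        class_sizes=list(class_sizes),
    )


def monte_carlo_classification(
    protocol: ClassificationProtocol, features: CohortFeatures
) -> ConfusionReport:
    """Average confusion over ``protocol.n_trials`` fresh subject-level half splits."""
    rng = np.random.default_rng(protocol.seed)
    classes = sorted(np.unique(features.meta["group"]))
    sg = features.subject_group()
    class_sizes = [int((sg == c).sum()) for c in classes]

    columns: list[int] | None = None
    if protocol.feature_mode == "wilks_top20_whole":
        pairs = select_top(features, n_select=protocol.stability_top_k)
        columns = [features.pair_index.index(p) for p in pairs]

    per_trial_rates = []
    per_trial_counts = []
    seeds = []
    for _ in range(protocol.n_trials):
        trial_seed = int(rng.integers(0, 2**31 - 1))
        seeds.append(trial_seed)
        train, test = split_half(features, balance=protocol.balance_classes, seed=trial_seed)
        pred = fit_predict(protocol, train, test, columns=columns, seed=trial_seed)
        counts = _confusion_counts(test.meta["group"].to_numpy(), pred, classes)
        per_trial_counts.append(counts)
        row = counts.sum(axis=1, keepdims=True)
        per_trial_rates.append(100.0 * counts / np.where(row == 0, 1, row))
    matrix = np.mean(per_trial_rates, axis=0)
    overall = weighted_overall(np.diag(matrix), class_sizes)
    return ConfusionReport(
        classes=classes,
        matrix=matrix,
        overall_accuracy=overall,
        class_sizes=class_sizes,
        per_trial_counts=per_trial_counts,
        trial_seeds=seeds,
    )
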