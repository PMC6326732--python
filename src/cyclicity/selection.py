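"""Wilks'-lambda discriminability ranking and Monte Carlo stability selection.

For a single feature and two groups, Wilks' lambda is the within-group to
total sum-of-squares ratio Λ = SSW/SST ∈ (0, 1]; small Λ marks a feature
whose group means are well separated relative to its spread.  Ranking all
channel-pair features by Λ picks the pairs that most help discriminate the
groups.  Because a ranking computed on one sample can be idiosyncratic,
stability selection reranks on many random half-subsets (drawn at the
subject level, stratified by group) and counts how often each pair lands
in the top k.

Caveat: selecting features on the *whole* dataset and then classifying on
half-splits of that same data constitutes inherent double dipping; that
mode is provided for comparison only and emits a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import DataError
from .features import CohortFeatures

__all__ = [
    "WilksRanking",
    "wilks_lambda",
    "wilks_lambda_columns",
    "rank_pairs",
    "monte_carlo_stability",
    "select_stable",
    "DoubleDippingWarning",
]


class DoubleDippingWarning(UserWarning):
    """Feature selection used the same data that will later be classified."""


def wilks_lambda(feature: np.ndarray, labels: np.ndarray) -> float:
    """Univariate two-group Wilks' lambda, Λ = SSW/SST.

    Equivalent to ranking by the one-way F statistic through the monotone
    map F = (N-2)(1-Λ)/Λ.
    """
    lam = wilks_lambda_columns(np.asarray(feature, float).reshape(-1, 1), labels)
    return float(lam[0])


def wilks_lambda_columns(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized Λ for every column of a runs x features matrix."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise DataError("Wilks' lambda requires exactly two groups")
    masks = [labels == g for g in groups]
    if any(m.sum() == 0 for m in masks):
        raise DataError("both groups must be nonempty")
    grand = X.mean(axis=0)
    sst = ((X - grand) ** 2).sum(axis=0)
    ssw = np.zeros_like(sst)
    for m in masks:
        ssw += ((X[m] - X[m].mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = ssw / sst
    if np.any(sst == 0):
        raise DataError("constant feature: Wilks' lambda undefined")
    return lam


@dataclass
class WilksRanking:
    pair_index: list[tuple[str, str]]
    lambda_values: np.ndarray
    ranks: np.ndarray  # permutation: ranks[r] = pair position of rank r
    stability_counts: np.ndarray | None = None
    n_trials: int = 0
    trial_seeds: list[int] = field(default_factory=list)


def rank_pairs(features: CohortFeatures, labels: np.ndarray | None = None) -> WilksRanking:
    """Rank channel pairs by ascending Λ (most discriminating first).

    Ties broken by pair position (lexicographic pair order), so the ranking
    is deterministic.
    """
    if labels is None:
        labels = features.meta["group"].to_numpy()
    lam = wilks_lambda_columns(features.X, labels)
    order = np.lexsort((np.arange(len(lam)), lam))
    return WilksRanking(features.pair_index, lam, order)


def _half_subset(features: CohortFeatures, rng: np.random.Generator) -> np.ndarray:
    """Row mask for a random half of subjects, stratified by group."""
    sg = features.subject_group()
    chosen: list[str] = []
    for g in np.unique(sg.to_numpy()):
        subs = sorted(sg[sg == g].index)
        n_half = max(1, len(subs) // 2)
        chosen.extend(rng.choice(subs, size=n_half, replace=False))
    return features.meta["subject"].isin(chosen).to_numpy()


def monte_carlo_stability(
    features: CohortFeatures,
    n_trials: int = 1000,
    top_k: int = 20,
    seed: int = 0,
) -> WilksRanking:
    """Count how often each pair ranks in the top-k over random half-subsets.

    Each trial draws half of each group's subjects (all their runs),
    reranks by Λ on that half, and increments the counts of the top-k
    pairs.  Degenerate trials (a constant feature in the half) are skipped
    and logged in the seed list as -1.
    """
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(features.pair_index), dtype=int)
    seeds: list[int] = []
    done = 0
    while done < n_trials:
        trial_seed = int(rng.integers(0, 2**31 - 1))
        trng = np.random.default_rng(trial_seed)
        mask = _half_subset(features, trng)
        sub = CohortFeatures(
            features.meta[mask].reset_index(drop=True),
            features.X[mask],
            features.pair_index,
        )
        try:
            ranking = rank_pairs(sub)
        except DataError:
            seeds.append(-1)
            done += 1
            continue
        counts[ranking.ranks[:top_k]] += 1
        seeds.append(trial_seed)
        done += 1
    full = rank_pairs(features)
    full.stability_counts = counts
    full.n_trials = n_trials
    full.trial_seeds = seeds
    return full


def select_stable(ranking: WilksRanking, n_select: int = 10) -> list[tuple[str, str]]:
    """The n pairs with the highest stability counts (ties → lower full-data Λ)."""
    if ranking.stability_counts is None:
        raise DataError("ranking carries no stability counts")
    order = np.lexsort((ranking.lambda_values, -ranking.stability_counts))
    return [ranking.pair_index[i] for i in order[:n_select]]


def select_top(features: CohortFeatures, n_select: int = 20, *, warn_double_dipping: bool = True) -> list[tuple[str, str]]:
    """Top-n pairs by whole-data Λ.

    If the same data will be split for classification afterwards, this is
    double dipping; a warning is emitted unless suppressed.
    """
    if warn_double_dipping:
        warnings.warn(
            "whole-data Wilks selection before split-half classification "
            "constitutes inherent double dipping",
            DoubleDippingWarning,
            stacklevel=2,
        )
    ranking = rank_pairs(features)
    return [ranking.pair_index[i] for i in ranking.ranks[:n_select]]


__all__.append("select_top")
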