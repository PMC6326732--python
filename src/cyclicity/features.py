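"""Lead-matrix features: vectorization, strength rankings, ROI removal, group PCA.

The strict upper triangle of an m-channel lead matrix is the canonical
feature vector (length m(m-1)/2; 528 for 33 channels).  Antisymmetry makes
the vectorization invertible, so principal-component loadings over feature
vectors can always be rendered back as a matrix over channel pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core import DataError, LeadMatrix, SpectralSummary, TimeCourse

__all__ = [
    "FeatureVector",
    "GroupPCAResult",
    "CohortFeatures",
    "vectorize",
    "devectorize",
    "pair_index_for",
    "strength_ranking",
    "drop_channels",
    "group_pca",
    "loading_to_matrix",
    "cohort_features",
]


def pair_index_for(labels: list[str]) -> list[tuple[str, str]]:
    """Row-major strict-upper-triangle pair order for the given channel labels."""
    m = len(labels)
    return [(labels[i], labels[j]) for i in range(m) for j in range(i + 1, m)]


@dataclass
class FeatureVector:
    """Upper-triangle values of a lead matrix plus their (i, j) pair labels."""

    values: np.ndarray
    pair_index: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.pair_index),):
            raise DataError("feature length must match pair index")


def vectorize(lm: LeadMatrix) -> FeatureVector:
    """Strict upper triangle in row-major pair order."""
    iu = np.triu_indices(lm.n_channels, k=1)
    return FeatureVector(lm.values[iu], pair_index_for(lm.channel_labels))


def devectorize(fv: FeatureVector, channel_labels: list[str]) -> LeadMatrix:
    """Rebuild the antisymmetric matrix from its upper triangle."""
    m = len(channel_labels)
    if len(fv.values) != m * (m - 1) // 2:
        raise DataError("feature length inconsistent with channel count")
    a = np.zeros((m, m))
    iu = np.triu_indices(m, k=1)
    a[iu] = fv.values
    a -= a.T
    return LeadMatrix(a, list(channel_labels))


def drop_channels(tc: TimeCourse, labels: list[str]) -> TimeCourse:
    """Remove channels from the time course before any lead-matrix computation.

    Removing channels from the raw signal (rather than deleting rows and
    columns of an existing lead matrix) keeps downstream spectral features
    consistent with a genuinely smaller system.
    """
    missing = [lab for lab in labels if lab not in tc.channel_labels]
    if missing:
        raise KeyError(f"unknown channel labels: {missing}")
    keep = [k for k, lab in enumerate(tc.channel_labels) if lab not in set(labels)]
    return TimeCourse(
        tc.values[keep], [tc.channel_labels[k] for k in keep], tc.sample_spacing
    )


def strength_ranking(
    summaries_by_group: dict[str, list[SpectralSummary]], top_n: int = 10
) -> pd.DataFrame:
    """Per-group proportion of records in which each channel ranks in the top-n strengths.

    Ties in strength are broken by label order (earlier label wins), so the
    ranking is deterministic.
    """
    out: dict[str, np.ndarray] = {}
    labels: list[str] | None = None
    for group, summaries in summaries_by_group.items():
        if not summaries:
            raise DataError(f"group {group!r} has no records")
        if labels is None:
            labels = list(summaries[0].channel_labels)
        counts = np.zeros(len(labels))
        for ss in summaries:
            if not ss.defined:
                raise DataError("strength ranking requires defined strengths")
            # stable sort on negated strengths = descending with label-order ties
            order = np.argsort(-ss.leading_strengths, kind="stable")
            counts[order[:top_n]] += 1
        out[group] = counts / len(summaries)
    return pd.DataFrame(out, index=labels)


@dataclass
class GroupPCAResult:
    """Orthonormal loading directions and covariance eigenvalues for one group."""

    loading_vectors: np.ndarray  # components x features, unit rows
    eigenvalues: np.ndarray  # descending variances
    eigenvalue_ratios: dict[str, float] = field(default_factory=dict)


def group_pca(features: list[FeatureVector] | np.ndarray, n_components: int | None = None) -> GroupPCAResult:
    """PCA of the centered feature covariance for one group of runs.

    Loadings are unit-norm with a deterministic sign convention (largest-
    magnitude coefficient positive).  Reports the spectral ratios λ1/λ2 and
    λ1/λ3 that quantify how dominant the first direction is.
    """
    if isinstance(features, list):
        x = np.vstack([fv.values for fv in features])
    else:
        x = np.asarray(features, dtype=float)
    if x.shape[0] < 2:
        raise DataError("group PCA needs at least 2 samples")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(x)
    load = pca.components_.copy()
    for row in load:
        k = int(np.argmax(np.abs(row)))
        if row[k] < 0:
            row *= -1
    ev = pca.explained_variance_.copy()
    ev[ev < 1e-12 * max(ev[0], 1e-300)] = 0.0  # numerically-zero variance
    ratios = {}
    for name, j in (("l1/l2", 1), ("l1/l3", 2)):
        if len(ev) > j and ev[j] > 0:
            ratios[name] = float(ev[0] / ev[j])
        else:
            ratios[name] = np.inf
    return GroupPCAResult(load, ev, ratios)


def loading_to_matrix(
    loading: np.ndarray, pair_index: list[tuple[str, str]]
) -> LeadMatrix:
    """Render a loading vector over channel pairs as an antisymmetric display matrix."""
    loading = np.asarray(loading, dtype=float)
    if loading.shape != (len(pair_index),):
        raise DataError("loading length must match pair index")
    labels: list[str] = []
    for i, j in pair_index:
        for lab in (i, j):
            if lab not in labels:
                labels.append(lab)
    return devectorize(FeatureVector(loading, pair_index), labels)


@dataclass
class CohortFeatures:
    """Per-run feature vectors keyed by subject/group/session/run.

    ``meta`` rows align with rows of ``X`` (runs x pairs).
    """

    meta: pd.DataFrame  # columns: subject, group, session, run
    X: np.ndarray
    pair_index: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if len(self.meta) != self.X.shape[0]:
            raise DataError("meta rows must align with feature rows")
        if self.X.shape[1] != len(self.pair_index):
            raise DataError("feature columns must match pair index")

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.meta["subject"]))

    def subject_group(self) -> pd.Series:
        return self.meta.drop_duplicates("subject").set_index("subject")["group"]


def cohort_features(records, *, normalize: bool = False, drop: list[str] | None = None) -> CohortFeatures:
    """Lead-matrix feature table for a list of SubjectRecord runs."""
    from .core import lead_matrix  # local import to avoid cycle at module load

    rows, feats = [], []
    pair_index = None
    for rec in records:
        tc = rec.timecourse
        if drop:
            tc = drop_channels(tc, drop)
        fv = vectorize(lead_matrix(tc, normalize=normalize))
        if pair_index is None:
            pair_index = fv.pair_index
        rows.append(
            {"subject": rec.subject_id, "group": rec.group,
             "session": rec.session, "run": rec.run}
        )
        feats.append(fv.values)
    if pair_index is None:
        raise DataError("no records supplied")
    return CohortFeatures(pd.DataFrame(rows), np.vstack(feats), pair_index)
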