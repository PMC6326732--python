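"""Cross-session subject identification (connectome-style fingerprinting).

A 1-nearest-neighbor classifier under the cosine metric, trained on one
session's run features and tested on the other, in both directions.  High
accuracy means the lead matrix is a stable, subject-specific trait across
sessions.  Groups are pooled: the question is identity, not diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import DataError
from .features import CohortFeatures

__all__ = ["IdentificationResult", "knn_session_identification"]


@dataclass
class IdentificationResult:
    subjects: list[str]
    confusion: np.ndarray  # rows true subject, cols predicted, counts
    per_subject_correct: dict[str, int]
    runs_tested_per_subject: dict[str, int]
    overall_accuracy: float


def knn_session_identification(
    features: CohortFeatures, k: int = 1, metric: str = "cosine"
) -> IdentificationResult:
    """Identify each run's subject from the other session's runs.

    Every run in session 2 is matched against all session-1 runs and vice
    versa, so with 2 runs per session each subject can be correctly
    recognised four times.  Nearest-neighbor ties are broken by the lowest
    subject index (training rows sorted by subject, session, run).
    """
    if k != 1:
        raise NotImplementedError("only k=1 is supported")
    meta = features.meta
    sessions = sorted(meta["session"].unique())
    if len(sessions) != 2:
        raise DataError("session identification requires exactly 2 sessions")
    subjects = sorted(meta["subject"].unique())
    sub_idx = {s: i for i, s in enumerate(subjects)}
    for s in subjects:
        per_sess = meta[meta["subject"] == s]["session"].value_counts()
        if not all(per_sess.get(sess, 0) >= 1 for sess in sessions):
            raise DataError(f"subject {s!r} missing a session")
    norms = np.linalg.norm(features.X, axis=1)
    if np.any(norms == 0):
        raise DataError("zero-norm feature vector; cosine distance undefined")

    order = meta.reset_index().sort_values(["subject", "session", "run"])["index"].to_numpy()
    confusion = np.zeros((len(subjects), len(subjects)), dtype=int)
    for train_sess, test_sess in ((sessions[0], sessions[1]), (sessions[1], sessions[0])):
        train_rows = order[meta["session"].to_numpy()[order] == train_sess]
        test_rows = order[meta["session"].to_numpy()[order] == test_sess]
        d = cdist(features.X[test_rows], features.X[train_rows], metric=metric)
        nearest = np.argmin(d, axis=1)  # first minimum = lowest subject index
        for row, nn in zip(test_rows, nearest):
            true = sub_idx[meta["subject"].iloc[row]]
            pred = sub_idx[meta["subject"].iloc[train_rows[nn]]]
            confusion[true, pred] += 1
    row_sums = confusion.sum(axis=1)
    correct = {s: int(confusion[i, i]) for i, s in enumerate(subjects)}
    tested = {s: int(row_sums[i]) for i, s in enumerate(subjects)}
    return IdentificationResult(
        subjects=subjects,
        confusion=confusion,
        per_subject_correct=correct,
        runs_tested_per_subject=tested,
        overall_accuracy=float(np.trace(confusion) / confusion.sum()),
    )
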