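"""Delimited-text readers and writers for every artifact in the pipeline.

Time courses travel as CSV with one row per channel (first column the
channel label, remaining columns samples).  Lead matrices are square CSV
with the channel labels as both header row and index column.  A cohort is
a directory of per-run time-course files plus a manifest CSV
(subject_id, group, session, run, path).

The bundled region-of-interest table lists the 33 ROI spheres (name, MNI
center coordinates in mm, resting-state network label) used throughout
the worked examples.  Two entries carry coordinate anomalies from the
source table (left-hemisphere names with positive x); they are shipped
verbatim, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import LeadMatrix, TimeCourse
from .synthetic import SubjectRecord

__all__ = [
    "RoiTable",
    "trim_initial_samples",
    "read_timecourse",
    "write_timecourse",
    "read_leadmatrix",
    "write_leadmatrix",
    "read_roi_table",
    "bundled_roi_table",
    "write_cohort",
    "read_cohort",
    "write_features",
]


class ParseError(ValueError):
    """Malformed delimited-text input; message names the offending line."""


def trim_initial_samples(tc: TimeCourse, n_discard: int = 4) -> TimeCourse:
    """Drop the first samples of a run (scanner stabilization volumes).

    fMRI acquisitions discard the leading volumes collected before the
    magnetization reaches steady state; with the conventional 4 discarded
    from a 304-volume run, 300 samples remain for analysis.
    """
    if n_discard < 0 or tc.n_samples - n_discard < 2:
        raise ValueError("cannot discard that many samples")
    return TimeCourse(
        tc.values[:, n_discard:], list(tc.channel_labels), tc.sample_spacing
    )


@dataclass
class RoiTable:
    """ROI names, MNI (x, y, z) centers in mm, and network labels."""

    table: pd.DataFrame  # columns: name, x, y, z, network

    def __len__(self) -> int:
        return len(self.table)

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    def center(self, name: str) -> tuple[int, int, int]:
        row = self.table[self.table["name"] == name]
        if row.empty:
            raise KeyError(name)
        return tuple(int(v) for v in row.iloc[0][["x", "y", "z"]])

    def by_network(self, network: str) -> list[str]:
        return self.table[self.table["network"] == network]["name"].tolist()


def read_roi_table(path: str | Path) -> RoiTable:
    df = pd.read_csv(path)
    required = ["name", "x", "y", "z", "network"]
    if list(df.columns) != required:
        raise ParseError(f"ROI table must have columns {required}, got {list(df.columns)}")
    dup = df["name"][df["name"].duplicated()]
    if not dup.empty:
        line = int(dup.index[0]) + 2  # header is line 1
        raise ParseError(f"duplicate ROI name {dup.iloc[0]!r} at line {line}")
    return RoiTable(df)


def bundled_roi_table() -> RoiTable:
    """The packaged 33-region table."""
    ref = resources.files("cyclicity").joinpath("data/roi_table.csv")
    with resources.as_file(ref) as p:
        return read_roi_table(p)


def write_timecourse(tc: TimeCourse, path: str | Path) -> None:
    df = pd.DataFrame(tc.values, index=tc.channel_labels)
    df.to_csv(path, header=False)


def read_timecourse(path: str | Path) -> TimeCourse:
    try:
        df = pd.read_csv(path, header=None, index_col=0)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.to_numpy().any():
        line = int(np.argwhere(bad.to_numpy().any(axis=1))[0, 0]) + 1
        raise ParseError(f"{path}: non-numeric cell at line {line}")
    df = coerced
    labels = [str(x) for x in df.index]
    if len(set(labels)) != len(labels):
        seen = set()
        for k, lab in enumerate(labels):
            if lab in seen:
                raise ParseError(f"{path}: duplicate channel label {lab!r} at line {k + 1}")
            seen.add(lab)
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = int(np.argwhere(~np.isfinite(values))[0, 0]) + 1
        raise ParseError(f"{path}: non-numeric or non-finite cell at line {bad}")
    return TimeCourse(values, labels)


def write_leadmatrix(lm: LeadMatrix, path: str | Path) -> None:
    pd.DataFrame(lm.values, index=lm.channel_labels, columns=lm.channel_labels).to_csv(path)


def read_leadmatrix(path: str | Path) -> LeadMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: lead matrix header and index disagree")
    return LeadMatrix(df.to_numpy(dtype=float), [str(c) for c in df.columns])


def write_cohort(records: list[SubjectRecord], out_dir: str | Path) -> Path:
    """One time-course CSV per run plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.subject_id}_s{rec.session}_r{rec.run}.csv"
        write_timecourse(rec.timecourse, out / fname)
        rows.append(
            {"subject_id": rec.subject_id, "group": rec.group,
             "session": rec.session, "run": rec.run, "path": fname}
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[SubjectRecord]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    records = []
    for _, row in df.iterrows():
        tc = read_timecourse(manifest_path.parent / row["path"])
        records.append(
            SubjectRecord(str(row["subject_id"]), str(row["group"]),
                          int(row["session"]), int(row["run"]), tc)
        )
    return records


def write_features(features, path: str | Path) -> None:
    """Feature table CSV: keys then one column per pair, named 'a->b'."""
    cols = [f"{a}->{b}" for a, b in features.pair_index]
    df = pd.concat(
        [features.meta.reset_index(drop=True), pd.DataFrame(features.X, columns=cols)],
        axis=1,
    )
    df.to_csv(path, index=False)
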