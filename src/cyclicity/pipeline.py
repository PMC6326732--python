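"""End-to-end pipeline: simulate -> lead matrices -> spectra -> analyses.

A :class:`PipelineConfig` fixes every stage parameter (and every seed), so
two runs with the same config produce byte-identical output tables.  The
stages mirror the analysis flow: generate or load a cohort, compute
per-run lead matrices and spectral summaries, then branch into stability
fingerprinting, Wilks selection, group classification, and leader-follower
graph construction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassificationProtocol, monte_carlo_classification
from .core import lead_matrix, spectral_decomposition
from .features import cohort_features, strength_ranking
from .graphs import consistency_graph, flipped_edges
from .io import write_cohort, write_features, write_leadmatrix
from .selection import monte_carlo_stability, select_stable
from .stability import knn_session_identification
from .synthetic import CohortSpec, gen_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "leadmatrix", "spectra", "stability", "select", "classify", "graph")


@dataclass
class PipelineConfig:
    """Every stage parameter of the pipeline, with explicit seeds."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    stages: tuple[str, ...] = ALL_STAGES
    normalize: bool = False
    drop_channels: list[str] = field(default_factory=list)
    selection_trials: int = 1000
    selection_top_k: int = 20
    selection_n_stable: int = 10
    selection_seed: int = 1
    protocol: ClassificationProtocol = field(default_factory=ClassificationProtocol)
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortSpec(**raw.pop("cohort", {}))
        protocol = ClassificationProtocol(**raw.pop("protocol", {}))
        return cls(cohort=cohort, protocol=protocol, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _provenance(config: PipelineConfig) -> dict:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return {
        "version": __version__,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "config": config.to_dict(),
    }


def run_pipeline(config: PipelineConfig, records=None) -> dict:
    """Execute the configured stages; returns a results bundle.

    ``records`` may supply a pre-loaded cohort, otherwise the simulate
    stage must be enabled.  All outputs are also written under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"provenance": _provenance(config)}
    stages = set(config.stages)

    if records is None:
        if "simulate" not in stages:
            raise ValueError("no cohort supplied and simulate stage disabled")
        log.info("simulate: generating cohort (seed=%d)", config.cohort.seed)
        records = gen_cohort(config.cohort)
        write_cohort(records, out / "cohort")
    results["n_records"] = len(records)

    features = None
    if stages & {"leadmatrix", "spectra", "stability", "select", "classify", "graph"}:
        log.info("leadmatrix: %d runs", len(records))
        features = cohort_features(
            records, normalize=config.normalize, drop=config.drop_channels or None
        )
        write_features(features, out / "features.csv")
        results["feature_dim"] = features.X.shape[1]
        if "leadmatrix" in stages:
            rec0 = records[0]
            write_leadmatrix(
                lead_matrix(rec0.timecourse, normalize=config.normalize),
                out / "leadmatrix_example.csv",
            )

    if "spectra" in stages:
        by_group: dict[str, list] = {}
        for rec in records:
            ss = spectral_decomposition(lead_matrix(rec.timecourse, normalize=config.normalize))
            by_group.setdefault(rec.group, []).append(ss)
        ranking = strength_ranking(by_group)
        ranking.to_csv(out / "strength_ranking.csv")
        results["strength_ranking"] = ranking

    if "stability" in stages:
        ident = knn_session_identification(features)
        results["identification_accuracy"] = ident.overall_accuracy
        pd.DataFrame(
            ident.confusion, index=ident.subjects, columns=ident.subjects
        ).to_csv(out / "identification_confusion.csv")
        (out / "identification.json").write_text(
            json.dumps(
                {
                    "overall_accuracy": ident.overall_accuracy,
                    "per_subject_correct": ident.per_subject_correct,
                },
                indent=2,
            )
        )

    selected_pairs = None
    if "select" in stages:
        ranking = monte_carlo_stability(
            features,
            n_trials=config.selection_trials,
            top_k=config.selection_top_k,
            seed=config.selection_seed,
        )
        selected_pairs = select_stable(ranking, config.selection_n_stable)
        df = pd.DataFrame(
            {
                "pair": [f"{a}->{b}" for a, b in ranking.pair_index],
                "lambda": ranking.lambda_values,
                "count": ranking.stability_counts,
            }
        )
        df.to_csv(out / "wilks_ranking.csv", index=False)
        results["selected_pairs"] = selected_pairs

    if "classify" in stages:
        rep = monte_carlo_classification(config.protocol, features)
        rep.to_frame().to_csv(out / "confusion.csv")
        (out / "classification.json").write_text(
            json.dumps(
                {
                    "classes": rep.classes,
                    "matrix_percent": rep.matrix.tolist(),
                    "overall_accuracy_percent": rep.overall_accuracy,
                },
                indent=2,
            )
        )
        results["classification"] = rep

    if "graph" in stages:
        if selected_pairs is None:
            ranking = monte_carlo_stability(
                features,
                n_trials=config.selection_trials,
                top_k=config.selection_top_k,
                seed=config.selection_seed,
            )
            selected_pairs = select_stable(ranking, config.selection_n_stable)
        groups = sorted(features.meta["group"].unique())
        graphs = {}
        for g in groups:
            mask = (features.meta["group"] == g).to_numpy()
            from .features import CohortFeatures

            sub = CohortFeatures(
                features.meta[mask].reset_index(drop=True),
                features.X[mask],
                features.pair_index,
            )
            lfg = consistency_graph(sub, selected_pairs)
            graphs[g] = lfg
            pd.DataFrame(lfg.edge_table()).to_csv(out / f"graph_{g}.csv", index=False)
        if len(graphs) == 2:
            flips = flipped_edges(*[graphs[g] for g in groups])
            results["flipped_pairs"] = flips
            (out / "flipped_pairs.json").write_text(
                json.dumps([list(p) for p in flips], indent=2)
            )
        results["graphs"] = graphs

    (out / "provenance.json").write_text(
        json.dumps(results["provenance"], indent=2, default=str)
    )
    return results
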