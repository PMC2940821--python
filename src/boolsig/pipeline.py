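"""High-level workflow helpers shared by the CLI, tests and scripts."""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .data_model import Condition, ErrorModel, PerturbationDataset
from .network_reconstruction import ReconstructionResult, reconstruct
from .prediction import PredictionTask, predict_batch
from .scoring import (
    DEFAULT_R,
    ScoreReport,
    measurements_from_dataset,
    score_report,
)

__all__ = ["tasks_for", "predict_conditions", "score_against_dataset", "k_sweep"]


def tasks_for(
    proteins: Sequence[str],
    conditions: Iterable[Condition],
    timepoints: Sequence[float],
) -> list:
    """One task per (protein, condition, time), in deterministic order."""
    return [
        PredictionTask.make(p, cond.stimuli, cond.inhibitors, t)
        for p in proteins
        for cond in conditions
        for t in timepoints
    ]


def predict_conditions(
    ds: PerturbationDataset,
    result: ReconstructionResult,
    conditions: Iterable[Condition],
    timepoints: Sequence[float] | None = None,
):
    """Predict every protein at every condition and time point."""
    tasks = tasks_for(ds.proteins, conditions, timepoints or ds.timepoints)
    return predict_batch(ds, result.network, result.tables, tasks)


def score_against_dataset(
    records,
    measured: PerturbationDataset,
    model: ErrorModel,
    edge_count: int,
    r: float = DEFAULT_R,
    n_draws: int = 10000,
    seed: int = 0,
) -> ScoreReport:
    measurements = measurements_from_dataset(measured, [rec.task for rec in records])
    return score_report(
        records, measurements, model, edge_count=edge_count, r=r, n_draws=n_draws, seed=seed
    )


def k_sweep(
    ds: PerturbationDataset,
    model: ErrorModel,
    conditions: Iterable[Condition],
    measured: PerturbationDataset,
    ks: Sequence[float],
    r: float = DEFAULT_R,
    n_draws: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Reconstruct, predict and score at each ``k``.

    Returns a data frame with columns ``k``, ``n_links``, ``edge_count``,
    ``prediction_score`` and ``overall_score`` — the sensitivity profile of
    the method to the significance threshold.  Only post-baseline time
    points are scored: the basal (t = 0) level is an input the prediction
    step takes as given, not an output of the method.
    """
    conditions = list(conditions)
    post = [t for t in ds.timepoints if t > 0]
    rows = []
    for k in ks:
        result = reconstruct(ds, model, k)
        records = predict_conditions(ds, result, conditions, timepoints=post)
        report = score_against_dataset(
            records,
            measured,
            model,
            edge_count=result.network.edge_count,
            r=r,
            n_draws=n_draws,
            seed=seed,
        )
        rows.append(
            {
                "k": k,
                "n_links": len(result.network.paths),
                "edge_count": result.network.edge_count,
                "prediction_score": report.prediction_score,
                "overall_score": report.overall_score,
            }
        )
    return pd.DataFrame(rows)
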