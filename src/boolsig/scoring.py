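"""Challenge-style evaluation of predictions against measured test data.

Per prediction, the Normalized Error (NE) is the absolute deviation from
the measurement divided by the measurement-error SD at the measured level;
the per-protein Normalized Squared Error (NSE) is the mean of squared NEs.
Each protein's NSE is compared with an empirical null in which every
prediction is replaced by a draw (with replacement) from the protein's pool
of measured values; the resulting add-one-smoothed p-values are combined
into the Prediction Score, ``mean of -log10(p)``.  The Overall Score
penalizes network size: ``Prediction Score - r * edge_count``, with the
per-edge cost ``r`` defaulting to 0.0827.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data_model import ErrorModel, PerturbationDataset
from .prediction import PredictionRecord, PredictionTask

__all__ = [
    "DEFAULT_R",
    "ScoreReport",
    "normalized_error",
    "protein_nse",
    "null_pvalue",
    "prediction_score",
    "overall_score",
    "score_report",
    "measurements_from_dataset",
    "write_report",
    "write_ne_csv",
]

DEFAULT_R = 0.0827


def normalized_error(pred: float, meas: float, model: ErrorModel) -> float:
    """|pred - meas| over the measurement-error SD evaluated at the measurement."""
    if meas < 0:
        raise ValueError("measured intensity must be >= 0")
    return abs(pred - meas) / math.sqrt(model.variance(meas))


def _protein_records(records, protein):
    return [r for r in records if r.task.protein == protein]


def protein_nse(
    records: Iterable[PredictionRecord],
    measurements: Mapping[PredictionTask, float],
    model: ErrorModel,
    protein: str,
) -> float:
    """Mean squared normalized error over the protein's predictions."""
    recs = _protein_records(records, protein)
    if not recs:
        raise ValueError(f"no predictions for protein {protein!r}")
    return float(
        np.mean([normalized_error(r.predicted, measurements[r.task], model) ** 2 for r in recs])
    )


def null_pvalue(
    protein: str,
    records: Iterable[PredictionRecord],
    measurements: Mapping[PredictionTask, float],
    measured_pool: Iterable[float],
    model: ErrorModel,
    n_draws: int = 10000,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Empirical p-value of the protein's NSE against a resampling null.

    Each null replicate replaces every prediction slot independently with a
    uniform draw (with replacement) from the protein's measured-value pool
    and recomputes the NSE; the add-one-smoothed p-value is
    ``(1 + #{null NSE <= observed}) / (n_draws + 1)``, so it is always
    strictly positive.  Seeded and reproducible.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    pool = list(measured_pool)
    if not pool:
        raise ValueError(f"empty measured pool for protein {protein!r}")
    recs = _protein_records(records, protein)
    observed = protein_nse(recs, measurements, model, protein)
    meas_list = [measurements[r.task] for r in recs]
    return _null_pvalue_impl(observed, meas_list, pool, model, n_draws, seed)


def prediction_score(p_values: Iterable[float]) -> float:
    """Combine per-protein p-values: mean of ``-log10(p)`` (larger is better)."""
    ps = list(p_values)
    if not ps:
        raise ValueError("no p-values to combine")
    if any(p <= 0 or p > 1 for p in ps):
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.mean([-math.log10(p) for p in ps]))


def overall_score(pred_score: float, edge_count: int, r: float = DEFAULT_R) -> float:
    """Edge-penalized score: ``prediction_score - r * edge_count``."""
    if edge_count < 0:
        raise ValueError("edge_count must be >= 0")
    if r < 0:
        raise ValueError("r must be >= 0")
    return pred_score - r * edge_count


@dataclass
class ScoreReport:
    """Full evaluation summary."""

    nse: dict
    p_values: dict
    per_prediction_ne: list  # (task, NE) pairs in record order
    mean_ne: float
    median_ne: float
    prediction_score: float
    overall_score: float
    r: float
    edge_count: int
    n_draws: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "nse": dict(self.nse),
            "p_values": dict(self.p_values),
            "mean_ne": self.mean_ne,
            "median_ne": self.median_ne,
            "prediction_score": self.prediction_score,
            "overall_score": self.overall_score,
            "r": self.r,
            "edge_count": self.edge_count,
            "n_draws": self.n_draws,
            "seed": self.seed,
        }


def measurements_from_dataset(
    ds: PerturbationDataset, tasks: Iterable[PredictionTask]
) -> dict:
    """Look up measured values for each task in a (test) dataset."""
    return {task: ds.value(task.protein, task.condition, task.time) for task in tasks}


def score_report(
    records: Iterable[PredictionRecord],
    measurements: Mapping[PredictionTask, float],
    model: ErrorModel,
    edge_count: int = 0,
    r: float = DEFAULT_R,
    n_draws: int = 10000,
    seed: int = 0,
) -> ScoreReport:
    """Assemble NSE, p-values, NE summaries and both scores (seed-deterministic).

    Per-protein null resampling streams are spawned from ``seed`` in sorted
    protein order, so the report does not depend on record ordering.
    """
    records = list(records)
    if not records:
        raise ValueError("no predictions to score")
    proteins = sorted({r.task.protein for r in records})
    nes = [
        (r.task, normalized_error(r.predicted, measurements[r.task], model))
        for r in records
    ]
    ne_values = np.array([ne for _, ne in nes])
    nse = {p: protein_nse(records, measurements, model, p) for p in proteins}

    children = np.random.SeedSequence(seed).spawn(len(proteins))
    p_values = {}
    for child, protein in zip(children, proteins):
        recs = _protein_records(records, protein)
        pool = [measurements[r.task] for r in recs]
        p_values[protein] = _null_pvalue_impl(
            nse[protein], [measurements[r.task] for r in recs], pool, model, n_draws, child
        )
    ps = prediction_score(p_values.values())
    return ScoreReport(
        nse=nse,
        p_values=p_values,
        per_prediction_ne=nes,
        mean_ne=float(ne_values.mean()),
        median_ne=float(np.median(ne_values)),
        prediction_score=ps,
        overall_score=overall_score(ps, edge_count, r),
        r=r,
        edge_count=edge_count,
        n_draws=n_draws,
        seed=seed,
    )


def _null_pvalue_impl(observed_nse, meas_list, pool, model, n_draws, seed) -> float:
    rng = np.random.default_rng(seed)
    pool = np.asarray(pool, dtype=float)
    meas = np.asarray(meas_list, dtype=float)
    draws = pool[rng.integers(0, pool.size, size=(n_draws, meas.size))]
    null_ne = np.abs(draws - meas) / np.sqrt(model.variance(meas))
    null_nse = (null_ne**2).mean(axis=1)
    return float((1 + int((null_nse <= observed_nse).sum())) / (n_draws + 1))


def write_report(report: ScoreReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_ne_csv(report: ScoreReport, path) -> None:
    """Flat CSV of per-prediction normalized errors."""
    rows = [
        {
            "protein": task.protein,
            "stimuli": "+".join(sorted(task.stimuli)),
            "inhibitors": "+".join(sorted(task.inhibitors)),
            "time_min": task.time,
            "ne": ne,
        }
        for task, ne in report.per_prediction_ne
    ]
    pd.DataFrame(rows, columns=["protein", "stimuli", "inhibitors", "time_min", "ne"]).to_csv(
        path, index=False, float_format="%.10g"
    )
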