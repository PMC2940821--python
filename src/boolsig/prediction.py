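"""Linear superposition prediction of multi-stimulus/multi-inhibitor levels.

A protein's level under a combination of stimuli ``I`` and inhibitors ``J``
is predicted from single-perturbation training data alone.  For every
stimulus the protein's Boolean table marks active (``s = 1``), the increment
measured in the matching single-perturbation condition is added to a
reference level: if an inhibitor in ``J`` mediates the stimulus' path, the
stimulus+inhibitor condition is used (so the blocked effect is absent from
the data being combined); otherwise the stimulus-alone condition is used.
Each increment is taken relative to the corresponding no-stimulus condition
so inhibitor baselines are not double counted — for the canonical example
of a protein reached by two stimuli through one inhibited node this reduces
to ``X(i1, j) + X(i2, j) - X(0, j)``.

If no stimulus in ``I`` is active the prediction is the reference level
itself.  References average in the training measurements of conditions the
network deems inert for the protein, which are extra replicates of the
unperturbed level.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Iterable, Mapping

import pandas as pd

from .boolean_inference import BooleanTable
from .data_model import Condition, PerturbationDataset, parse_treatment_field
from .errors import MissingConditionError
from .network_reconstruction import ROLE_INHIBITED, SignalingNetwork

__all__ = [
    "PredictionTask",
    "PredictionRecord",
    "isolate_subnetwork",
    "active_stimuli_and_mediators",
    "reference_level",
    "predict_condition",
    "predict_batch",
    "write_predictions",
    "read_predictions",
]


@dataclass(frozen=True)
class PredictionTask:
    """One quantity to predict: a protein under (stimuli, inhibitors) at time t."""

    protein: str
    stimuli: frozenset
    inhibitors: frozenset
    time: float

    @classmethod
    def make(cls, protein, stimuli=(), inhibitors=(), time=0.0) -> "PredictionTask":
        return cls(protein, frozenset(stimuli), frozenset(inhibitors), float(time))

    @property
    def condition(self) -> Condition:
        return Condition(self.stimuli, self.inhibitors)

    def sort_key(self):
        return (self.protein, *self.condition.sort_key(), self.time)


@dataclass
class PredictionRecord:
    """A prediction plus the bookkeeping of how it was assembled."""

    task: PredictionTask
    predicted: float
    active_stimuli: frozenset = frozenset()
    mediator_assignment: dict = None
    reference_used: float = 0.0


def isolate_subnetwork(net: SignalingNetwork, protein: str, I: Iterable[str], J: Iterable[str],
                       inhibitor_targets: Mapping[str, str] | None = None):
    """Nodes and edges of the network relevant to predicting ``protein`` under (I, J).

    Keeps the protein, the requested stimuli with a 1- or 2-step route to
    it, and the inhibited nodes of requested inhibitors that sit on those
    routes; everything else (e.g. an inhibited node with no edge into the
    protein) is dropped.
    """
    if protein not in net.graph:
        raise KeyError(f"protein {protein!r} not in network")
    from .data_model import default_inhibitor_target

    targets = dict(inhibitor_targets or {})
    I, J = set(I), set(J)
    q_candidates = {
        targets.get(j, default_inhibitor_target(j)) for j in J
    }
    q_linked = {
        q
        for q in q_candidates
        if net.graph.has_node(q)
        and ROLE_INHIBITED in net.roles(q)
        and net.graph.has_edge(q, protein)
    }
    stimuli = set()
    for i in I:
        if not net.graph.has_node(i):
            continue
        if net.graph.has_edge(i, protein):
            stimuli.add(i)
        elif any(
            net.graph.has_edge(i, q) and net.graph.has_edge(q, protein)
            for q in net.graph.successors(i)
            if ROLE_INHIBITED in net.roles(q)
        ):
            stimuli.add(i)
    if I:
        q_linked = {q for q in q_linked if any(net.graph.has_edge(i, q) for i in stimuli)}
    nodes = {protein} | stimuli | q_linked
    edges = {
        (u, v)
        for (u, v) in net.edges
        if u in nodes and v in nodes
    }
    return nodes, edges


def active_stimuli_and_mediators(
    tables: Mapping[str, BooleanTable],
    net: SignalingNetwork,
    protein: str,
    I: Iterable[str],
    J: Iterable[str],
):
    """Stimuli in ``I`` acting on the protein, and their mediating inhibitors in ``J``.

    Returns ``(A, mediators)`` where ``A`` is the sorted tuple of active
    stimuli and ``mediators[i]`` is the sorted tuple of inhibitors in ``J``
    that mediate stimulus ``i`` (empty when the stimulus-alone data must be
    used).
    """
    table = tables[protein]
    J = set(J)
    A = tuple(sorted(i for i in I if table.s(i) == 1))
    mediators = {i: tuple(sorted(table.mediating_inhibitors(i) & J)) for i in A}
    return A, mediators


def _linked_inhibitors(table: BooleanTable, J: Iterable[str]) -> list:
    """Inhibitors in J with an edge into the protein according to its table."""
    recorded = set().union(*table.mediators_for_prediction.values()) if table.mediators_for_prediction else set()
    linked = [
        j
        for j in sorted(J)
        if j in recorded or any(table.v(i, j) == 1 for i in table.stimuli)
    ]
    return linked


def reference_level(
    ds: PerturbationDataset,
    tables: Mapping[str, BooleanTable],
    protein: str,
    J: Iterable[str],
    t: float,
) -> float:
    """Reference (no-active-stimulus) level of the protein under inhibitors ``J``.

    The base is the mean of ``X(t|0,j)`` over the inhibitors in ``J`` linked
    to the protein, or ``X(t|0,0)`` when none is.  Training conditions the
    network deems inert for the protein — those whose stimulus has
    ``s = 0`` — are averaged in as extra replicates of the same level.
    """
    table = tables[protein]
    linked = _linked_inhibitors(table, J)
    inert = [i for i in table.stimuli if table.s(i) == 0]
    base_conditions = (
        [Condition.single(inhibitor=j) for j in linked]
        if linked
        else [Condition.reference()]
    )
    levels = []
    for base in base_conditions:
        pool = [ds.value(protein, base, t)]
        for i in inert:
            cond = Condition.make([i], base.inhibitors)
            if ds.has(protein, cond, t):
                pool.append(ds.value(protein, cond, t))
        levels.append(fmean(pool))
    return fmean(levels)


def predict_condition(
    ds: PerturbationDataset,
    net: SignalingNetwork,
    tables: Mapping[str, BooleanTable],
    task: PredictionTask,
) -> PredictionRecord:
    """Predict one protein level by linear combination of training data."""
    protein = task.protein
    if protein not in tables:
        raise KeyError(f"no Boolean table for protein {protein!r}")
    A, mediators = active_stimuli_and_mediators(tables, net, protein, task.stimuli, task.inhibitors)
    ref = reference_level(ds, tables, protein, task.inhibitors, task.time)
    total = ref
    for i in A:
        meds = mediators[i]
        if meds:
            contribs = []
            for j in meds:
                x_ij = ds.value(protein, Condition.make([i], [j]), task.time)
                x_0j = ds.value(protein, Condition.single(inhibitor=j), task.time)
                contribs.append(x_ij - x_0j)
            total += fmean(contribs)
        else:
            x_i0 = ds.value(protein, Condition.single(stimulus=i), task.time)
            x_00 = ds.value(protein, Condition.reference(), task.time)
            total += x_i0 - x_00
    return PredictionRecord(
        task=task,
        predicted=max(total, 0.0),
        active_stimuli=frozenset(A),
        mediator_assignment=mediators,
        reference_used=ref,
    )


def predict_batch(
    ds: PerturbationDataset,
    net: SignalingNetwork,
    tables: Mapping[str, BooleanTable],
    tasks: Iterable[PredictionTask],
) -> list:
    """Predict every task, preserving input order; errors name the failing task."""
    records = []
    for idx, task in enumerate(tasks):
        try:
            records.append(predict_condition(ds, net, tables, task))
        except MissingConditionError as exc:
            raise MissingConditionError(f"task #{idx} ({task!r}): {exc}") from exc
    return records


def write_predictions(records: Iterable[PredictionRecord], path) -> None:
    """Write predictions as CSV, ordered by (protein, condition, time)."""
    rows = [
        {
            "protein": r.task.protein,
            "stimuli": "+".join(sorted(r.task.stimuli)),
            "inhibitors": "+".join(sorted(r.task.inhibitors)),
            "time_min": r.task.time,
            "predicted_value": r.predicted,
        }
        for r in sorted(records, key=lambda r: r.task.sort_key())
    ]
    pd.DataFrame(
        rows, columns=["protein", "stimuli", "inhibitors", "time_min", "predicted_value"]
    ).to_csv(path, index=False, float_format="%.10g")


def read_predictions(path) -> list:
    """Read a predictions CSV back into minimal :class:`PredictionRecord` objects."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        task = PredictionTask.make(
            row["protein"],
            parse_treatment_field(row["stimuli"]),
            parse_treatment_field(row["inhibitors"]),
            float(row["time_min"]),
        )
        records.append(PredictionRecord(task=task, predicted=float(row["predicted_value"])))
    return records
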