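"""Per-protein Boolean tables of significant stimulus/inhibitor actions.

For each measured protein a table with one column per stimulus and one row
per inhibitor is filled with two-value cells ``[s, v]``:

* ``s = 1`` iff the stimulus alone raises the protein significantly above
  the unperturbed reference at some post-baseline time point — the increase
  must exceed ``k`` times the standard deviation of the measurement error
  of the difference;
* ``v = 1`` iff, given ``s = 1``, adding the inhibitor lowers the protein
  significantly below the stimulus-alone course at some post-baseline time
  point, by the same ``k``-threshold rule.

Only increases count for stimuli and only decreases for inhibitors; the
``t = 0`` sample is excluded because no stimulus can act at time zero.
Both tests have an exact analytic flip point in ``k`` — the maximum over
post-baseline times of the difference divided by its error SD — exposed by
the ``*_k_threshold`` operations and used to rank network links.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

from .data_model import Condition, ErrorModel, PerturbationDataset, delta_with_variance
from .errors import ContractError

__all__ = [
    "InferenceParams",
    "BooleanTable",
    "stimulus_significant",
    "inhibitor_significant",
    "build_table",
    "stimulus_k_threshold",
    "inhibitor_k_threshold",
    "all_k_thresholds",
    "write_tables",
    "write_thresholds",
]

DEFAULT_K = 2.5


@dataclass(frozen=True)
class InferenceParams:
    """Significance multiplier ``k`` on the measurement-error SD (default 2.5)."""

    k: float = DEFAULT_K

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("k must be > 0")


@dataclass
class BooleanTable:
    """Stimulus x inhibitor classification of significant actions on one protein.

    ``cells[(stimulus, inhibitor)] = (s, v)``.  ``s`` depends only on the
    stimulus, so it is constant down a column, and ``s = 0`` forces
    ``v = 0`` for the whole column.  ``mediators_for_prediction`` records,
    per stimulus, extra inhibitors that must be treated as mediating the
    stimulus' action after network-level pruning replaced a direct link by
    a two-step route.
    """

    protein: str
    stimuli: tuple
    inhibitors: tuple
    cells: dict
    inhibitor_targets: dict = field(default_factory=dict)
    mediators_for_prediction: dict = field(default_factory=dict)

    def s(self, stimulus: str) -> int:
        if not self.inhibitors:
            return self.cells[(stimulus, None)][0]
        return self.cells[(stimulus, self.inhibitors[0])][0]

    def v(self, stimulus: str, inhibitor: str) -> int:
        return self.cells[(stimulus, inhibitor)][1]

    def target_of(self, inhibitor: str) -> str:
        from .data_model import default_inhibitor_target

        return self.inhibitor_targets.get(inhibitor, default_inhibitor_target(inhibitor))

    def mediating_inhibitors(self, stimulus: str) -> set:
        """Inhibitors whose action mediates this stimulus (v = 1 or recorded by pruning)."""
        meds = {j for j in self.inhibitors if self.v(stimulus, j) == 1}
        meds |= set(self.mediators_for_prediction.get(stimulus, ()))
        return meds

    def validate(self) -> None:
        for stimulus in self.stimuli:
            col = [self.cells[(stimulus, j)] for j in self.inhibitors] or [
                self.cells[(stimulus, None)]
            ]
            s_values = {s for s, _ in col}
            if len(s_values) != 1:
                raise ValueError(f"s not constant down column {stimulus!r}")
            if s_values == {0} and any(v for _, v in col):
                raise ValueError(f"s=0 column {stimulus!r} has v=1 cells")


def _post_baseline(ds: PerturbationDataset):
    return [t for t in ds.timepoints if t > 0]


def stimulus_significant(
    ds: PerturbationDataset,
    model: ErrorModel,
    protein: str,
    stimulus: str,
    k: float,
) -> int:
    """1 iff the stimulus alone significantly raises the protein at some t > 0.

    The increase over the unperturbed reference must strictly exceed
    ``k * sd`` of the difference; the test is one-sided (increase only).
    """
    if not k > 0:
        raise ValueError("k must be > 0")
    cond = Condition.single(stimulus=stimulus)
    ref = Condition.reference()
    for t in _post_baseline(ds):
        delta, var = delta_with_variance(ds, model, protein, cond, ref, t)
        if delta > k * math.sqrt(var):
            return 1
    return 0


def inhibitor_significant(
    ds: PerturbationDataset,
    model: ErrorModel,
    protein: str,
    stimulus: str,
    inhibitor: str,
    k: float,
) -> int:
    """1 iff, under the stimulus, the inhibitor significantly lowers the protein.

    The reference is the stimulus-alone course; the decrease must strictly
    exceed ``k * sd`` of the difference at some t > 0.  Calling this when
    the stimulus itself is not significant is a contract violation: the
    inhibitor's effect is not considered in that case and ``v`` is 0.
    """
    if stimulus_significant(ds, model, protein, stimulus, k) == 0:
        raise ContractError(
            f"inhibitor_significant({protein!r}, {stimulus!r}, {inhibitor!r}): "
            "stimulus is not significant, inhibitor effects are not considered"
        )
    stim_alone = Condition.single(stimulus=stimulus)
    both = Condition.make([stimulus], [inhibitor])
    for t in _post_baseline(ds):
        delta, var = delta_with_variance(ds, model, protein, stim_alone, both, t)
        if delta > k * math.sqrt(var):
            return 1
    return 0


def build_table(
    ds: PerturbationDataset,
    model: ErrorModel,
    protein: str,
    k: float,
) -> BooleanTable:
    """Fill the protein's Boolean table from single-perturbation data."""
    cells = {}
    for stimulus in ds.stimuli:
        s = stimulus_significant(ds, model, protein, stimulus, k)
        if ds.inhibitors:
            for inhibitor in ds.inhibitors:
                v = (
                    inhibitor_significant(ds, model, protein, stimulus, inhibitor, k)
                    if s
                    else 0
                )
                cells[(stimulus, inhibitor)] = (s, v)
        else:
            cells[(stimulus, None)] = (s, 0)
    table = BooleanTable(
        protein=protein,
        stimuli=ds.stimuli,
        inhibitors=ds.inhibitors,
        cells=cells,
        inhibitor_targets=dict(ds.inhibitor_targets),
    )
    table.validate()
    return table


def stimulus_k_threshold(
    ds: PerturbationDataset,
    model: ErrorModel,
    protein: str,
    stimulus: str,
) -> float:
    """Supremum of ``k`` at which the stimulus is still significant.

    ``max over t > 0 of (X(t|i,0) - X(t|0,0)) / sd_delta(t)``; significance
    at ``k`` is exactly the indicator ``k < k_max``.
    """
    cond = Condition.single(stimulus=stimulus)
    ref = Condition.reference()
    ratios = []
    for t in _post_baseline(ds):
        delta, var = delta_with_variance(ds, model, protein, cond, ref, t)
        ratios.append(delta / math.sqrt(var))
    return max(ratios)


def inhibitor_k_threshold(
    ds: PerturbationDataset,
    model: ErrorModel,
    protein: str,
    stimulus: str,
    inhibitor: str,
) -> float:
    """Supremum of ``k`` at which the inhibitor's decrease is still significant."""
    stim_alone = Condition.single(stimulus=stimulus)
    both = Condition.make([stimulus], [inhibitor])
    ratios = []
    for t in _post_baseline(ds):
        delta, var = delta_with_variance(ds, model, protein, stim_alone, both, t)
        ratios.append(delta / math.sqrt(var))
    return max(ratios)


def all_k_thresholds(ds: PerturbationDataset, model: ErrorModel) -> dict:
    """All stimulus and inhibitor flip points, keyed by protein."""
    out = {"stimulus": {}, "inhibitor": {}}
    for protein in ds.proteins:
        out["stimulus"][protein] = {
            s: stimulus_k_threshold(ds, model, protein, s) for s in ds.stimuli
        }
        out["inhibitor"][protein] = {
            s: {
                j: inhibitor_k_threshold(ds, model, protein, s, j)
                for j in ds.inhibitors
            }
            for s in ds.stimuli
        }
    return out


def write_tables(tables, outdir) -> list:
    """Write one CSV per protein: rows = inhibitors, columns = stimuli, cells ``"s,v"``."""
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for protein in sorted(tables):
        table = tables[protein]
        path = os.path.join(outdir, f"{protein}_table.csv")
        with open(path, "w") as fh:
            fh.write("inhibitor," + ",".join(table.stimuli) + "\n")
            for j in table.inhibitors:
                cells = ",".join(
                    f'"{table.cells[(s, j)][0]},{table.cells[(s, j)][1]}"'
                    for s in table.stimuli
                )
                fh.write(f"{j},{cells}\n")
        paths.append(path)
    return paths


def write_thresholds(ds: PerturbationDataset, model: ErrorModel, path) -> None:
    """Dump all analytic k-thresholds as JSON."""
    with open(path, "w") as fh:
        json.dump(all_k_thresholds(ds, model), fh, indent=2, sort_keys=True)
        fh.write("\n")
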