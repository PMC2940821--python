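"""Core types for single-perturbation phosphoprotein datasets.

The experimental design this package targets applies, per training
condition, at most one extracellular stimulus (a cytokine such as TNFa) and
at most one small-molecule kinase inhibitor (such as IKKi), then reads out
phosphoprotein intensities (sandwich-assay arbitrary units) at a small
number of time points.  Test conditions may combine up to two stimuli and
two inhibitors.  Measurements carry an intensity-dependent error described
by :class:`ErrorModel`.

Datasets travel as a MIDAS-dialect CSV (CellNOpt-compatible):

* ``TR:<name>`` treatment columns take 0/1; a trailing ``i`` in the
  treatment name marks an inhibitor (``TR:MEKi``), anything else is a
  stimulus (``TR:TNFa``);
* ``DA:ALL`` gives the row's time in minutes; per-protein ``DA:<protein>``
  columns are accepted instead but must agree within each row;
* ``DV:<protein>`` columns carry the measured intensities.

One row per (condition, time point); replicate rows for the same condition
and time are averaged on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import MidasFormatError, MissingConditionError

__all__ = [
    "ErrorModel",
    "Condition",
    "PerturbationDataset",
    "variance_of",
    "delta_with_variance",
    "read_midas",
    "write_midas",
    "default_inhibitor_target",
]


@dataclass(frozen=True)
class ErrorModel:
    """Additive technical + proportional biological measurement-error model.

    ``variance(x) = technical_sd**2 + (biological_cv * x)**2``

    Parameters
    ----------
    technical_sd : float
        Standard deviation of the intensity-independent technical noise,
        in intensity units (default 300).
    biological_cv : float
        Coefficient of variation of the proportional biological noise,
        dimensionless (default 0.08, i.e. 8%).  The CV is evaluated at the
        measured level.
    """

    technical_sd: float = 300.0
    biological_cv: float = 0.08

    def __post_init__(self) -> None:
        if self.technical_sd < 0:
            raise ValueError("technical_sd must be >= 0")
        if not 0 <= self.biological_cv < 1:
            raise ValueError("biological_cv must be in [0, 1)")

    def variance(self, x):
        """Measurement-error variance at measured intensity ``x`` (scalar or array)."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("intensity must be >= 0")
        out = self.technical_sd**2 + (self.biological_cv * x) ** 2
        return float(out) if out.ndim == 0 else out

    def sd(self, x):
        """Measurement-error standard deviation at measured intensity ``x``."""
        return np.sqrt(self.variance(x))


def variance_of(model: ErrorModel, x: float) -> float:
    """Measurement-error variance of a single intensity, in intensity**2."""
    return model.variance(x)


@dataclass(frozen=True)
class Condition:
    """A perturbation condition: a set of stimuli and a set of inhibitors.

    The reference condition (no stimulus, no inhibitor) is represented by
    two empty sets.  Training conditions carry at most one of each; test
    conditions up to two of each.
    """

    stimuli: frozenset = frozenset()
    inhibitors: frozenset = frozenset()

    @classmethod
    def make(cls, stimuli: Iterable[str] = (), inhibitors: Iterable[str] = ()) -> "Condition":
        return cls(frozenset(stimuli), frozenset(inhibitors))

    @classmethod
    def single(cls, stimulus: str | None = None, inhibitor: str | None = None) -> "Condition":
        return cls.make(
            [stimulus] if stimulus else (),
            [inhibitor] if inhibitor else (),
        )

    @classmethod
    def reference(cls) -> "Condition":
        return cls()

    @property
    def is_reference(self) -> bool:
        return not self.stimuli and not self.inhibitors

    def sort_key(self):
        return (tuple(sorted(self.stimuli)), tuple(sorted(self.inhibitors)))

    def label(self) -> str:
        """Human-readable ``stimuli/inhibitors`` label, e.g. ``"TNFa/IKKi"``."""
        stim = "+".join(sorted(self.stimuli)) or "-"
        inh = "+".join(sorted(self.inhibitors)) or "-"
        return f"{stim}/{inh}"


def parse_treatment_field(text) -> frozenset:
    """Parse a ``+``-joined treatment field (empty, ``-`` or NaN mean none)."""
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return frozenset()
    text = str(text).strip()
    if text in ("", "-"):
        return frozenset()
    return frozenset(part.strip() for part in text.split("+") if part.strip())


def default_inhibitor_target(inhibitor: str) -> str:
    """Default inhibitor -> inhibited-protein-node mapping (strip trailing ``i``)."""
    return inhibitor[:-1] if inhibitor.endswith("i") and len(inhibitor) > 1 else inhibitor


@dataclass
class PerturbationDataset:
    """All measured intensities of an experiment, indexed by (protein, condition, time).

    Attributes
    ----------
    proteins, stimuli, inhibitors : tuple of str
        Measured phosphoproteins, stimulus ids and inhibitor ids.
    timepoints : tuple of float
        Ordered measurement times in minutes; for a training set the first
        entry is 0 (the basal sample).
    values : dict
        ``(protein, Condition, time) -> intensity``.
    inhibitor_targets : dict
        Inhibitor id -> id of the protein node it blocks.  Defaults to
        stripping a trailing ``i`` (``MEKi -> MEK``); supply explicitly when
        the convention does not hold (``MEKi -> MEK12``).
    """

    proteins: tuple
    stimuli: tuple
    inhibitors: tuple
    timepoints: tuple
    values: dict
    inhibitor_targets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.proteins = tuple(self.proteins)
        self.stimuli = tuple(self.stimuli)
        self.inhibitors = tuple(self.inhibitors)
        self.timepoints = tuple(sorted(float(t) for t in self.timepoints))
        for inh in self.inhibitors:
            self.inhibitor_targets.setdefault(inh, default_inhibitor_target(inh))
        for (protein, cond, t), x in self.values.items():
            if not np.isfinite(x) or x < 0:
                raise ValueError(
                    f"intensity for {protein!r} under {cond.label()} at t={t} "
                    f"must be finite and >= 0, got {x!r}"
                )

    def target_of(self, inhibitor: str) -> str:
        return self.inhibitor_targets.get(inhibitor, default_inhibitor_target(inhibitor))

    def conditions(self) -> list:
        """All conditions present, in deterministic order."""
        seen = {cond for (_, cond, _) in self.values}
        return sorted(seen, key=Condition.sort_key)

    def value(self, protein: str, condition: Condition, t: float) -> float:
        try:
            return self.values[(protein, condition, float(t))]
        except KeyError:
            raise MissingConditionError(
                f"no measurement for protein {protein!r} under condition "
                f"{condition.label()} at t={t}"
            ) from None

    def has(self, protein: str, condition: Condition, t: float) -> bool:
        return (protein, condition, float(t)) in self.values

    def validate(self, require_reference: bool = True) -> None:
        """Check dataset invariants; raise :class:`MidasFormatError` on violation.

        With ``require_reference`` the reference condition must be present
        for every protein at every time point and t=0 must be measured
        (a training set); without it only completeness per (protein,
        condition) over the shared time grid is enforced (a test set).
        """
        if not self.proteins:
            raise MidasFormatError("dataset has no measured proteins")
        conds = self.conditions()
        if not conds:
            raise MidasFormatError("dataset has no conditions")
        if require_reference:
            if Condition.reference() not in conds:
                raise MidasFormatError(
                    "reference condition (no stimulus, no inhibitor) is missing"
                )
            if 0.0 not in self.timepoints:
                raise MidasFormatError("t=0 (basal) measurements are missing")
        for protein in self.proteins:
            for cond in conds:
                for t in self.timepoints:
                    if not self.has(protein, cond, t):
                        raise MidasFormatError(
                            f"missing value: protein {protein!r}, condition "
                            f"{cond.label()}, t={t}"
                        )


def delta_with_variance(
    ds: PerturbationDataset,
    model: ErrorModel,
    protein: str,
    cond_a: Condition,
    cond_b: Condition,
    t: float,
):
    """Difference ``X(t|a) - X(t|b)`` and its measurement-error variance.

    Errors of the two measurements are taken as independent, so variances add.
    """
    xa = ds.value(protein, cond_a, t)
    xb = ds.value(protein, cond_b, t)
    return xa - xb, model.variance(xa) + model.variance(xb)


# ---------------------------------------------------------------------------
# MIDAS-dialect I/O


def read_midas(
    path,
    inhibitor_targets: Mapping[str, str] | None = None,
    require_reference: bool = True,
) -> PerturbationDataset:
    """Read a MIDAS-dialect CSV into a :class:`PerturbationDataset`.

    Replicate rows (same condition and time) are averaged per data column.
    """
    df = pd.read_csv(path)
    tr_cols = [c for c in df.columns if c.startswith("TR:")]
    da_cols = [c for c in df.columns if c.startswith("DA:")]
    dv_cols = [c for c in df.columns if c.startswith("DV:")]
    if not tr_cols or not da_cols or not dv_cols:
        raise MidasFormatError(
            f"{path}: header must contain TR:, DA: and DV: columns "
            f"(found {list(df.columns)})"
        )
    stimuli = tuple(c[3:] for c in tr_cols if not c[3:].endswith("i"))
    inhibitors = tuple(c[3:] for c in tr_cols if c[3:].endswith("i"))
    proteins = tuple(c[3:] for c in dv_cols)

    for col in tr_cols + da_cols + dv_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            row = int((df[col].isna() | bad).idxmax())
            raise MidasFormatError(
                f"{path}: non-numeric or missing value in column {col!r}, row {row + 2}"
            )
        df[col] = numeric
    for col in tr_cols:
        if not df[col].isin([0, 1]).all():
            row = int((~df[col].isin([0, 1])).idxmax())
            raise MidasFormatError(
                f"{path}: treatment column {col!r} must be 0/1 (row {row + 2})"
            )

    if "DA:ALL" in df.columns:
        times = df["DA:ALL"]
    else:
        ref = df[da_cols[0]]
        for col in da_cols[1:]:
            if not (df[col] == ref).all():
                row = int((df[col] != ref).idxmax())
                raise MidasFormatError(
                    f"{path}: per-protein DA columns disagree in row {row + 2}"
                )
        times = ref

    accum: dict = {}
    counts: dict = {}
    for idx, row in df.iterrows():
        cond = Condition.make(
            (s for s in stimuli if row[f"TR:{s}"] == 1),
            (j for j in inhibitors if row[f"TR:{j}"] == 1),
        )
        t = float(times.loc[idx])
        for protein in proteins:
            key = (protein, cond, t)
            accum[key] = accum.get(key, 0.0) + float(row[f"DV:{protein}"])
            counts[key] = counts.get(key, 0) + 1
    values = {key: total / counts[key] for key, total in accum.items()}

    try:
        ds = PerturbationDataset(
            proteins,
            stimuli,
            inhibitors,
            sorted({t for (_, _, t) in values}),
            values,
            dict(inhibitor_targets or {}),
        )
    except ValueError as exc:
        raise MidasFormatError(f"{path}: {exc}") from exc
    try:
        ds.validate(require_reference=require_reference)
    except MidasFormatError as exc:
        raise MidasFormatError(f"{path}: {exc}") from exc
    return ds


def write_midas(ds: PerturbationDataset, path) -> None:
    """Write a dataset as a MIDAS-dialect CSV (deterministic row/column order)."""
    if not ds.proteins:
        raise MidasFormatError("cannot write a dataset with no proteins")
    header = (
        [f"TR:{s}" for s in ds.stimuli]
        + [f"TR:{j}" for j in ds.inhibitors]
        + ["DA:ALL"]
        + [f"DV:{p}" for p in ds.proteins]
    )
    rows = []
    for cond in ds.conditions():
        for t in ds.timepoints:
            row = [int(s in cond.stimuli) for s in ds.stimuli]
            row += [int(j in cond.inhibitors) for j in ds.inhibitors]
            row.append(f"{t:.10g}")
            row += [f"{ds.value(p, cond, t):.10g}" for p in ds.proteins]
            rows.append(row)
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(str(x) for x in row) + "\n")
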