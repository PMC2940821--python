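"""Ground-truth networks and simulated perturbation datasets.

The generator emulates the structure the inference method assumes: a
three-layer network (stimuli -> optionally one inhibited protein ->
measured phosphoproteins) with strictly additive stimulus effects that are
constant across post-baseline time points, and an inhibitor that removes
the whole effect of every path it mediates.  The default design mirrors a
combinatorial cytokine/kinase-inhibitor screen: 4 stimuli, 4 inhibitors,
7 measured proteins, time points 0/30/180 minutes, 25 single-perturbation
training conditions and 20 pairwise-combination test conditions, with
Gaussian measurement noise whose variance follows the additive
technical (SD 300) + proportional biological (CV 8%) error model.

Basal levels are drawn from U(800, 1500) intensity units, a mid-range
plateau for sandwich-assay readouts, and effect sizes from
``U(1.0, 1.5) * effect_scale * technical_sd`` so that ``effect_scale``
is a guaranteed lower bound in SD units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .data_model import Condition, ErrorModel, PerturbationDataset, write_midas
from .network_reconstruction import SignalingNetwork, write_sif

__all__ = [
    "GroundTruth",
    "sample_ground_truth",
    "simulate_dataset",
    "simulate_test_truth",
    "dream4_test_conditions",
    "make_fixture",
    "add_noise",
    "precision_recall",
    "PROFILES",
]


@dataclass
class GroundTruth:
    """A sampled additive ground truth: network, basal levels and effect sizes.

    ``effect_sizes[(stimulus, protein)]`` is the intensity increment the
    stimulus adds at every t > 0; ``mediation[(stimulus, protein)]`` names
    the inhibited node the path runs through, or ``None`` for a direct link.
    """

    stimuli: tuple
    inhibitors: tuple
    proteins: tuple
    inhibitor_targets: dict
    network: SignalingNetwork
    basal_levels: dict
    effect_sizes: dict
    mediation: dict
    timepoints: tuple = (0.0, 30.0, 180.0)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    seed: int = 0

    def links(self) -> frozenset:
        """Ground-truth links as 2-/3-node path tuples."""
        paths = []
        for (stim, protein), effect in self.effect_sizes.items():
            if effect <= 0:
                continue
            q = self.mediation.get((stim, protein))
            paths.append((stim, q, protein) if q else (stim, protein))
        return frozenset(paths)

    def clean_level(self, protein: str, condition: Condition, t: float) -> float:
        """Noise-free level: basal plus every unblocked additive effect (t > 0)."""
        level = self.basal_levels[protein]
        if t <= 0:
            return level
        blocked = {self.inhibitor_targets[j] for j in condition.inhibitors}
        for stim in condition.stimuli:
            if stim not in self.stimuli:
                raise KeyError(f"unknown stimulus {stim!r}")
            effect = self.effect_sizes.get((stim, protein), 0.0)
            if effect and self.mediation.get((stim, protein)) not in blocked:
                level += effect
        for j in condition.inhibitors:
            if j not in self.inhibitors:
                raise KeyError(f"unknown inhibitor {j!r}")
        return level


def sample_ground_truth(
    n_stimuli: int = 4,
    n_inhibitors: int = 4,
    n_proteins: int = 7,
    p_direct: float = 0.15,
    p_mediated: float = 0.15,
    effect_scale: float = 10.0,
    seed: int = 0,
    error_model: ErrorModel | None = None,
    timepoints: Sequence[float] = (0.0, 30.0, 180.0),
) -> GroundTruth:
    """Sample a random three-layer ground truth (seeded, reproducible).

    Each (stimulus, protein) pair independently receives no link, a direct
    link (probability ``p_direct``) or a link mediated by a uniformly
    chosen inhibited node (probability ``p_mediated``).
    """
    if p_direct < 0 or p_mediated < 0 or p_direct + p_mediated > 1:
        raise ValueError("need p_direct, p_mediated >= 0 and p_direct + p_mediated <= 1")
    if effect_scale <= 0:
        raise ValueError("effect_scale must be > 0")
    model = error_model or ErrorModel()
    rng = np.random.default_rng(seed)
    stimuli = tuple(f"ST{n + 1}" for n in range(n_stimuli))
    inhibitors = tuple(f"IN{n + 1}i" for n in range(n_inhibitors))
    targets = {j: j[:-1] for j in inhibitors}
    proteins = tuple(f"P{n + 1}" for n in range(n_proteins))

    basal = {p: float(rng.uniform(800.0, 1500.0)) for p in proteins}
    effects, mediation = {}, {}
    for stim in stimuli:
        for protein in proteins:
            u = rng.random()
            if u >= p_direct + p_mediated:
                continue
            effects[(stim, protein)] = float(
                rng.uniform(1.0, 1.5) * effect_scale * model.technical_sd
            )
            if u < p_direct or not inhibitors:
                mediation[(stim, protein)] = None
            else:
                mediation[(stim, protein)] = targets[
                    inhibitors[int(rng.integers(0, len(inhibitors)))]
                ]
    truth = GroundTruth(
        stimuli=stimuli,
        inhibitors=inhibitors,
        proteins=proteins,
        inhibitor_targets=targets,
        network=None,
        basal_levels=basal,
        effect_sizes=effects,
        mediation=mediation,
        timepoints=tuple(float(t) for t in timepoints),
        error_model=model,
        seed=int(seed),
    )
    truth.network = SignalingNetwork.from_paths(sorted(truth.links()))
    return truth


def training_conditions(truth: GroundTruth) -> list:
    """The single-perturbation design: reference, each stimulus, each inhibitor, each pair."""
    conds = [Condition.reference()]
    conds += [Condition.single(stimulus=s) for s in truth.stimuli]
    conds += [Condition.single(inhibitor=j) for j in truth.inhibitors]
    conds += [
        Condition.make([s], [j]) for s in truth.stimuli for j in truth.inhibitors
    ]
    return conds


def add_noise(clean, model: ErrorModel, rng: np.random.Generator):
    """Add Gaussian measurement noise with the model's variance at the clean level.

    Negative draws are clamped to the assay floor of 0.
    """
    clean = np.asarray(clean, dtype=float)
    noisy = clean + rng.standard_normal(clean.shape) * np.sqrt(model.variance(clean))
    return np.clip(noisy, 0.0, None)


def simulate_dataset(truth: GroundTruth, noise: bool = True, seed: int | None = None) -> PerturbationDataset:
    """Simulate the full single-perturbation training dataset.

    The noise stream is derived from ``truth.seed`` unless ``seed`` is given,
    so the same truth always yields the same dataset.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed if seed is None else int(seed), 1])
    )
    values = {}
    for cond in training_conditions(truth):
        for t in truth.timepoints:
            for protein in truth.proteins:
                x = truth.clean_level(protein, cond, t)
                if noise:
                    x = float(add_noise(x, truth.error_model, rng))
                values[(protein, cond, t)] = x
    return PerturbationDataset(
        proteins=truth.proteins,
        stimuli=truth.stimuli,
        inhibitors=truth.inhibitors,
        timepoints=truth.timepoints,
        values=values,
        inhibitor_targets=dict(truth.inhibitor_targets),
    )


def simulate_test_truth(
    truth: GroundTruth,
    test_conditions: Iterable[Condition],
    noise: bool = False,
    seed: int | None = None,
) -> dict:
    """Clean (or optionally noisy) levels under multi-perturbation conditions.

    Returns ``(protein, Condition, time) -> intensity`` over the truth's
    time grid, additive across stimuli exactly like the training simulator.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed if seed is None else int(seed), 2])
    )
    values = {}
    for cond in test_conditions:
        for t in truth.timepoints:
            for protein in truth.proteins:
                x = truth.clean_level(protein, cond, t)
                if noise:
                    x = float(add_noise(x, truth.error_model, rng))
                values[(protein, cond, t)] = x
    return values


def multiperturbation_dataset(truth: GroundTruth, values: dict) -> PerturbationDataset:
    """Wrap multi-perturbation levels as a dataset (no reference condition required)."""
    return PerturbationDataset(
        proteins=truth.proteins,
        stimuli=truth.stimuli,
        inhibitors=truth.inhibitors,
        timepoints=truth.timepoints,
        values=dict(values),
        inhibitor_targets=dict(truth.inhibitor_targets),
    )


def dream4_test_conditions(stimuli: Sequence[str], inhibitors: Sequence[str]) -> list:
    """The 20 pairwise test conditions of the 4x4 challenge design.

    Five stimulus settings (each single stimulus plus the combination of
    the last two) crossed with four inhibitor pairs (each of the middle two
    inhibitors with each of the outer two).
    """
    if len(stimuli) < 4 or len(inhibitors) < 4:
        raise ValueError("the pairwise design needs at least 4 stimuli and 4 inhibitors")
    stim_sets = [frozenset([s]) for s in stimuli[:4]]
    stim_sets.append(frozenset([stimuli[2], stimuli[3]]))
    inh_pairs = [
        frozenset([inhibitors[1], inhibitors[0]]),
        frozenset([inhibitors[2], inhibitors[0]]),
        frozenset([inhibitors[1], inhibitors[3]]),
        frozenset([inhibitors[2], inhibitors[3]]),
    ]
    return [Condition(S, J) for S in stim_sets for J in inh_pairs]


def write_conditions(conditions: Iterable[Condition], path) -> None:
    """Write a condition list as CSV with ``+``-joined stimuli / inhibitors columns."""
    with open(path, "w") as fh:
        fh.write("stimuli,inhibitors\n")
        for cond in conditions:
            stim = "+".join(sorted(cond.stimuli)) or "-"
            inh = "+".join(sorted(cond.inhibitors)) or "-"
            fh.write(f"{stim},{inh}\n")


def read_conditions(path) -> list:
    """Read back a condition-list CSV written by :func:`write_conditions`."""
    import pandas as pd

    from .data_model import parse_treatment_field

    df = pd.read_csv(path)
    return [
        Condition(parse_treatment_field(row["stimuli"]), parse_treatment_field(row["inhibitors"]))
        for _, row in df.iterrows()
    ]


def write_test_truth_csv(values: dict, path) -> None:
    rows = sorted(values.items(), key=lambda kv: (kv[0][0], kv[0][1].sort_key(), kv[0][2]))
    with open(path, "w") as fh:
        fh.write("protein,stimuli,inhibitors,time_min,value\n")
        for (protein, cond, t), x in rows:
            stim = "+".join(sorted(cond.stimuli)) or "-"
            inh = "+".join(sorted(cond.inhibitors)) or "-"
            fh.write(f"{protein},{stim},{inh},{t:.10g},{x:.10g}\n")


# named scenarios: (n_stimuli, n_inhibitors, n_proteins, p_direct, p_mediated,
#                   effect_scale, noise)
PROFILES = {
    "dream4-like": dict(
        n_stimuli=4, n_inhibitors=4, n_proteins=7,
        p_direct=0.15, p_mediated=0.15, effect_scale=10.0, noise=True,
    ),
    "tiny": dict(
        n_stimuli=2, n_inhibitors=1, n_proteins=2,
        p_direct=0.3, p_mediated=0.3, effect_scale=10.0, noise=False,
    ),
    "no-signal": dict(
        n_stimuli=4, n_inhibitors=4, n_proteins=7,
        p_direct=0.0, p_mediated=0.0, effect_scale=10.0, noise=False,
    ),
}


def _profile_test_conditions(truth: GroundTruth) -> list:
    if len(truth.stimuli) >= 4 and len(truth.inhibitors) >= 4:
        return dream4_test_conditions(truth.stimuli, truth.inhibitors)
    # small designs: every stimulus pair (or single) x every inhibitor
    conds = []
    stims = [frozenset([s]) for s in truth.stimuli]
    if len(truth.stimuli) >= 2:
        stims.append(frozenset(truth.stimuli[:2]))
    for S in stims:
        for j in truth.inhibitors:
            conds.append(Condition(S, frozenset([j])))
    return conds


def make_fixture(profile: str, seed: int, outdir) -> dict:
    """Write the named scenario's fixture files; returns a name -> path map.

    Files: MIDAS training data, test-condition list, ground-truth SIF,
    clean multi-perturbation truth CSV and (noisy scenarios) a measured
    test-set MIDAS file.  Same (profile, seed) yields byte-identical files.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    params = dict(PROFILES[profile])
    noise = params.pop("noise")
    truth = sample_ground_truth(seed=seed, **params)
    os.makedirs(outdir, exist_ok=True)
    ds = simulate_dataset(truth, noise=noise)
    conditions = _profile_test_conditions(truth)
    clean = simulate_test_truth(truth, conditions, noise=False)
    measured = simulate_test_truth(truth, conditions, noise=noise)

    paths = {
        "training": os.path.join(outdir, "training.csv"),
        "conditions": os.path.join(outdir, "test_conditions.csv"),
        "truth_sif": os.path.join(outdir, "truth.sif"),
        "test_truth": os.path.join(outdir, "test_truth.csv"),
        "test_measured": os.path.join(outdir, "test_measured.csv"),
    }
    write_midas(ds, paths["training"])
    write_conditions(conditions, paths["conditions"])
    write_sif(truth.network, paths["truth_sif"])
    write_test_truth_csv(clean, paths["test_truth"])
    write_midas(multiperturbation_dataset(truth, measured), paths["test_measured"])
    return paths


def precision_recall(truth_links: Iterable[tuple], recovered: Iterable[tuple]):
    """Link-level precision and recall of a recovered path set.

    Empty recovered sets give precision 1 by convention (no false claims);
    empty truth sets give recall 1.
    """
    truth_links = {tuple(p) for p in truth_links}
    recovered = {tuple(p) for p in recovered}
    tp = len(truth_links & recovered)
    precision = tp / len(recovered) if recovered else 1.0
    recall = tp / len(truth_links) if truth_links else 1.0
    return precision, recall
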