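import pytest

from boolsig import Condition, ErrorModel, PerturbationDataset


@pytest.fixture
def model_flat():
    """Constant-variance error model (no proportional term)."""
    return ErrorModel(technical_sd=300.0, biological_cv=0.0)


@pytest.fixture
def model_default():
    return ErrorModel()


def build_dataset(stimuli, inhibitors, proteins, timepoints, courses,
                  inhibitor_targets=None):
    """Construct a full single-perturbation dataset from per-condition courses.

    ``courses[(protein, stimulus_or_None, inhibitor_or_None)]`` is a tuple of
    intensities aligned with ``timepoints``; missing entries default to the
    protein's reference course.
    """
    values = {}
    conditions = [(None, None)]
    conditions += [(s, None) for s in stimuli]
    conditions += [(None, j) for j in inhibitors]
    conditions += [(s, j) for s in stimuli for j in inhibitors]
    for protein in proteins:
        ref_course = courses[(protein, None, None)]
        for stim, inh in conditions:
            course = courses.get((protein, stim, inh), ref_course)
            cond = Condition.single(stimulus=stim, inhibitor=inh)
            for t, x in zip(timepoints, course):
                values[(protein, cond, float(t))] = float(x)
    return PerturbationDataset(
        proteins=tuple(proteins),
        stimuli=tuple(stimuli),
        inhibitors=tuple(inhibitors),
        timepoints=tuple(float(t) for t in timepoints),
        values=values,
        inhibitor_targets=dict(inhibitor_targets or {}),
    )


@pytest.fixture
def ikb_dataset():
    """Hand-built dataset reproducing the classic Ikb inference cases.

    TNFa raises Ikb (flip point 2000/424.26 = 4.714 with flat SD 300);
    IKKi abolishes the response, MEKi leaves it untouched; IGF1 is inert.
    """
    courses = {
        ("Ikb", None, None): (1000, 1000, 1000),
        ("Ikb", "TNFa", None): (1000, 1000, 3000),
        ("Ikb", "TNFa", "IKKi"): (1000, 1000, 1000),
        ("Ikb", "TNFa", "MEKi"): (1000, 1000, 3000),
    }
    return build_dataset(
        ["TNFa", "IGF1"], ["IKKi", "MEKi"], ["Ikb"], (0, 30, 180), courses
    )
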