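import pytest

from boolsig import (
    Condition,
    PredictionTask,
    active_stimuli_and_mediators,
    isolate_subnetwork,
    predict_batch,
    predict_condition,
    reconstruct,
    reference_level,
    sample_ground_truth,
    simulate_dataset,
    simulate_test_truth,
    dream4_test_conditions,
)
from boolsig.pipeline import predict_conditions, tasks_for
from boolsig.synthetic_data import GroundTruth
from boolsig.network_reconstruction import SignalingNetwork

K = 2.5


def akt_truth(seed=0, extra_inert_stimulus=False):
    """Hand-built ground truth with the canonical two-stimuli-one-node topology:
    TGFa and IGF1 both act on AKT through PI3K; MEKi blocks nothing relevant."""
    stimuli = ("TGFa", "IGF1") + (("TNFa",) if extra_inert_stimulus else ())
    truth = GroundTruth(
        stimuli=stimuli,
        inhibitors=("MEKi", "PI3Ki"),
        proteins=("AKT", "ERK12"),
        inhibitor_targets={"MEKi": "MEK12", "PI3Ki": "PI3K"},
        network=None,
        basal_levels={"AKT": 1000.0, "ERK12": 900.0},
        effect_sizes={
            ("TGFa", "AKT"): 3000.0,
            ("IGF1", "AKT"): 2500.0,
            ("TGFa", "ERK12"): 2800.0,
        },
        mediation={
            ("TGFa", "AKT"): "PI3K",
            ("IGF1", "AKT"): "PI3K",
            ("TGFa", "ERK12"): "MEK12",
        },
        seed=seed,
    )
    truth.network = SignalingNetwork.from_paths(sorted(truth.links()))
    return truth


@pytest.fixture
def akt_setup():
    truth = akt_truth()
    ds = simulate_dataset(truth, noise=True)
    result = reconstruct(ds, truth.error_model, K)
    return truth, ds, result


class TestSubnetworkIsolation:
    def test_canonical_akt_subnetwork(self, akt_setup):
        truth, ds, result = akt_setup
        nodes, edges = isolate_subnetwork(
            result.network, "AKT", {"TGFa", "IGF1"}, {"MEKi", "PI3Ki"},
            inhibitor_targets=ds.inhibitor_targets,
        )
        assert nodes == {"AKT", "TGFa", "IGF1", "PI3K"}  # MEK12 excluded
        assert edges == {("TGFa", "PI3K"), ("IGF1", "PI3K"), ("PI3K", "AKT")}

    def test_unlinked_protein_is_isolated(self, akt_setup):
        truth, ds, result = akt_setup
        nodes, edges = isolate_subnetwork(result.network, "ERK12", {"IGF1"}, set())
        assert nodes == {"ERK12"}
        assert edges == set()

    def test_empty_stimuli_keeps_linked_inhibited_nodes(self, akt_setup):
        truth, ds, result = akt_setup
        nodes, _ = isolate_subnetwork(
            result.network, "AKT", set(), {"PI3Ki"},
            inhibitor_targets=ds.inhibitor_targets,
        )
        assert nodes == {"AKT", "PI3K"}

    def test_unknown_protein_rejected(self, akt_setup):
        with pytest.raises(KeyError):
            isolate_subnetwork(akt_setup[2].network, "nope", set(), set())


class TestActiveStimuliAndMediators:
    def test_both_stimuli_share_the_mediator(self, akt_setup):
        truth, ds, result = akt_setup
        A, mediators = active_stimuli_and_mediators(
            result.tables, result.network, "AKT", {"TGFa", "IGF1"}, {"MEKi", "PI3Ki"}
        )
        assert set(A) == {"TGFa", "IGF1"}
        assert mediators == {"TGFa": ("PI3Ki",), "IGF1": ("PI3Ki",)}

    def test_inert_stimuli_excluded(self, akt_setup):
        truth, ds, result = akt_setup
        A, _ = active_stimuli_and_mediators(
            result.tables, result.network, "ERK12", {"IGF1"}, set()
        )
        assert A == ()

    def test_no_mediator_in_requested_inhibitors(self, akt_setup):
        truth, ds, result = akt_setup
        A, mediators = active_stimuli_and_mediators(
            result.tables, result.network, "AKT", {"TGFa"}, {"MEKi"}
        )
        assert mediators == {"TGFa": ()}


class TestReferenceLevel:
    def test_linked_inhibitor_baseline(self, akt_setup):
        truth, ds, result = akt_setup
        ref = reference_level(ds, result.tables, "AKT", {"MEKi", "PI3Ki"}, 30.0)
        assert ref == ds.value("AKT", Condition.single(inhibitor="PI3Ki"), 30.0)

    def test_plain_reference_when_nothing_applies(self, akt_setup):
        truth, ds, result = akt_setup
        ref = reference_level(ds, result.tables, "AKT", set(), 30.0)
        assert ref == ds.value("AKT", Condition.reference(), 30.0)

    def test_inert_stimulus_conditions_averaged_in(self):
        truth = akt_truth(extra_inert_stimulus=True)  # TNFa never moves anything
        ds = simulate_dataset(truth, noise=True)
        result = reconstruct(ds, truth.error_model, K)
        ref = reference_level(ds, result.tables, "AKT", set(), 180.0)
        expected = (
            ds.value("AKT", Condition.reference(), 180.0)
            + ds.value("AKT", Condition.single(stimulus="TNFa"), 180.0)
        ) / 2
        assert ref == pytest.approx(expected, rel=1e-12)


class TestPredictCondition:
    def test_worked_example_formula(self, akt_setup):
        """Two stimuli sharing one mediating inhibitor: the inhibitor baseline
        is counted once — X(i1,j) + X(i2,j) − X(0,j)."""
        truth, ds, result = akt_setup
        task = PredictionTask.make("AKT", {"TGFa", "IGF1"}, {"MEKi", "PI3Ki"}, 180.0)
        record = predict_condition(ds, result.network, result.tables, task)
        expected = (
            ds.value("AKT", Condition.make(["TGFa"], ["PI3Ki"]), 180.0)
            + ds.value("AKT", Condition.make(["IGF1"], ["PI3Ki"]), 180.0)
            - ds.value("AKT", Condition.single(inhibitor="PI3Ki"), 180.0)
        )
        assert record.predicted == pytest.approx(expected, rel=1e-12)
        assert record.active_stimuli == {"TGFa", "IGF1"}

    def test_single_active_stimulus_with_mediator_reduces_to_lookup(self, akt_setup):
        truth, ds, result = akt_setup
        task = PredictionTask.make("AKT", {"TGFa"}, {"PI3Ki"}, 30.0)
        record = predict_condition(ds, result.network, result.tables, task)
        assert record.predicted == pytest.approx(
            ds.value("AKT", Condition.make(["TGFa"], ["PI3Ki"]), 30.0), rel=1e-12
        )

    def test_single_active_stimulus_no_inhibitors(self, akt_setup):
        truth, ds, result = akt_setup
        task = PredictionTask.make("AKT", {"IGF1"}, set(), 30.0)
        record = predict_condition(ds, result.network, result.tables, task)
        assert record.predicted == pytest.approx(
            ds.value("AKT", Condition.single(stimulus="IGF1"), 30.0), rel=1e-12
        )

    def test_no_active_stimulus_returns_reference(self, akt_setup):
        truth, ds, result = akt_setup
        task = PredictionTask.make("ERK12", {"IGF1"}, {"PI3Ki"}, 180.0)
        record = predict_condition(ds, result.network, result.tables, task)
        assert record.active_stimuli == frozenset()
        assert record.predicted == record.reference_used

    def test_negative_totals_clamped_to_zero(self):
        # force a negative combination: tiny stimulus+inhibitor level, large baseline
        truth = akt_truth()
        ds = simulate_dataset(truth, noise=False)
        key = ("AKT", Condition.make(["TGFa"], ["PI3Ki"]), 180.0)
        ds.values[key] = 0.0
        key2 = ("AKT", Condition.make(["IGF1"], ["PI3Ki"]), 180.0)
        ds.values[key2] = 0.0
        result = reconstruct_with_truth_tables(truth, ds)
        task = PredictionTask.make("AKT", {"TGFa", "IGF1"}, {"PI3Ki"}, 180.0)
        record = predict_condition(ds, result.network, result.tables, task)
        assert record.predicted == 0.0

    def test_prediction_at_t0_equals_reference(self, akt_setup):
        truth, ds, result = akt_setup
        task = PredictionTask.make("AKT", {"TGFa", "IGF1"}, {"PI3Ki"}, 0.0)
        record = predict_condition(ds, result.network, result.tables, task)
        # noise-free at t=0 every condition sits at basal, so use clean data
        ds_clean = simulate_dataset(truth, noise=False)
        result_clean = reconstruct(ds_clean, truth.error_model, K)
        rec = predict_condition(ds_clean, result_clean.network, result_clean.tables, task)
        assert rec.predicted == pytest.approx(rec.reference_used, rel=1e-12)


def reconstruct_with_truth_tables(truth, ds):
    return reconstruct(ds, truth.error_model, K)


class TestExactnessOnAdditiveTruth:
    @pytest.mark.parametrize("seed", range(3))
    def test_noise_free_predictions_match_truth(self, seed):
        truth = sample_ground_truth(seed=seed, effect_scale=10.0)
        ds = simulate_dataset(truth, noise=False)
        result = reconstruct(ds, truth.error_model, K)
        conds = dream4_test_conditions(truth.stimuli, truth.inhibitors)
        expected = simulate_test_truth(truth, conds)
        records = predict_conditions(ds, result, conds)
        for r in records:
            want = expected[(r.task.protein, r.task.condition, r.task.time)]
            assert r.predicted == pytest.approx(want, rel=1e-9, abs=1e-6)


class TestBatch:
    def test_empty_task_list(self, akt_setup):
        truth, ds, result = akt_setup
        assert predict_batch(ds, result.network, result.tables, []) == []

    def test_order_preserved_and_deterministic(self, akt_setup):
        truth, ds, result = akt_setup
        tasks = tasks_for(ds.proteins, dream4_test_conditions_small(truth), ds.timepoints)
        recs1 = predict_batch(ds, result.network, result.tables, tasks)
        recs2 = predict_batch(ds, result.network, result.tables, tasks)
        assert [r.task for r in recs1] == tasks
        assert [r.predicted for r in recs1] == [r.predicted for r in recs2]


def dream4_test_conditions_small(truth):
    return [
        Condition.make([truth.stimuli[0]], [truth.inhibitors[0]]),
        Condition.make(truth.stimuli[:2], truth.inhibitors[:2]),
    ]
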