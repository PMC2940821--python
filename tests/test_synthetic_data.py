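import numpy as np
import pytest

from boolsig import (
    Condition,
    ErrorModel,
    dream4_test_conditions,
    make_fixture,
    precision_recall,
    reconstruct,
    sample_ground_truth,
    simulate_dataset,
    simulate_test_truth,
)
from boolsig.synthetic_data import add_noise, read_conditions, training_conditions


class TestSampleGroundTruth:
    def test_same_seed_identical_truth(self):
        a = sample_ground_truth(seed=5)
        b = sample_ground_truth(seed=5)
        assert a.links() == b.links()
        assert a.basal_levels == b.basal_levels
        assert a.effect_sizes == b.effect_sizes

    def test_zero_probabilities_give_empty_network(self):
        truth = sample_ground_truth(p_direct=0.0, p_mediated=0.0, seed=2)
        assert truth.links() == frozenset()
        assert truth.network.edge_count == 0

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            sample_ground_truth(p_direct=0.7, p_mediated=0.5)

    def test_link_count_distribution(self):
        """~Binomial(28, 0.3) links per 4x4x7 truth."""
        counts = [
            len(sample_ground_truth(seed=s).effect_sizes) for s in range(200)
        ]
        assert abs(float(np.mean(counts)) - 28 * 0.3) < 0.6

    def test_effect_sizes_bounded_below_by_scale(self):
        truth = sample_ground_truth(seed=9, effect_scale=5.0)
        sd = truth.error_model.technical_sd
        assert all(5.0 * sd <= e <= 7.5 * sd for e in truth.effect_sizes.values())


class TestSimulateDataset:
    def test_training_design_counts(self):
        truth = sample_ground_truth(seed=0)
        ds = simulate_dataset(truth, noise=False)
        assert len(ds.conditions()) == 25  # ref + 4 stim + 4 inh + 16 pairs
        assert len(ds.values) == 25 * 3 * 7

    def test_noise_off_no_links_is_flat(self):
        truth = sample_ground_truth(p_direct=0.0, p_mediated=0.0, seed=1)
        ds = simulate_dataset(truth, noise=False)
        for (protein, cond, t), x in ds.values.items():
            assert x == truth.basal_levels[protein]

    def test_noise_off_direct_link_pattern(self):
        truth = sample_ground_truth(
            n_stimuli=1, n_inhibitors=1, n_proteins=1, p_direct=1.0, p_mediated=0.0, seed=3
        )
        ds = simulate_dataset(truth, noise=False)
        basal = truth.basal_levels["P1"]
        effect = truth.effect_sizes[("ST1", "P1")]
        stim = Condition.single(stimulus="ST1")
        assert ds.value("P1", stim, 0) == basal
        assert ds.value("P1", stim, 30) == basal + effect
        assert ds.value("P1", Condition.reference(), 180) == basal
        # a non-mediating inhibitor does not block a direct effect
        assert ds.value("P1", Condition.make(["ST1"], ["IN1i"]), 30) == basal + effect

    def test_same_seed_identical_noise(self):
        truth = sample_ground_truth(seed=4)
        a = simulate_dataset(truth, noise=True)
        b = simulate_dataset(truth, noise=True)
        assert a.values == b.values

    def test_noise_sd_matches_error_model(self):
        model = ErrorModel()
        rng = np.random.default_rng(123)
        clean = np.full(1000, 2000.0)
        draws = add_noise(clean, model, rng)
        assert abs(float(np.std(draws, ddof=1)) - model.sd(2000.0)) / model.sd(2000.0) < 0.05


class TestSimulateTestTruth:
    def test_disjoint_mediators_are_additive(self):
        truth = sample_ground_truth(seed=8)
        # pick two stimuli with effects on some protein
        conds = [Condition.make(truth.stimuli[:2])]
        vals = simulate_test_truth(truth, conds)
        for protein in truth.proteins:
            expected = truth.basal_levels[protein]
            for s in truth.stimuli[:2]:
                expected += truth.effect_sizes.get((s, protein), 0.0)
            assert vals[(protein, conds[0], 30.0)] == pytest.approx(expected)

    def test_inhibitor_blocking_all_paths_returns_basal(self):
        truth = sample_ground_truth(
            n_stimuli=1, n_inhibitors=1, n_proteins=1, p_direct=0.0, p_mediated=1.0, seed=5
        )
        cond = Condition.make(["ST1"], ["IN1i"])
        vals = simulate_test_truth(truth, [cond])
        assert vals[("P1", cond, 180.0)] == truth.basal_levels["P1"]

    def test_unknown_ids_rejected(self):
        truth = sample_ground_truth(seed=1)
        with pytest.raises(KeyError):
            simulate_test_truth(truth, [Condition.make(["bogus"])])


class TestDesigns:
    def test_pairwise_test_conditions(self):
        truth = sample_ground_truth(seed=0)
        conds = dream4_test_conditions(truth.stimuli, truth.inhibitors)
        assert len(conds) == 20
        assert all(len(c.inhibitors) == 2 for c in conds)
        assert sum(len(c.stimuli) == 2 for c in conds) == 4
        assert len(set(conds)) == 20

    def test_training_conditions_single_perturbation_only(self):
        truth = sample_ground_truth(seed=0)
        for cond in training_conditions(truth):
            assert len(cond.stimuli) <= 1 and len(cond.inhibitors) <= 1


class TestMakeFixture:
    def test_tiny_profile_files(self, tmp_path):
        paths = make_fixture("tiny", seed=1, outdir=tmp_path)
        for p in paths.values():
            assert (tmp_path / p.split("/")[-1]).exists()
        conds = read_conditions(paths["conditions"])
        assert conds and all(len(c.inhibitors) >= 1 for c in conds)

    def test_same_seed_byte_identical(self, tmp_path):
        a = make_fixture("dream4-like", seed=7, outdir=tmp_path / "a")
        b = make_fixture("dream4-like", seed=7, outdir=tmp_path / "b")
        for name in a:
            assert open(a[name], "rb").read() == open(b[name], "rb").read()

    def test_no_signal_profile_yields_empty_network(self, tmp_path):
        from boolsig import read_midas

        paths = make_fixture("no-signal", seed=3, outdir=tmp_path)
        ds = read_midas(paths["training"])
        for k in (1.0, 2.5, 6.0):
            assert reconstruct(ds, ErrorModel(), k).network.edge_count == 0

    def test_dream4_profile_counts(self, tmp_path):
        from boolsig import read_midas

        paths = make_fixture("dream4-like", seed=2, outdir=tmp_path)
        ds = read_midas(paths["training"])
        assert len(ds.proteins) == 7
        assert len(ds.stimuli) == 4
        assert len(ds.inhibitors) == 4
        assert len(ds.conditions()) == 25
        assert len(read_conditions(paths["conditions"])) == 20

    def test_unknown_profile_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            make_fixture("nope", seed=0, outdir=tmp_path)


def test_precision_recall_conventions():
    truth = {("a", "p"), ("b", "q", "p")}
    assert precision_recall(truth, truth) == (1.0, 1.0)
    assert precision_recall(truth, set()) == (1.0, 0.0)
    assert precision_recall(set(), {("a", "p")}) == (0.0, 1.0)
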