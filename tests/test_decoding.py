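from collections import Counter

import numpy as np
import pytest
from scipy import stats

from aobdecode import (
    PopulationSpec,
    build_task_suite,
    generate_population,
    generate_stimulus_panel,
    simulate_trials,
)
from aobdecode.core import StimulusDescriptor
from aobdecode.decoding import (
    DecodingTask,
    best_single_unit,
    removal_curve_least,
    run_cycles,
    sample_population_vectors,
    train_perceptron,
)
from conftest import make_tiny_table
from oracles import grid_min_error, novikoff_update_bound


def pair_task(label_map, name="t", category="simple_pairwise", test_map=None):
    return DecodingTask(name, category, "state", label_map, test_map or label_map)


class TestTaskSuite:
    @pytest.mark.parametrize("trait", ["state", "strain"])
    def test_diluted_panel_task_counts(self, set1_panel, trait):
        counts = Counter(t.category for t in build_task_suite(set1_panel, trait))
        assert counts == {
            "simple_pairwise": 6,
            "cross_dilution_generalization": 12,
            "dilution_invariant": 2,
            "cross_strain_generalization": 2,
            "general": 1,
        }

    @pytest.mark.parametrize("trait", ["state", "strain"])
    def test_multi_secretion_task_counts(self, set3_panel, trait):
        counts = Counter(t.category for t in build_task_suite(set3_panel, trait))
        assert counts == {
            "per_secretion": 3,
            "cross_secretion_generalization": 6,
            "across_secretions": 1,
        }

    def test_generalization_maps_are_disjoint(self, set1_panel):
        for task in build_task_suite(set1_panel, "state"):
            if task.is_generalization:
                assert not set(task.train_map) & set(task.test_map)
            else:
                assert task.train_map == task.test_map
            assert set(task.train_map.values()) == {0, 1}

    def test_degenerate_panel_single_pairwise_task(self):
        panel = [
            StimulusDescriptor(f"s{i}", "urine", "BC", state, "H")
            for i, state in enumerate(["estrus", "non_estrus"])
        ]
        tasks = build_task_suite(panel, "state")
        assert [t.category for t in tasks] == ["simple_pairwise"]

    def test_missing_trait_level_named_in_error(self):
        panel = [StimulusDescriptor("s0", "urine", "BC", "estrus", "H")]
        with pytest.raises(ValueError, match="state"):
            build_task_suite(panel, "state")


class TestVectorSampling:
    def test_labels_balanced(self, structured_table):
        task = build_task_suite(structured_table.stimuli, "state")[-1]
        _, y = sample_population_vectors(
            structured_table, task.train_map, 100, np.random.default_rng(0)
        )
        assert np.sum(y == 0) == np.sum(y == 1) == 50

    def test_single_trial_table_gives_deterministic_vectors(self):
        table = make_tiny_table(np.arange(8.0).reshape(2, 4, 1))
        X, y = sample_population_vectors(
            table, {"s0": 0, "s1": 1}, 40, np.random.default_rng(1)
        )
        for label, stim_col in ((0, 0), (1, 1)):
            rows = X[y == label]
            np.testing.assert_array_equal(
                rows, np.tile(table.responses[:, stim_col, 0], (len(rows), 1))
            )

    def test_per_stimulus_vector_distribution_uniform(self):
        # 2 units x 5 trials: 25 equally likely vectors per stimulus
        rng = np.random.default_rng(2)
        table = make_tiny_table(np.arange(20.0).reshape(2, 2, 5))
        X, y = sample_population_vectors(table, {"s0": 0, "s1": 1}, 10_000, rng)
        rows = X[y == 0]
        # map each vector to its (trial_u0, trial_u1) cell
        cells = (rows[:, 0].astype(int) * 5) + (rows[:, 1].astype(int) - 10)
        observed = np.bincount(cells, minlength=25)
        chi2 = ((observed - len(rows) / 25) ** 2 / (len(rows) / 25)).sum()
        assert stats.chi2.sf(chi2, df=24) > 0.001

    def test_empty_map_rejected(self, structured_table):
        with pytest.raises(ValueError):
            sample_population_vectors(structured_table, {}, 10, np.random.default_rng(0))


class TestPerceptron:
    def test_separable_one_unit_converges(self):
        rng = np.random.default_rng(0)
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        clf = train_perceptron(X, y, rng)
        assert clf.training_error == 0.0
        assert clf.epochs_run <= 100

    def test_learned_boundary_matches_grid_oracle(self):
        # grid search certifies separability and that only unit 2 carries
        # label information (the expected separator weights it positively)
        X = np.array([[0.0, 1.0], [0.0, -1.0], [1.0, 1.0], [1.0, -1.0]])
        y = np.array([1, 0, 1, 0])
        err, v = grid_min_error(X, y)
        assert err == 0.0 and v[1] > 0
        clf = train_perceptron(X, y, np.random.default_rng(3))
        assert clf.training_error == 0.0
        assert np.array_equal(clf.decide(X), y)
        assert clf.weights[1] > 0

    def test_xor_labels_leave_training_error(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1, 1, 0])
        clf = train_perceptron(X, y, np.random.default_rng(4))
        assert clf.epochs_run == 100
        assert clf.training_error > 0.0

    def test_update_count_respects_novikoff_bound(self):
        # clusters at +/-(2, 0) with margin 2: the update bound from the
        # unit separator w=(1,0), b=0 caps total updates
        rng = np.random.default_rng(5)
        X = np.vstack([
            rng.normal([2.0, 0.0], 0.3, (20, 2)),
            rng.normal([-2.0, 0.0], 0.3, (20, 2)),
        ])
        y = np.r_[np.ones(20, dtype=int), np.zeros(20, dtype=int)]
        v = np.array([1.0, 0.0, 0.0])
        bound = novikoff_update_bound(X, y, v)
        clf = train_perceptron(X, y, rng, max_epochs=1000)
        assert clf.training_error == 0.0
        assert clf.n_updates <= bound

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            train_perceptron(np.array([[np.nan]]), np.array([0]), np.random.default_rng(0))

    def test_ties_assigned_to_label_zero(self):
        clf = train_perceptron(np.array([[1.0]]), np.array([0]), np.random.default_rng(0))
        assert clf.decide(np.array([[0.0]]))[0] == 0  # activation exactly 0


class TestRunCycles:
    def test_shuffled_test_labels_give_chance_accuracy(self, structured_table):
        # destroying the vector <-> label association at test time must
        # reduce any trained classifier to chance
        rng = np.random.default_rng(7)
        task = build_task_suite(structured_table.stimuli, "state")[-1]
        correct = 0
        n_total = 0
        for _ in range(10):
            X_tr, y_tr = sample_population_vectors(
                structured_table, task.train_map, 100, rng
            )
            clf = train_perceptron(X_tr, y_tr, rng)
            X_te, y_te = sample_population_vectors(
                structured_table, task.test_map, 100, rng
            )
            rng.shuffle(y_te)
            correct += int(np.sum(clf.decide(X_te) == y_te))
            n_total += 100
        lo, hi = stats.binom.interval(0.95, n_total, 0.5)
        assert lo / n_total <= correct / n_total <= hi / n_total

    def test_zero_noise_separable_means_perfect_accuracy(self, set1_panel):
        spec = PopulationSpec(seed=9, trial_noise_sd=0.0, interaction_fraction=0.0)
        pop = generate_population(spec)
        table = simulate_trials(pop, set1_panel, seed=10)
        task = [
            t for t in build_task_suite(set1_panel, "state")
            if t.category == "simple_pairwise"
        ][0]
        result = run_cycles(task, table, np.random.default_rng(8), n_cycles=5)
        assert result.best_accuracy == 1.0

    def test_reproducible_under_seed(self, structured_table):
        task = build_task_suite(structured_table.stimuli, "state")[0]
        r1 = run_cycles(task, structured_table, np.random.default_rng(42), n_cycles=3)
        r2 = run_cycles(task, structured_table, np.random.default_rng(42), n_cycles=3)
        np.testing.assert_array_equal(r1.accuracies, r2.accuracies)

    def test_accuracies_within_unit_interval(self, structured_table):
        task = build_task_suite(structured_table.stimuli, "state")[3]
        result = run_cycles(task, structured_table, np.random.default_rng(1), n_cycles=4)
        assert np.all((result.accuracies >= 0) & (result.accuracies <= 1))


class TestRemovalCurve:
    def test_noise_unit_removed_before_informative_unit(self):
        rng = np.random.default_rng(12)
        # unit 0 separates perfectly; unit 1 is pure noise
        informative = np.array([[-1.0, -1.2, 1.0, 1.1]])
        noise = rng.normal(0, 1.0, (1, 2, 2))
        data = np.stack(
            [informative.reshape(2, 2), noise[0]], axis=0
        )
        table = make_tiny_table(data)
        task = pair_task({"s0": 0, "s1": 1})
        curve = removal_curve_least(task, table, rng, n_cycles=5, n_train=40, n_test=40)
        assert curve.removal_order == ["u1", "u0"]

    def test_curve_defined_at_every_count(self, structured_table):
        sub = structured_table.subset_units(range(8))
        task = build_task_suite(sub.stimuli, "state")[0]
        curve = removal_curve_least(task, sub, np.random.default_rng(13), n_cycles=2)
        np.testing.assert_array_equal(curve.unit_counts, np.arange(8, 0, -1))
        assert sorted(curve.removal_order) == sorted(sub.unit_ids)

    def test_single_unit_table_rejected(self, structured_table):
        task = build_task_suite(structured_table.stimuli, "state")[0]
        with pytest.raises(ValueError):
            removal_curve_least(
                task, structured_table.subset_units([0]), np.random.default_rng(0)
            )


class TestBestSingleUnit:
    def test_perfect_unit_found(self):
        data = np.zeros((3, 2, 3))
        data[1, 0] = [-2.0, -2.1, -1.9]
        data[1, 1] = [2.0, 2.1, 1.9]
        table = make_tiny_table(data)
        task = pair_task({"s0": 0, "s1": 1})
        unit, acc = best_single_unit(task, table, np.random.default_rng(14), n_cycles=3)
        assert unit == "u1"
        assert acc == 1.0

    def test_not_below_removal_curve_single_unit_endpoint(self, structured_table):
        # the sequential-removal path can end on a suboptimal unit, so the
        # exhaustive single-unit sweep may only match or beat its endpoint
        sub = structured_table.subset_units(range(12))
        task = build_task_suite(sub.stimuli, "state")[-1]
        rng = np.random.default_rng(15)
        curve = removal_curve_least(task, sub, rng, n_cycles=3)
        _, best = best_single_unit(task, sub, rng, n_cycles=3)
        assert best >= curve.accuracy_at(1) - 0.1  # sampling tolerance
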