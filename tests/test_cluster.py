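import numpy as np
import pytest

import clustvar as cv
from clustvar.exceptions import InfeasiblePartitionError, ParameterError
from conftest import make_stationary_model, simulate_series


def random_panel(rng, I=8, M=2, T=25):
    """Persons drawn from two latent regimes, moderate noise."""
    models = [make_stationary_model(M, rng) for _ in range(2)]
    return cv.panel_from_arrays({
        f"p{i}": simulate_series(models[i % 2], T, rng) for i in range(I)
    })


class TestPersonSse:
    def test_noiseless_data_zero_error(self, rng):
        model = make_stationary_model(2, rng)
        y = simulate_series(model, 15, rng, noise=0.0)
        assert cv.person_sse([y], model) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computation_univariate(self):
        # pairs (1,2),(2,4): slope 2 fits exactly, slope 1 errs 1^2 + 2^2
        seg = [np.array([[1.0], [2.0], [4.0]])]
        exact = cv.VARModel(np.zeros(1), np.array([[2.0]]), np.eye(1), 0, 0.0)
        off = cv.VARModel(np.zeros(1), np.array([[1.0]]), np.eye(1), 0, 0.0)
        assert cv.person_sse(seg, exact) == pytest.approx(0.0)
        assert cv.person_sse(seg, off) == pytest.approx(5.0)

    def test_cluster_sse_is_sum_of_member_sses(self, rng):
        panel = random_panel(rng)
        segs = [s for p in panel.persons for s in p.segments]
        model = cv.fit_var(segs, variable_names=panel.variable_names)
        total = sum(cv.person_sse(p.segments, model) for p in panel.persons)
        assert model.sse == pytest.approx(total, rel=1e-9)


class TestStarts:
    def test_random_start_each_cluster_nonempty(self):
        part = cv.random_start(5, 5, rng_seed=3)
        assert sorted(part.assignment) == [0, 1, 2, 3, 4]

    def test_single_cluster(self):
        part = cv.random_start(7, 1, rng_seed=0)
        assert np.all(part.assignment == 0)

    def test_shares_concentrate(self):
        part = cv.random_start(1000, 2, rng_seed=11)
        share = part.sizes()[0] / 1000
        assert 0.4 < share < 0.6

    def test_infeasible(self):
        with pytest.raises(InfeasiblePartitionError):
            cv.random_start(2, 3, rng_seed=0)

    def test_deterministic_given_seed(self):
        a = cv.random_start(50, 4, rng_seed=9)
        b = cv.random_start(50, 4, rng_seed=9)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_rational_start_recovers_separated_groups(self, two_cluster_dataset):
        ds = two_cluster_dataset
        part = cv.rational_start(ds.panel, 2)
        assert cv.adjusted_rand(ds.true_partition, part) == pytest.approx(1.0)

    def test_rational_start_k1(self, two_cluster_dataset):
        part = cv.rational_start(two_cluster_dataset.panel, 1)
        assert np.all(part.assignment == 0)

    def test_identical_persons_co_clustered(self, rng):
        a = rng.standard_normal((20, 2))
        b = rng.standard_normal((20, 2)) + 5
        panel = cv.panel_from_arrays({"a1": a, "a2": a.copy(),
                                      "b1": b, "b2": b.copy()})
        part = cv.rational_start(panel, 2)
        assert part.assignment[0] == part.assignment[1]
        assert part.assignment[2] == part.assignment[3]
        assert part.assignment[0] != part.assignment[2]


class TestAlsFit:
    def test_truth_start_is_fixed_point_noiseless(self, rng):
        models = [make_stationary_model(2, rng) for _ in range(2)]
        panel = cv.panel_from_arrays({
            f"p{i}": simulate_series(models[i % 2], 12, rng, noise=0.0)
            for i in range(6)
        })
        truth = cv.Partition(np.arange(6) % 2, 2)
        fit = cv.als_fit(panel, 2, truth)
        assert fit.converged and fit.n_iterations == 1
        np.testing.assert_array_equal(fit.partition.assignment,
                                      truth.assignment)
        assert fit.loss == pytest.approx(0.0, abs=1e-10)

    def test_k1_equals_pooled_fit(self, rng):
        panel = random_panel(rng)
        fit = cv.als_fit(panel, 1, cv.Partition(np.zeros(8, dtype=int), 1))
        pooled = cv.fit_var([s for p in panel.persons for s in p.segments])
        assert fit.loss == pytest.approx(pooled.sse, rel=1e-9)
        np.testing.assert_allclose(fit.models[0].slopes, pooled.slopes,
                                   atol=1e-10)

    def test_easy_cell_rational_start_perfect(self, two_cluster_dataset):
        ds = two_cluster_dataset
        start = cv.rational_start(ds.panel, 2)
        fit = cv.als_fit(ds.panel, 2, start)
        assert cv.adjusted_rand(ds.true_partition,
                                fit.partition) == pytest.approx(1.0)

    def test_loss_monotone_over_sweeps_50_instances(self, rng):
        """The loss never increases across recorded sweeps (random starts)."""
        for trial in range(50):
            panel = random_panel(rng, I=int(rng.integers(6, 12)),
                                 T=int(rng.integers(12, 30)))
            K = int(rng.integers(2, 4))
            start = cv.random_start(panel.n_persons, K, rng_seed=trial)
            fit = cv.als_fit(panel, K, start, debug_monotonic=True)
            hist = np.array(fit.loss_history)
            assert np.all(np.diff(hist) <= 1e-7 * np.maximum(hist[:-1], 1.0))
            assert fit.converged

    def test_final_loss_matches_person_sse_recomputation(self, rng):
        panel = random_panel(rng)
        fit = cv.als_fit(panel, 2, cv.random_start(8, 2, rng_seed=1))
        direct = sum(
            cv.person_sse(p.segments, fit.models[fit.partition.assignment[i]])
            for i, p in enumerate(panel.persons)
        )
        assert fit.loss == pytest.approx(direct, rel=1e-9)

    def test_label_permutation_changes_nothing_but_labels(self, rng):
        panel = random_panel(rng, I=10)
        start = cv.random_start(10, 3, rng_seed=4)
        swapped = cv.Partition((start.assignment + 1) % 3, 3)
        f1 = cv.als_fit(panel, 3, start)
        f2 = cv.als_fit(panel, 3, swapped)
        assert f1.loss == pytest.approx(f2.loss, rel=1e-12)
        np.testing.assert_array_equal(
            (f1.partition.assignment + 1) % 3, f2.partition.assignment)

    def test_empty_cluster_veto_preserves_k(self, rng):
        # K close to I forces veto situations; cluster count must survive
        panel = random_panel(rng, I=6, T=40)
        fit = cv.als_fit(panel, 5, cv.random_start(6, 5, rng_seed=2))
        assert len(np.unique(fit.partition.assignment)) == 5

    def test_mismatched_start_rejected(self, rng):
        panel = random_panel(rng)
        with pytest.raises(ParameterError):
            cv.als_fit(panel, 2, cv.Partition(np.zeros(3, dtype=int), 1))


class TestMultistart:
    def test_single_run_attraction_is_one(self, rng):
        panel = random_panel(rng)
        res = cv.multistart_fit(panel, 2, n_random_starts=1,
                                use_rational=False, rng_seed=5)
        assert res.attraction_rate == 1.0
        assert len(res.all_losses) == 1

    def test_noiseless_separable_all_runs_reach_zero(self, rng):
        models = [make_stationary_model(2, rng, radius=0.8) for _ in range(2)]
        panel = cv.panel_from_arrays({
            f"p{i}": simulate_series(models[i % 2], 15, rng, noise=0.0)
            for i in range(8)
        })
        res = cv.multistart_fit(panel, 2, n_random_starts=8, rng_seed=7)
        assert res.attraction_rate == 1.0
        assert res.best.loss == pytest.approx(0.0, abs=1e-10)

    def test_best_is_minimum_of_all_losses(self, rng):
        panel = random_panel(rng, I=10, T=18)
        res = cv.multistart_fit(panel, 3, n_random_starts=10, rng_seed=13)
        assert res.best.loss == min(res.all_losses)

    def test_seed_determinism_bit_identical(self, two_cluster_dataset):
        panel = two_cluster_dataset.panel
        r1 = cv.multistart_fit(panel, 2, n_random_starts=4, rng_seed=99)
        r2 = cv.multistart_fit(panel, 2, n_random_starts=4, rng_seed=99)
        assert r1.all_losses == r2.all_losses
        assert r1.best.loss == r2.best.loss
        np.testing.assert_array_equal(r1.best.partition.assignment,
                                      r2.best.partition.assignment)
        for m1, m2 in zip(r1.best.models, r2.best.models):
            np.testing.assert_array_equal(m1.slopes, m2.slopes)

    def test_estimated_loss_never_exceeds_truth_refit(self, rng):
        """Local-minimum check: the multistart loss is at most the loss of
        refitting under the true partition."""
        for seed in range(5):
            cell = cv.DesignCell(2, 50, 30, "similar", "equal", "equal")
            ds = cv.generate_dataset(cell, 0, seed=seed)
            res = cv.multistart_fit(ds.panel, 2, n_random_starts=10,
                                    rng_seed=seed)
            truth_fit = cv.als_fit(ds.panel, 2, ds.true_partition,
                                   max_sweeps=0)
            assert res.best.loss <= truth_fit.loss * (1 + 1e-12)
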