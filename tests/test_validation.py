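"""Cross-validation, permutation testing, and variable-selection behaviour."""
import numpy as np
import pytest

from arrestomix.validation import (
    cross_validate_q2,
    make_folds,
    permutation_test,
    select_components,
    stability_selection,
    validate,
    vip_select,
)

from conftest import make_signal_dataset


class TestFolds:
    def test_interleaved_assignment(self):
        folds = make_folds(14, 7)
        assert all(f.size == 2 for f in folds)
        assert np.array_equal(folds[0], [0, 7])

    def test_grouped_keeps_animals_whole(self):
        gids = np.repeat([f"a{i}" for i in range(6)], 4)
        folds = make_folds(24, 3, scheme="grouped", group_ids=gids)
        for f in folds:
            animals = set(gids[f])
            for other in folds:
                if other is not f:
                    assert animals.isdisjoint(set(gids[other]))

    def test_small_fold_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            make_folds(8, 7)


class TestQ2:
    def test_noiseless_linear_signal_is_recovered(self, rng):
        X = rng.normal(size=(28, 5))
        b = rng.normal(size=5)
        y = X @ b
        q2 = cross_validate_q2(X, y, 5, n_folds=7)
        assert q2[-1] >= 0.99

    def test_null_response_gives_nonpositive_q2(self):
        neg = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            X = r.normal(size=(42, 10))
            y = r.normal(size=42)
            q2 = cross_validate_q2(X, y, 2, n_folds=7)
            neg += q2[-1] <= 0
        assert neg >= 90

    def test_q2_invariant_to_variable_order(self, rng):
        X, y = make_signal_dataset(rng, n=21, p=6)
        q2 = cross_validate_q2(X, y, 2, n_folds=7)
        perm = rng.permutation(6)
        q2p = cross_validate_q2(X[:, perm], y, 2, n_folds=7)
        np.testing.assert_allclose(q2, q2p, atol=1e-10)


class TestSelectComponents:
    def test_one_dimensional_signal_selects_one(self):
        """SNR-5 rank-one signal: one latent direction should suffice."""
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            latent = r.normal(size=28)
            X = np.outer(latent, r.normal(size=8)) + 0.1 * r.normal(size=(28, 8))
            y = latent + 0.2 * r.normal(size=28)
            a, _ = select_components(X, y, 3, n_folds=7)
            hits += a == 1
        assert hits >= 95

    def test_pure_noise_floors_at_one_with_warning(self):
        r = np.random.default_rng(3)
        X = r.normal(size=(42, 10))
        y = r.normal(size=42)
        with pytest.warns(UserWarning, match="Q2 <= 0"):
            a, q2 = select_components(X, y, 3, n_folds=7)
        assert a == 1 and q2[0] <= 0

    def test_two_orthogonal_signals_select_two(self, rng):
        n = 42
        t1, t2 = rng.normal(size=n), rng.normal(size=n)
        X = np.column_stack([t1, t1, t2, t2]) + 0.01 * rng.normal(size=(n, 4))
        Y = np.column_stack([t1, t2])
        a, _ = select_components(X, Y, 3, n_folds=7, x_scaling=None)
        assert a == 2


class TestPermutation:
    def test_minimum_p_is_one_over_n_plus_one(self, rng):
        X, y = make_signal_dataset(rng, n=21, p=5, effect=8.0, noise=0.05)
        out = permutation_test(X, y, 1, n_permutations=19, seed=0, statistics=("R2",))
        assert out["p_R2"] >= 1 / 20
        # analytic floor: even a perfect separation cannot beat 1/(n+1)
        assert min(out["p_R2"], 1.0) >= 1.0 / (19 + 1)

    def test_strong_separation_hits_floor(self, rng):
        labels = np.repeat([1.0, -1.0], 14)
        X = np.outer(labels, np.ones(5)) * 5 + rng.normal(size=(28, 5))
        out = permutation_test(X, labels, 1, n_permutations=99, seed=1, statistics=("R2", "Q2"))
        assert out["p_R2"] == pytest.approx(1 / 100)
        assert out["p_Q2"] == pytest.approx(1 / 100)

    def test_group_level_permutation_requires_balanced_blocks(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        gids = ["a"] * 4 + ["b"] * 3 + ["c"] * 3
        with pytest.raises(ValueError, match="equal sample counts"):
            permutation_test(X, y, 1, n_permutations=5, group_ids=gids, statistics=("R2",))

    def test_group_level_permutation_runs_on_balanced_blocks(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.repeat(rng.normal(size=4), 3)
        gids = np.repeat(list("abcd"), 3)
        out = permutation_test(X, y, 1, n_permutations=9, group_ids=gids, statistics=("R2",))
        assert 0 < out["p_R2"] <= 1


class TestVIPSelect:
    def test_recovers_informative_variables(self):
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            X, y = make_signal_dataset(r, n=35, p=55, n_informative=5, effect=3.0, noise=0.3)
            kept, _ = vip_select(X, y, 1, n_folds=7)
            hits += set(range(5)).issubset(set(kept.tolist()))
        assert hits >= 45

    def test_exchangeable_variables_left_unchanged(self, rng):
        latent = rng.normal(size=25)
        X = latent[:, None] + 0.2 * rng.normal(size=(25, 6))
        y = latent
        kept, trace = vip_select(X - X.mean(0), y - y.mean(), 1, n_folds=5)
        assert kept.size == 6  # symmetric VIPs ~= 1: nothing can be dropped to gain Q2

    def test_selected_subset_never_worse_than_full_model(self, rng):
        X, y = make_signal_dataset(rng, n=28, p=20, n_informative=3)
        kept, trace = vip_select(X, y, 1, n_folds=7)
        q2_full = trace[0]["q2"]
        q2_best = max(t["q2"] for t in trace)
        kept_q2 = [t["q2"] for t in trace if np.array_equal(t["kept"], kept)]
        assert kept_q2[0] == q2_best >= q2_full - 1e-9


class TestStabilitySelection:
    def test_dominant_variable_always_selected(self, rng):
        X, y = make_signal_dataset(rng, n=40, p=10, effect=10.0, noise=0.1)
        res = stability_selection(X, y, 1, n_subsets=50, seed=3)
        assert res.selection_frequency[0] == 1.0
        assert 0 in res.stable_set

    def test_noise_variables_below_informative(self):
        ok = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X, y = make_signal_dataset(r, n=40, p=10, effect=10.0, noise=0.1)
            res = stability_selection(X, y, 1, n_subsets=30, seed=seed)
            noise_mean = res.selection_frequency[1:].mean()
            ok += (noise_mean < 0.5) and (noise_mean < res.selection_frequency[0])
        assert ok >= 19

    def test_same_seed_identical(self, rng):
        X, y = make_signal_dataset(rng, n=30, p=8)
        a = stability_selection(X, y, 1, n_subsets=20, seed=7)
        b = stability_selection(X, y, 1, n_subsets=20, seed=7)
        np.testing.assert_array_equal(a.selection_frequency, b.selection_frequency)

    def test_bad_inclusion_probability_errors(self, rng):
        X, y = make_signal_dataset(rng)
        with pytest.raises(ValueError, match="inclusion_probability"):
            stability_selection(X, y, 1, inclusion_probability=1.0)


class TestValidateReport:
    def test_report_fields_and_q2_le_r2(self, rng):
        X, y = make_signal_dataset(rng, n=28, p=8)
        rep = validate(X, y, 2, n_permutations=19, seed=5)
        assert rep.q2 <= rep.r2 + 1e-9
        assert 0 < rep.permutation_p_r2 <= 1
        assert "Q2" in rep.summary()
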