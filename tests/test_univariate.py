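"""Mixed models, exact rank tests vs brute-force enumeration, FDR, fold changes."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arrestomix.simulate import simulate_linear_mixed
from arrestomix.univariate import (
    fdr_qvalues,
    fit_mixed_model,
    fold_changes,
    mann_whitney,
    wilcoxon_paired,
)


# --- independent brute-force oracles -------------------------------------


def wilcoxon_exact_oracle(d):
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    from scipy.stats import rankdata

    r = rankdata(np.abs(d))
    w_obs = r[d > 0].sum()
    n = len(d)
    total = w_obs_count = 0
    mu = r.sum() / 2
    dev = abs(w_obs - mu)
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(ri for ri, s in zip(r, signs) if s)
        total += 1
        if abs(w - mu) >= dev - 1e-12:
            w_obs_count += 1
    return min(w_obs, r.sum() - w_obs), w_obs_count / total


def mannwhitney_exact_oracle(a, b):
    """Two-sided U p by enumerating all C(n, n_a) group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)

    def u_of(idx):
        ga = pooled[list(idx)]
        gb = np.delete(pooled, list(idx))
        return sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)

    u_obs = u_of(range(na))
    mu = na * (n - na) / 2
    dev = abs(u_obs - mu)
    count = total = 0
    for idx in itertools.combinations(range(n), na):
        total += 1
        if abs(u_of(idx) - mu) >= dev - 1e-12:
            count += 1
    return u_obs, count / total


# --- mixed models ---------------------------------------------------------


class TestMixedModel:
    def test_zero_noise_exact_interpolation(self):
        df = simulate_linear_mixed(beta=(1, 2, 3, 4), sigma_b=0.0, sigma=0.0,
                                   n_animals_per_group=3, n_timepoints=4, seed=0)
        fit = fit_mixed_model(df, "sim", include_interaction=True)
        expected = {"Intercept": 1.0, "time": 2.0, "group": 3.0, "time:group": 4.0}
        for term, truth in expected.items():
            assert fit.coefficients[term][0] == pytest.approx(truth, abs=1e-6)

    def test_interaction_free_data_nested_fits_agree(self):
        df = simulate_linear_mixed(beta=(1, 2, 3, 0), sigma_b=0.5, sigma=0.3,
                                   n_animals_per_group=8, n_timepoints=8, seed=4)
        with_i = fit_mixed_model(df, "sim", include_interaction=True)
        without = fit_mixed_model(df, "sim", include_interaction=False)
        assert "time:group" not in without.coefficients
        se = with_i.standard_errors
        for term in ("time", "group"):
            assert abs(with_i.coefficients[term][0] - without.coefficients[term][0]) < 3 * se[term]

    def test_invariant_to_animal_relabeling_and_time_shift(self):
        df = simulate_linear_mixed(seed=7, n_animals_per_group=5, n_timepoints=6)
        base = fit_mixed_model(df, "sim", include_interaction=True)
        relabeled = df.copy()
        relabeled["animal_id"] = relabeled["animal_id"].map(lambda s: "z" + s[::-1])
        shifted = df.copy()
        shifted["minute"] = shifted["minute"] + 100
        fit_r = fit_mixed_model(relabeled, "sim", include_interaction=True)
        fit_s = fit_mixed_model(shifted, "sim", include_interaction=True)
        assert fit_r.coefficients["time"][0] == pytest.approx(base.coefficients["time"][0], abs=1e-6)
        assert fit_s.coefficients["time"][0] == pytest.approx(base.coefficients["time"][0], abs=1e-4)

    def test_one_group_errors(self):
        df = simulate_linear_mixed(seed=0, n_animals_per_group=4, n_timepoints=4)
        with pytest.raises(ValueError, match="2 groups"):
            fit_mixed_model(df[df["group"] == "ACA"], "sim")

    def test_summary_mentions_coding(self):
        df = simulate_linear_mixed(seed=1, n_animals_per_group=4, n_timepoints=5)
        fit = fit_mixed_model(df, "sim")
        assert "VFCA" in fit.group_coding and "reference" in fit.group_coding
        assert "random intercept" in fit.summary()


# --- rank tests -----------------------------------------------------------


class TestWilcoxon:
    def test_all_positive_differences_n5(self):
        _, p = wilcoxon_paired([1, 2, 3, 4, 5], [2, 4, 6, 9, 11])
        assert p == pytest.approx(2 / 32)

    def test_matches_enumeration_oracle(self):
        for seed in range(25):
            r = np.random.default_rng(seed)
            before = r.normal(size=10)
            after = before + r.normal(size=10)
            stat, p = wilcoxon_paired(before, after)
            stat_o, p_o = wilcoxon_exact_oracle(after - before)
            assert p == pytest.approx(p_o, abs=1e-12), f"seed {seed}"
            assert stat == pytest.approx(stat_o)

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_paired([1.0, 2.0], [1.0, 2.0])

    def test_symmetric_null_type_i_error(self):
        rejections = 0
        n_runs = 400
        for seed in range(n_runs):
            r = np.random.default_rng(seed)
            d = r.normal(size=12)
            _, p = wilcoxon_paired(np.zeros(12), d)
            rejections += p <= 0.05
        # binomial 95% band around alpha=0.05 (exact test is conservative)
        se = math.sqrt(0.05 * 0.95 / n_runs)
        assert rejections / n_runs <= 0.05 + 2 * se


class TestMannWhitney:
    def test_extreme_arrangement(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(2 / math.comb(6, 3))

    def test_identical_groups_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_matches_enumeration_oracle(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            a, b = r.normal(size=8), r.normal(size=7)
            u, p = mann_whitney(a, b)
            u_o, p_o = mannwhitney_exact_oracle(a, b)
            assert p == pytest.approx(p_o, abs=1e-12), f"seed {seed}"
            assert u == pytest.approx(u_o)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0])


# --- fold changes & FDR ---------------------------------------------------


def tiny_tidy(values_from, values_to):
    rows = []
    for i, (f, t) in enumerate(zip(values_from, values_to)):
        aid = f"a{i}"
        rows.append({"animal_id": aid, "group": "G", "phase": "p0", "minute": 0,
                     "metabolite": "m", "value": f})
        rows.append({"animal_id": aid, "group": "G", "phase": "p1", "minute": 0,
                     "metabolite": "m", "value": t})
    return pd.DataFrame(rows)


class TestFoldChanges:
    def test_relative_increase_definition(self):
        df = tiny_tidy([2.0], [6.0])
        fc = fold_changes(df, {"phase": "p0"}, {"phase": "p1"})
        assert fc.loc["m", "mean_fc"] == 2.0

    def test_no_change_is_zero(self):
        fc = fold_changes(tiny_tidy([3.0], [3.0]), {"phase": "p0"}, {"phase": "p1"})
        assert fc.loc["m", "mean_fc"] == 0.0

    def test_programmed_five_fold_increase(self):
        """Every animal exactly 5x: (5x - x)/x = 4 for all, so mean = 4 exactly."""
        base = [1.0, 2.0, 7.0]
        fc = fold_changes(tiny_tidy(base, [5 * b for b in base]),
                          {"phase": "p0"}, {"phase": "p1"})
        assert fc.loc["m", "mean_fc"] == 4.0
        assert fc.loc["m", "min_fc"] == fc.loc["m", "max_fc"] == 4.0

    def test_nonpositive_baseline_excluded_with_warning(self):
        df = tiny_tidy([0.0, 2.0], [1.0, 6.0])
        with pytest.warns(UserWarning, match="non-positive baseline"):
            fc = fold_changes(df, {"phase": "p0"}, {"phase": "p1"})
        assert fc.loc["m", "n_animals"] == 1


class TestFDR:
    def test_hand_worked_example(self):
        q = fdr_qvalues([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_single_p_unchanged(self):
        assert fdr_qvalues([0.2])[0] == 0.2

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(fdr_qvalues([0.3, 0.3, 0.3]), 0.3)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            fdr_qvalues([0.1, 0.0])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    def test_q_at_least_p_and_matches_statsmodels(self, ps):
        from statsmodels.stats.multitest import multipletests

        q = fdr_qvalues(ps)
        assert np.all(q >= np.asarray(ps) - 1e-15)
        assert np.all(q <= 1.0)
        _, q_sm, _, _ = multipletests(ps, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, atol=1e-12)
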