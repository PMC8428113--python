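"""Permutation inference: max-stat correction, LME contrast, SVR null,
power-variation test."""

import numpy as np
import pandas as pd
import pytest

from syncdecode.inference import (
    NullDistribution,
    impulse_effect_model,
    label_permutation_null,
    maxstat_correct,
    power_variation_test,
    svr_permutation_null,
)


def make_nulls(values_by_test):
    return {
        t: NullDistribution(statistic="accuracy", values=np.asarray(v))
        for t, v in values_by_test.items()
    }


class TestMaxstatCorrect:
    def test_observed_below_null_minimum_gives_p_one(self):
        nulls = make_nulls({"a": np.linspace(0.2, 0.4, 99), "b": np.linspace(0.2, 0.4, 99)})
        rep = maxstat_correct({"a": 0.1, "b": 0.05}, nulls)
        assert (rep.table["p"] == 1.0).all()
        assert not rep.table["significant"].any()

    def test_observed_above_null_maximum_gives_min_p(self):
        n_perm = 99
        nulls = make_nulls({"a": np.linspace(0.2, 0.4, n_perm)})
        rep = maxstat_correct({"a": 0.9}, nulls)
        assert rep.table["p"].iloc[0] == pytest.approx(1.0 / (n_perm + 1))

    def test_p_monotone_nonincreasing_in_observed(self):
        rng = np.random.default_rng(0)
        nulls = make_nulls({t: rng.random(200) for t in "abcd"})
        obs = {"a": 0.1, "b": 0.4, "c": 0.7, "d": 0.95}
        rep = maxstat_correct(obs, nulls)
        tab = rep.table.set_index("test")
        ordered = [tab.loc[t, "p"] for t in "abcd"]
        assert all(p1 >= p2 for p1, p2 in zip(ordered, ordered[1:]))

    def test_pooled_never_less_conservative_than_per_test(self):
        rng = np.random.default_rng(1)
        values = {t: rng.random(300) for t in "abcde"}
        obs = {t: rng.random() for t in "abcde"}
        rep = maxstat_correct(obs, make_nulls(values))
        for t in "abcde":
            per_test_p = (1 + np.sum(values[t] >= obs[t])) / (1 + 300)
            assert rep.table.set_index("test").loc[t, "p"] >= per_test_p

    def test_pooling_over_60_tests(self):
        """12 connections x 5 bands pool into a single 60-test family."""
        rng = np.random.default_rng(2)
        tests = [(f"conn{i}", f"band{j}") for i in range(12) for j in range(5)]
        nulls = make_nulls({t: rng.random(100) for t in tests})
        rep = maxstat_correct({t: 0.5 for t in tests}, nulls)
        assert rep.notes["n_tests"] == 60
        assert rep.pooled_null.size == 100

    def test_mismatched_n_perm_rejected(self):
        nulls = make_nulls({"a": np.zeros(100), "b": np.zeros(99)})
        with pytest.raises(ValueError, match="permutations"):
            maxstat_correct({"a": 0.5, "b": 0.5}, nulls)


class TestLabelPermutationNull:
    def test_same_seed_identical_null(self):
        y = np.tile(np.arange(6), 8)
        decode_fn = lambda perm: float(np.mean(perm == y))
        a = label_permutation_null(decode_fn, y, n_perm=50, seed=3)
        b = label_permutation_null(decode_fn, y, n_perm=50, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_permutations_unique(self):
        y = np.tile(np.arange(6), 4)
        seen = []
        decode_fn = lambda perm: seen.append(perm.copy()) or 0.0
        label_permutation_null(decode_fn, y, n_perm=40, seed=4)
        keys = {p.tobytes() for p in seen}
        assert len(keys) == 40

    def test_too_many_permutations_rejected(self):
        y = np.array([0, 0, 1])  # only 3 distinct arrangements
        with pytest.raises(ValueError, match="distinct"):
            label_permutation_null(lambda p: 0.0, y, n_perm=10, seed=0)

    def test_null_mean_near_chance_and_sd_matches_binomial_oracle(self):
        """Two-class toy with a fixed split: the null accuracy is a mean of
        Bernoulli outcomes, so its SD should approach sqrt(p(1-p)/n_test)."""
        from syncdecode.decoding import DecoderSpec, accuracy_over_splits, make_splits

        rng = np.random.default_rng(5)
        n_per = 16
        X = rng.standard_normal((2 * n_per, 3))
        y = np.repeat([0, 1], n_per)
        spec = DecoderSpec(n_repeats=1, seed=5, train_fraction=0.5)
        splits = make_splits(X, y, spec)
        decode_fn = lambda perm: accuracy_over_splits(X, y, splits, spec,
                                                      train_labels=perm)
        null = label_permutation_null(decode_fn, y, n_perm=800, seed=6)
        n_test = splits[0][1].size
        oracle_sd = np.sqrt(0.25 / n_test)
        assert abs(null.values.mean() - 0.5) < 3 * oracle_sd / np.sqrt(800) + 0.02
        assert null.values.std() == pytest.approx(oracle_sd, rel=0.2)


class TestImpulseEffectModel:
    def _table(self, accs, bands=(5.0, 10.0, 21.5, 45.5, 90.5)):
        rows = []
        i = 0
        n_subj = accs.shape[0]
        for s in range(n_subj):
            for bi, cf in enumerate(bands):
                for imp in (0, 1):
                    rows.append({"subject": s, "band_center": cf,
                                 "impulse": imp, "accuracy": accs[s, bi, imp]})
        return pd.DataFrame(rows)

    def test_constant_chance_accuracy_gives_zero_effect(self):
        accs = np.full((6, 5, 2), 1 / 6)
        res = impulse_effect_model(self._table(accs))
        assert res.estimates["impulse"] == pytest.approx(0.0, abs=1e-10)

    def test_reduces_to_ols_without_random_intercept(self):
        rng = np.random.default_rng(7)
        accs = 1 / 6 + 0.02 * rng.standard_normal((8, 5, 2))
        table = self._table(accs)
        res = impulse_effect_model(table, random_intercept=False)
        # independent least-squares oracle
        X = np.column_stack([
            np.ones(len(table)),
            table["impulse"].astype(float),
            np.log2(table["band_center"]),
        ])
        yv = table["accuracy"].to_numpy() - 1 / 6
        beta = np.linalg.lstsq(X, yv, rcond=None)[0]
        assert res.estimates["impulse"] == pytest.approx(beta[1], abs=1e-6)
        assert res.estimates["log2_cf"] == pytest.approx(beta[2], abs=1e-6)

    def test_recovers_planted_impulse_effect(self):
        """Known beta = 0.05 with subject intercept SD 0.02: the estimate's
        95% CI covers the truth in >= 93% of simulations."""
        from scipy import stats

        beta, intercept_sd, noise_sd = 0.05, 0.02, 0.02
        n_sims, covered = 200, 0
        for sim in range(n_sims):
            rng = np.random.default_rng(1000 + sim)
            subj_eff = rng.normal(0, intercept_sd, 10)
            accs = np.empty((10, 5, 2))
            for s in range(10):
                for bi in range(5):
                    base = 1 / 6 + subj_eff[s]
                    accs[s, bi, 0] = base + rng.normal(0, noise_sd)
                    accs[s, bi, 1] = base + beta + rng.normal(0, noise_sd)
            res = impulse_effect_model(self._table(np.clip(accs, 0, 1)))
            se = res.estimates["impulse"] / res.tvalues["impulse"]
            half = stats.t.ppf(0.975, res.dof) * se
            covered += abs(res.estimates["impulse"] - beta) <= half
        assert covered / n_sims >= 0.93

    def test_null_t_statistic_calibrated(self):
        """With identical with/without-impulse accuracy distributions, |t| < 2
        about as often as the nominal t distribution predicts."""
        big_t = 0
        n_sims = 100
        for sim in range(n_sims):
            rng = np.random.default_rng(5000 + sim)
            accs = 1 / 6 + 0.02 * rng.standard_normal((8, 5, 2))
            res = impulse_effect_model(self._table(accs))
            big_t += abs(res.tvalues["impulse"]) > 2.0
        assert big_t / n_sims < 0.15  # nominal ~0.05 at these dof

    def test_fewer_than_two_subjects_rejected(self):
        accs = np.full((1, 5, 2), 0.2)
        with pytest.raises(ValueError, match="2 subjects"):
            impulse_effect_model(self._table(accs))

    def test_bonferroni_adjustment(self):
        rng = np.random.default_rng(8)
        accs = 1 / 6 + 0.02 * rng.standard_normal((6, 5, 2))
        res = impulse_effect_model(self._table(accs), n_comparisons=13)
        for term in res.pvalues:
            expected = min(1.0, 13 * res.raw_pvalues[term])
            assert res.pvalues[term] == pytest.approx(expected)


class TestSvrPermutationNull:
    def _setup(self, seed, signal=False):
        from syncdecode.decoding import SvrFoldCache

        rng = np.random.default_rng(seed)
        ns, nq, T = 10, 4, 6
        b = np.clip(rng.normal(0.84, 0.1, ns), 0, 1)
        caches = {}
        for conn in ("c1", "c2"):
            for w in ("early", "late"):
                X = rng.standard_normal((ns, nq, T))
                if signal:
                    X[:, :, 0] = b[:, None] * 10
                caches[(conn, w)] = SvrFoldCache(X)
        return b, caches

    def test_same_seed_identical_null(self):
        b, caches = self._setup(0)
        fn = lambda test, pb: caches[test].rmse(b, pb)
        n1, _ = svr_permutation_null(fn, b, list(caches), n_perm=100, seed=9)
        n2, _ = svr_permutation_null(fn, b, list(caches), n_perm=100, seed=9)
        np.testing.assert_array_equal(n1.values, n2.values)

    def test_predictable_behavior_significant_in_both_windows(self):
        b, caches = self._setup(1, signal=True)
        fn = lambda test, pb: caches[test].rmse(b, pb)
        _, rep = svr_permutation_null(fn, b, list(caches), n_perm=150, seed=10)
        assert rep.table["significant"].all()

    def test_small_n_perm_warns(self):
        b, caches = self._setup(2)
        fn = lambda test, pb: caches[test].rmse(b, pb)
        with pytest.warns(UserWarning, match="unstable"):
            svr_permutation_null(fn, b, list(caches), n_perm=50, seed=11)


class TestPowerVariationTest:
    def test_zero_mean_changes_rarely_flagged(self):
        flagged = 0
        for sim in range(60):
            rng = np.random.default_rng(100 + sim)
            changes = 0.05 * rng.standard_normal((10, 5, 2))
            rep = power_variation_test(changes, n_perm=200, seed=sim)
            flagged += rep.table["significant"].any()
        assert flagged / 60 <= 0.12  # nominal FWER 0.05 + slack

    def test_large_common_change_recovered_specifically(self):
        hits = others = 0
        for sim in range(20):
            rng = np.random.default_rng(200 + sim)
            changes = 0.05 * rng.standard_normal((10, 5, 2))
            changes[:, 2, 0] += 0.5
            rep = power_variation_test(changes, n_perm=200, seed=sim)
            tab = rep.table.set_index("test")
            hits += bool(tab.loc[[("band2", "win0")], "significant"].iloc[0])
            others += int(tab.drop(index=[("band2", "win0")])["significant"].sum())
        assert hits >= 19
        assert others <= 2

    def test_degenerate_constant_input_flagged_with_p_one(self):
        rep = power_variation_test(np.zeros((5, 3, 1)), n_perm=100, seed=0)
        assert (rep.table["p"] == 1.0).all()
        assert rep.table["degenerate"].all()

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            power_variation_test(np.zeros((1, 3, 2)))
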