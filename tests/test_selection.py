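from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from adnexrad.selection import (FrozenScaler, MWUBHSelector, bh_adjust,
                                mrmr_select, mwu_screen, prune_correlated,
                                rfe_select, scale_features)


def exhaustive_mwu_p(a, b):
    """Two-tailed permutation p for the rank-sum statistic (no ties)."""
    pooled = np.concatenate([a, b])
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in a)
    n = len(pooled)
    stats = [sum(sorted(ranks.values())[i] for i in comb)
             for comb in combinations(range(n), len(a))]
    stats = []
    all_ranks = sorted(ranks[v] for v in pooled)
    for comb in combinations(all_ranks, len(a)):
        stats.append(sum(comb))
    mean = len(a) * (n + 1) / 2
    extreme = sum(abs(s - mean) >= abs(obs - mean) - 1e-12 for s in stats)
    return extreme / len(stats)


class TestMWUScreen:
    def test_exact_p_on_separated_triplets(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        y = [0, 0, 0, 1, 1, 1]
        p = mwu_screen(X, y)["f"]
        assert p == pytest.approx(0.1, abs=1e-12)
        assert p == pytest.approx(exhaustive_mwu_p([1, 2, 3], [4, 5, 6]), abs=1e-12)

    def test_exact_matches_permutation_oracle(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(loc=0.8, size=6)
        X = pd.DataFrame({"f": np.concatenate([a, b])})
        y = [0] * 5 + [1] * 6
        assert mwu_screen(X, y)["f"] == pytest.approx(exhaustive_mwu_p(a, b),
                                                      abs=1e-12)

    def test_label_swap_symmetry(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = rng.integers(0, 2, size=40)
        while len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
            y = rng.integers(0, 2, size=40)
        p1 = mwu_screen(X, y)
        p2 = mwu_screen(X, 1 - y)
        for k in p1:
            assert p1[k] == pytest.approx(p2[k], abs=1e-12)

    def test_null_p_values_roughly_uniform(self, rng):
        from scipy.stats import kstest

        X = pd.DataFrame(rng.normal(size=(1000, 74)))
        X.columns = [f"f{i}" for i in range(74)]
        y = np.array([0] * 500 + [1] * 500)
        p = np.array(list(mwu_screen(X, y).values()))
        assert kstest(p, "uniform").pvalue > 0.01

    def test_single_class_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            mwu_screen(X, [1, 1, 1])


class TestBHAdjust:
    def test_stepwise_thresholds_hand_example(self):
        adj, sig = bh_adjust({"a": 0.01, "b": 0.02, "c": 0.04}, alpha=0.05)
        assert set(sig) == {"a", "b", "c"}

    def test_all_ones(self):
        adj, sig = bh_adjust({"a": 1.0, "b": 1.0}, alpha=0.05)
        assert sig == [] and all(v == 1.0 for v in adj.values())

    def test_single_p_is_identity(self):
        adj, _ = bh_adjust({"only": 0.037})
        assert adj["only"] == pytest.approx(0.037, abs=1e-15)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=200)
        adj, _ = bh_adjust(p)
        assert (np.asarray(adj) >= p - 1e-15).all()

    def test_matches_reference_step_up_on_random_vectors(self, rng):
        """1000 random p-vectors against the statsmodels fdr_bh reference."""
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            adj, sig = bh_adjust(p, alpha=0.05)
            ref_rej, ref_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert np.max(np.abs(np.asarray(adj) - ref_adj)) < 1e-12
            assert set(sig) == set(np.flatnonzero(ref_rej))


class TestPruneCorrelated:
    def test_lower_p_wins_in_a_correlated_pair(self, rng):
        f1 = rng.normal(size=100)
        f2 = f1 + 0.1 * rng.normal(size=100)  # r ~ 0.99
        X = pd.DataFrame({"f1": f1, "f2": f2})
        kept = prune_correlated(X, ["f1", "f2"], {"f1": 0.001, "f2": 0.01})
        assert kept == ["f1"]

    def test_uncorrelated_features_all_kept_in_p_order(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
        kept = prune_correlated(X, ["a", "b", "c"], {"a": 0.3, "b": 0.1, "c": 0.2})
        assert kept == ["b", "c", "a"]

    def test_correlation_chain_matches_greedy_oracle(self, rng):
        z = rng.normal(size=300)
        X = pd.DataFrame({
            "f1": z,
            "f2": z + 0.5 * rng.normal(size=300),
            "f3": z + 1.2 * rng.normal(size=300),
            "f4": rng.normal(size=300),
            "f5": -z + 0.4 * rng.normal(size=300),  # anti-correlated duplicate
        })
        p = {"f1": 0.001, "f2": 0.002, "f3": 0.003, "f4": 0.004, "f5": 0.005}
        kept = prune_correlated(X, list(X.columns), p, threshold=0.6)
        # independent replay of the stated greedy rule
        expected = []
        for f in sorted(X.columns, key=p.get):
            if all(abs(np.corrcoef(X[f], X[g])[0, 1]) <= 0.6 for g in expected):
                expected.append(f)
        assert kept == expected

    def test_column_permutation_invariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(150, 4)), columns=list("abcd"))
        p = {"a": 0.04, "b": 0.01, "c": 0.02, "d": 0.03}
        k1 = prune_correlated(X, list("abcd"), p)
        k2 = prune_correlated(X[list("dcba")], list("dcba"), p)
        assert k1 == k2


class TestScaleFeatures:
    def test_frozen_statistics_hand_example(self):
        train = pd.DataFrame({"f": [2.0, 4.0, 6.0]})
        val = pd.DataFrame({"f": [8.0]})
        scaled, scaler = scale_features(train, val)
        assert scaled["f"].iloc[0] == pytest.approx(2.0)

    def test_training_set_scales_to_mean0_sd1(self, rng):
        train = pd.DataFrame(rng.normal(5, 3, size=(50, 4)), columns=list("abcd"))
        scaled, _ = scale_features(train)
        assert np.allclose(scaled.mean(), 0.0, atol=1e-12)
        assert np.allclose(scaled.std(ddof=1), 1.0, atol=1e-12)

    def test_zero_sd_feature_named_in_error(self):
        train = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            scale_features(train)

    def test_nan_passthrough_for_missing_ca125(self):
        train = pd.DataFrame({"ca125": [10.0, np.nan, 30.0, 20.0]})
        scaled, scaler = scale_features(train)
        assert np.isnan(scaled["ca125"].iloc[1])
        assert scaler.means["ca125"] == pytest.approx(20.0)


class TestAlternateSelectors:
    def _toy(self, rng, n=120):
        y = rng.integers(0, 2, size=n)
        signal = y + 0.3 * rng.normal(size=n)
        X = pd.DataFrame({
            "signal": signal,
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
            "dup": signal + 0.05 * rng.normal(size=n),
        })
        return X, y

    def test_k_equals_n_features_keeps_all(self, rng):
        X, y = self._toy(rng)
        assert set(mrmr_select(X, y, k=4)) == set(X.columns)
        from sklearn.linear_model import LogisticRegression
        assert set(rfe_select(LogisticRegression(max_iter=1000), X, y, k=4)) \
            == set(X.columns)

    def test_perfect_separator_beats_pure_noise(self, rng):
        n = 120
        y = rng.integers(0, 2, size=n)
        X = pd.DataFrame({"noise1": rng.normal(size=n),
                          "separator": y.astype(float),
                          "noise2": rng.normal(size=n)})
        assert mrmr_select(X, y, k=1) == ["separator"]
        from sklearn.linear_model import LogisticRegression
        assert rfe_select(LogisticRegression(max_iter=1000), X, y, k=1) \
            == ["separator"]

    def test_mrmr_matches_greedy_trace_oracle(self, rng):
        X, y = self._toy(rng, n=200)
        X["noise3"] = rng.normal(size=200)
        X["dup2"] = X["signal"] + 0.05 * rng.normal(size=200)
        got = mrmr_select(X, y, k=4)
        # replay the greedy objective independently
        yf = y.astype(float)
        rel = {c: abs(np.corrcoef(X[c], yf)[0, 1]) for c in X.columns}
        chosen = []
        remaining = list(X.columns)
        while len(chosen) < 4:
            def score(c):
                red = (np.mean([abs(np.corrcoef(X[c], X[s])[0, 1])
                                for s in chosen]) if chosen else 0.0)
                return rel[c] - red
            best = max(remaining, key=lambda c: (score(c), -remaining.index(c)))
            chosen.append(best)
            remaining.remove(best)
        assert got == chosen

    def test_k_out_of_range_rejected(self, rng):
        X, y = self._toy(rng)
        with pytest.raises(ValueError):
            mrmr_select(X, y, k=0)
        with pytest.raises(ValueError):
            mrmr_select(X, y, k=5)


class TestMWUBHSelector:
    def test_fitted_attributes_nest_correctly(self, medium_data):
        _, X, cl = medium_data
        sel = MWUBHSelector().fit(X, cl["malignant"])
        assert set(sel.kept_) <= set(sel.significant_) <= set(X.columns)
        for f in sel.significant_:
            assert sel.adjusted_p_[f] >= sel.p_values_[f] - 1e-15
        # kept features are pairwise below the redundancy threshold
        for i, a in enumerate(sel.kept_):
            for b in sel.kept_[i + 1:]:
                assert abs(np.corrcoef(X[a], X[b])[0, 1]) <= 0.6 + 1e-12

    def test_transform_selects_kept_columns(self, medium_data):
        _, X, cl = medium_data
        sel = MWUBHSelector().fit(X, cl["malignant"])
        assert list(sel.transform(X).columns) == sel.kept_

    def test_alpha_one_makes_everything_significant(self, medium_data):
        _, X, cl = medium_data
        sel = MWUBHSelector(alpha=1.0).fit(X, cl["malignant"])
        assert len(sel.significant_) == X.shape[1]
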