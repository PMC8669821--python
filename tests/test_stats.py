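"""Statistics layer: grouping, effect sizes, logistic adjustment,
selection, LOSO classification and lab-home comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mobifof.stats import (adjusted_logistic_p, assign_fof_group,
                           backward_eliminate, effect_band, effect_size_r,
                           home_lab_ratio, loso_classify, paired_lab_home,
                           rho_band, screen_features, split_feature_sets)


def oracle_effect_size(a, b):
    """Independent oracle: Mann-Whitney U by exhaustive pair counting."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    u = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)
    n1, n2 = len(a), len(b)
    n = n1 + n2
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts**3 - counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie)
    if var <= 0:
        return 0.0
    return (u - n1 * n2 / 2.0) / np.sqrt(var) / np.sqrt(n)


class TestGrouping:
    @pytest.mark.parametrize("fes,expected", [
        (20, "FOF+"), (19, "FOF-"), (64, "FOF+"), (16, "FOF-")])
    def test_threshold(self, fes, expected):
        assert assign_fof_group(fes) == expected

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            assign_fof_group(-1)


class TestEffectSize:
    def test_identical_groups_zero(self):
        a = [1.0, 2.0, 3.0]
        assert effect_size_r(a, list(a)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n1, n2 = rng.integers(2, 7), rng.integers(2, 7)
            a = rng.integers(0, 8, n1).astype(float)  # ties likely
            b = rng.integers(0, 8, n2).astype(float)
            if np.all(np.concatenate([a, b]) == a[0]):
                continue
            assert effect_size_r(a, b) == pytest.approx(
                oracle_effect_size(a, b), abs=1e-10)

    def test_sign_convention_positive_when_fof_pos_larger(self):
        r = effect_size_r([10, 11, 12], [1, 2, 3, 4])
        assert r > 0.5

    def test_all_tied_warns_zero(self):
        with pytest.warns(UserWarning):
            assert effect_size_r([1.0, 1.0], [1.0, 1.0, 1.0]) == 0.0

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=10),
           st.lists(st.floats(-100, 100), min_size=2, max_size=10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_and_antisymmetric(self, a, b):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = effect_size_r(a, b)
            assert -1.0 <= r <= 1.0
            assert r == pytest.approx(-effect_size_r(b, a), abs=1e-12)

    @pytest.mark.parametrize("r,band", [
        (0.05, "small"), (0.35, "medium"), (-0.61, "large"), (0.3, "medium")])
    def test_bands(self, r, band):
        assert effect_band(r) == band


class TestAdjustedLogistic:
    def _cohort(self, rng, effect=0.0, n=26):
        y = np.array([1] * 9 + [0] * (n - 9))
        rng.shuffle(y)
        gender = rng.integers(0, 2, n)
        updrs = rng.normal(25, 6, n)
        feat = rng.normal(0, 1, n) + effect * y
        labels = ["FOF+" if v else "FOF-" for v in y]
        return feat, gender, updrs, labels

    def test_strong_effect_detected_with_power(self):
        rng = np.random.default_rng(1)
        hits = total = 0
        for _ in range(200):
            feat, g, u, lab = self._cohort(rng, effect=2.0)
            res = adjusted_logistic_p(feat, g, u, lab)
            if res.p_value is not None:
                total += 1
                hits += res.p_value < 0.05
        assert hits / total >= 0.70

    def test_collinear_feature_flagged(self):
        rng = np.random.default_rng(2)
        feat, g, u, lab = self._cohort(rng)
        res = adjusted_logistic_p(u.copy(), g, u, lab)
        assert res.flag == "collinear"

    def test_separation_flagged_not_silent(self):
        rng = np.random.default_rng(3)
        feat, g, u, lab = self._cohort(rng)
        sep = np.array([1.0 if l == "FOF+" else 0.0 for l in lab])
        res = adjusted_logistic_p(sep, g, u, lab)
        assert res.p_value is None and res.flag is not None

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            adjusted_logistic_p([1.0] * 5, [0] * 5, [20] * 5, ["FOF+"] * 5)


def _make_cohort(rng, n_pos=9, n_neg=17, predictive=False):
    n = n_pos + n_neg
    y = np.array([1] * n_pos + [0] * n_neg)
    df = pd.DataFrame({"fof_group": ["FOF+" if v else "FOF-" for v in y]})
    df["T_TUG"] = rng.normal(18, 2, n) + (3.0 * y if predictive else 0.0)
    df["V_ALL_P50"] = rng.normal(0.85, 0.1, n)
    df["omega_H_P50"] = rng.normal(62, 5, n)
    return df


class TestLOSO:
    def test_separable_cohort_classified(self):
        rng = np.random.default_rng(0)
        df = _make_cohort(rng)
        df["T_TUG"] = 18.0 + 5.0 * (df["fof_group"] == "FOF+") + rng.normal(0, 0.1, len(df))
        rep = loso_classify(df, ["T_TUG"], seed=0)
        assert rep.accuracy >= 95.0
        assert rep.auc >= 0.95

    def test_confusion_counts_sum_to_n(self):
        rng = np.random.default_rng(1)
        df = _make_cohort(rng)
        rep = loso_classify(df, ["T_TUG", "V_ALL_P50"], seed=0)
        assert len(rep.y_pred) == len(df)
        assert 0 <= rep.accuracy <= 100

    def test_too_small_class_rejected(self):
        rng = np.random.default_rng(2)
        df = _make_cohort(rng, n_pos=1, n_neg=10)
        with pytest.raises(ValueError):
            loso_classify(df, ["T_TUG"], seed=0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        df = _make_cohort(rng, predictive=True)
        a = loso_classify(df, ["T_TUG", "V_ALL_P50"], seed=5)
        b = loso_classify(df, ["T_TUG", "V_ALL_P50"], seed=5)
        np.testing.assert_array_equal(a.y_proba, b.y_proba)
        assert a.auc == b.auc


class TestSelection:
    def test_screen_threshold(self):
        es = pd.DataFrame({"feature": ["a", "b", "c"],
                           "r": [0.15, -0.25, 0.61]})
        assert screen_features(es) == ["b", "c"]

    def test_elimination_keeps_predictive_feature(self):
        rng = np.random.default_rng(4)
        n = 26
        y = np.array([1] * 9 + [0] * 17)
        df = pd.DataFrame({"fof_group": ["FOF+" if v else "FOF-" for v in y]})
        df["T_TUG"] = y * 4.0 + rng.normal(0, 0.3, n)  # near-perfect
        for j, name in enumerate(["V_ALL_P50", "omega_H_P50", "P_H_P50"]):
            df[name] = rng.normal(0, 1, n)
        kept = backward_eliminate(df, ["T_TUG", "V_ALL_P50", "omega_H_P50",
                                       "P_H_P50"], seed=0)
        assert "T_TUG" in kept

    def test_split_partition(self):
        f1 = ["T_TUG", "P_TUG", "V_ALL_P50", "omega_H_P50"]
        f2, f3 = split_feature_sets(f1)
        assert f2 == ["T_TUG", "P_TUG"]
        assert f3 == ["V_ALL_P50", "omega_H_P50"]
        assert set(f2) | set(f3) == set(f1) and not set(f2) & set(f3)

    def test_untagged_feature_rejected(self):
        with pytest.raises(ValueError):
            split_feature_sets(["not_a_feature"])

    def test_all_lab_warns_empty_home_set(self):
        with pytest.warns(UserWarning):
            f2, f3 = split_feature_sets(["T_TUG", "P_TUG"])
        assert f3 == []


class TestPairedLabHome:
    def _paired_cohort(self, rng, n=17, shift=0.3, noise=0.05):
        lab = rng.normal(1.1, 0.15, n)
        home = lab + rng.normal(shift, noise, n)
        return pd.DataFrame({"fof_group": ["FOF-"] * n,
                             "V_TUG_avg": lab, "V_ALL_P50": home})

    def test_shift_detected_with_power(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(200):
            df = self._paired_cohort(rng)
            res = paired_lab_home(df, "V_TUG_avg", "V_ALL_P50", "FOF-")
            hits += res.signed_rank_p < 0.05
        assert hits / 200 >= 0.90

    def test_identical_features_flagged(self):
        rng = np.random.default_rng(1)
        df = self._paired_cohort(rng, shift=0.0, noise=0.0)
        res = paired_lab_home(df, "V_TUG_avg", "V_ALL_P50", "FOF-")
        assert res.flag == "all-differences-zero"
        assert res.rho == pytest.approx(1.0)

    @pytest.mark.parametrize("rho,band", [
        (0.70, "moderate"), (0.71, "high"), (0.49, "low"), (0.5, "moderate")])
    def test_rho_bands(self, rho, band):
        assert rho_band(rho) == band


class TestRatios:
    def test_arithmetic(self):
        assert home_lab_ratio(1.17, 1.01) == pytest.approx(1.17 / 1.01)
        assert home_lab_ratio(2.0, 2.0) == 1.0

    def test_nonpositive_lab_rejected(self):
        with pytest.raises(ValueError):
            home_lab_ratio(1.0, 0.0)

    def test_ratio_group_comparison_reuses_rank_oracle(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0.9, 1.4, 9)
        neg = rng.uniform(0.6, 1.1, 17)
        assert effect_size_r(pos, neg) == pytest.approx(
            oracle_effect_size(pos, neg), abs=1e-10)
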