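from math import comb

import numpy as np
import pandas as pd
import pytest

from mendriver.phenotype import (
    DelegatedPhenotype,
    ablate_phenotypes,
    delegated_phenotype,
    digitize,
    filter_and_impute,
    rotation_angle,
)


def _random_table(rng, n=40, n_vars=5, signal=1.5):
    d = rng.random(n) < 0.5
    if d.all() or not d.any():
        d[0] = ~d[0]
    cols = {"disease": np.where(d, "Y", "N")}
    for i in range(n_vars):
        cols[f"v{i}"] = signal * d * (i % 2 == 0) + rng.normal(size=n)
    return pd.DataFrame(cols, index=[f"s{j}" for j in range(n)])


class TestDigitize:
    def test_two_level_categorical_coding(self):
        t = pd.DataFrame(
            {"disease": ["Y", "N", "N"], "sex": ["M", "F", "F"]}, index=list("abc")
        )
        Z, labels = digitize(t, "disease")
        # sorted categories F -> 0, M -> 1, then standardized
        raw = np.array([1.0, 0.0, 0.0])
        expected = (raw - raw.mean()) / raw.std()
        assert np.allclose(Z["sex"].to_numpy(), expected)
        assert list(labels) == ["Y", "N", "N"]

    def test_numeric_column_standardized_only(self):
        t = pd.DataFrame(
            {"disease": ["Y", "N", "Y", "N"], "age": [10.0, 20.0, 30.0, 40.0]}
        )
        Z, _ = digitize(t, "disease")
        x = t["age"].to_numpy()
        assert np.allclose(Z["age"], (x - x.mean()) / x.std())

    def test_constant_column_dropped_with_warning(self):
        t = pd.DataFrame({"disease": ["Y", "N", "Y"], "site": ["A", "A", "A"]})
        with pytest.warns(UserWarning, match="constant"):
            Z, _ = digitize(t, "disease")
        assert "site" not in Z.columns

    def test_disease_included_or_excluded(self):
        t = _random_table(np.random.default_rng(0))
        Z_in, _ = digitize(t, "disease", include_disease=True)
        Z_out, _ = digitize(t, "disease", include_disease=False)
        assert "disease" in Z_in.columns and "disease" not in Z_out.columns


class TestFilterAndImpute:
    def test_variable_over_one_third_missing_dropped(self):
        n = 30
        t = pd.DataFrame(
            {
                "disease": ["Y", "N"] * 15,
                "mostly_missing": [np.nan] * 12 + [1.0] * 18,  # 40% missing
                "ok": np.arange(n, dtype=float),
            }
        )
        out = filter_and_impute(t, "disease", max_missing_frac=1 / 3)
        assert "mostly_missing" not in out.columns and "ok" in out.columns

    def test_exactly_one_third_kept(self):
        t = pd.DataFrame(
            {"disease": ["Y", "N", "Y"], "v": [1.0, np.nan, 3.0]}
        )
        out = filter_and_impute(t, "disease", max_missing_frac=1 / 3)
        assert "v" in out.columns

    def test_median_and_mode_imputation(self):
        t = pd.DataFrame(
            {
                "disease": ["Y", "N", "Y"],
                "num": [1.0, np.nan, 3.0],
                "cat": ["a", "b", None],
            }
        )
        out = filter_and_impute(t, "disease", max_missing_frac=0.5)
        assert out["num"].iloc[1] == 2.0
        assert out["cat"].iloc[2] == "a"  # smallest mode on tie

    def test_no_missing_unchanged(self):
        t = _random_table(np.random.default_rng(1))
        pd.testing.assert_frame_equal(filter_and_impute(t, "disease"), t)

    def test_missing_disease_label_raises(self):
        t = pd.DataFrame({"disease": ["Y", None, "N"], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="disease"):
            filter_and_impute(t, "disease")


class TestRotation:
    def test_separation_along_pc1_gives_theta_zero(self):
        x = np.array([-1.0, -1.0, 1.0, 1.0])
        y = np.zeros(4)
        d = np.array([True, True, False, False])  # Y at x<0, N at x>0
        assert rotation_angle(x, y, d) == pytest.approx(0.0)

    def test_separation_along_pc2_gives_pi_over_two(self):
        x = np.zeros(4)
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        d = np.array([True, True, False, False])
        assert rotation_angle(x, y, d) == pytest.approx(np.pi / 2)

    def test_indistinguishable_groups_raise(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        d = np.array([True, True, False, False])
        with pytest.raises(ValueError, match="indistinguishable"):
            rotation_angle(x, y, d)

    @pytest.mark.parametrize("seed", range(20))
    def test_grid_oracle(self, seed):
        """The returned angle attains the global maximum of f over a dense grid."""
        rng = np.random.default_rng(seed)
        n = 30
        x = rng.normal(scale=rng.uniform(0.5, 3.0), size=n)
        y = rng.normal(scale=rng.uniform(0.5, 3.0), size=n)
        d = rng.random(n) < 0.5
        if d.all() or not d.any():
            d[0] = ~d[0]
        theta = rotation_angle(x, y, d)

        def f(t):
            proj = x * np.cos(t) + y * np.sin(t)
            return proj[~d].sum() - proj[d].sum()

        grid = np.linspace(-np.pi, np.pi, 3600, endpoint=False)
        assert f(theta) >= max(f(t) for t in grid) - 1e-9
        # local-maximum check
        assert f(theta) >= f(theta + 1e-3) and f(theta) >= f(theta - 1e-3)


class TestDelegatedPhenotype:
    def test_equivariance_under_label_swap(self, rng):
        t = _random_table(rng)
        Z, labels = digitize(t, "disease")
        res = delegated_phenotype(Z, labels)
        swapped = labels.map({"Y": "N", "N": "Y"})
        # swap the included disease column too, for an exact symmetry
        Z2 = Z.copy()
        Z2["disease"] = -Z2["disease"]
        res2 = delegated_phenotype(Z2, swapped)
        dtheta = (res2.theta - res.theta) % (2 * np.pi)
        assert dtheta == pytest.approx(np.pi, abs=1e-8)
        assert np.allclose(res2.scores, -res.scores, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_correlation_dominates_single_axes(self, seed):
        rng = np.random.default_rng(seed)
        t = _random_table(rng, n=60)
        Z, labels = digitize(t, "disease")
        res = delegated_phenotype(Z, labels)
        d = (labels == "Y").astype(float)
        r_rot = abs(np.corrcoef(res.scores, d)[0, 1])
        r_x = abs(np.corrcoef(res.pc_scores["PC1"], d)[0, 1])
        r_y = abs(np.corrcoef(res.pc_scores["PC2"], d)[0, 1])
        assert r_rot >= max(r_x, r_y) - 1e-10

    def test_objective_evaluates_f(self, rng):
        t = _random_table(rng)
        Z, labels = digitize(t, "disease")
        res = delegated_phenotype(Z, labels)
        assert res.objective(res.theta) >= res.objective(res.theta + 0.3)

    def test_estimator_transform_matches_fit_scores(self, rng):
        t = _random_table(rng)
        dp = DelegatedPhenotype(disease_column="disease").fit(t)
        assert np.allclose(dp.transform(t), dp.scores_, atol=1e-8)
        assert -np.pi < dp.theta_ <= np.pi

    def test_requires_two_variables(self):
        t = pd.DataFrame({"disease": ["Y", "N", "Y", "N"]})
        with pytest.raises(ValueError):
            DelegatedPhenotype(disease_column="disease", include_disease=True).fit(t)


class TestAblation:
    def test_zero_removal_matches_unablated(self, rng):
        t = _random_table(rng)
        dp = DelegatedPhenotype(disease_column="disease").fit(t)
        e = rng.normal(size=len(t))
        out = ablate_phenotypes(t, "disease", 0, [e])
        assert len(out) == 1
        expected = abs(np.corrcoef(dp.scores_, e)[0, 1])
        assert out["abs_corr"].iloc[0] == pytest.approx(expected)

    def test_combination_count(self, rng):
        t = _random_table(rng, n_vars=5)
        e = rng.normal(size=len(t))
        out = ablate_phenotypes(t, "disease", 2, [e], max_combinations=1000)
        assert len(out) == comb(5, 2)

    def test_cap_on_combinations(self, rng):
        t = _random_table(rng, n_vars=8)
        e = rng.normal(size=len(t))
        out = ablate_phenotypes(t, "disease", 3, [e], max_combinations=10)
        assert len(out) == 10

    def test_removing_pure_noise_variable_barely_moves_correlation(self):
        rng = np.random.default_rng(3)
        n = 200
        d = np.repeat([True, False], n // 2)
        t = pd.DataFrame(
            {
                "disease": np.where(d, "Y", "N"),
                "a": 2.0 * d + 0.3 * rng.normal(size=n),
                "b": 2.0 * d + 0.3 * rng.normal(size=n),
                "c": -2.0 * d + 0.3 * rng.normal(size=n),
                "noise": 0.2 * rng.normal(size=n),
            },
            index=[f"s{j}" for j in range(n)],
        )
        eigen = 1.0 * d + 0.2 * rng.normal(size=n)
        baseline = ablate_phenotypes(t, "disease", 0, {"e": eigen})["abs_corr"].iloc[0]
        out = ablate_phenotypes(t, "disease", 1, {"e": eigen})
        row = out[out["removed"] == ("noise",)]
        assert abs(row["abs_corr"].iloc[0] - baseline) <= 0.05

    def test_n_remove_bounds(self, rng):
        t = _random_table(rng, n_vars=3)
        with pytest.raises(ValueError):
            ablate_phenotypes(t, "disease", 3, [rng.normal(size=len(t))])
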