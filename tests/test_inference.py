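import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mendriver.inference import (
    clr_normalize,
    fit_bins,
    mmi,
    mmi_matrix,
    pcc,
    pcc_matrix,
)


def _pcc_reference(x, y):
    # independently coded covariance formula (sum form)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    cov = (x * y).sum() / n - x.mean() * y.mean()
    sx = np.sqrt((x**2).sum() / n - x.mean() ** 2)
    sy = np.sqrt((y**2).sum() / n - y.mean() ** 2)
    return cov / (sx * sy)


class TestPcc:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
        ],
    )
    def test_exact_linear_dependence(self, x, y, expected):
        assert pcc(x, y) == pytest.approx(expected)

    def test_matches_independent_formula(self):
        x, y = [1, 2, 4], [1, 3, 3]
        assert pcc(x, y) == pytest.approx(_pcc_reference(x, y), abs=1e-12)

    def test_zero_variance_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert pcc([1, 1, 1], [1, 2, 3]) == 0.0

    def test_length_checks(self):
        with pytest.raises(ValueError):
            pcc([1, 2], [1, 2])


class TestPccMatrix:
    def test_identical_and_anticorrelated_features_have_zero_distance(self):
        p = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]],
            index=["a", "b", "c"],
        )
        A, D = pcc_matrix(p)
        assert D.at["a", "b"] == pytest.approx(0.0)
        assert A.at["a", "c"] == pytest.approx(-1.0)
        assert D.at["a", "c"] == pytest.approx(0.0)  # sign-blind distance

    def test_random_matrix_ranges(self, rng):
        p = pd.DataFrame(rng.normal(size=(10, 50)))
        A, D = pcc_matrix(p)
        V = A.to_numpy()
        assert np.allclose(V, V.T, atol=1e-10)
        assert np.allclose(np.diag(V), 1.0)
        assert ((D.to_numpy() >= 0) & (D.to_numpy() <= 1)).all()
        assert np.allclose(np.diag(D.to_numpy()), 0.0)


class TestFitBins:
    def test_unimodal_data_gets_one_bin(self, rng):
        x = 5.0 + 1e-3 * rng.normal(size=60)
        assert fit_bins(x, max_components=3, random_state=0).n_components == 1

    def test_two_clusters_recovered(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(0, 0.1, 100), rng.normal(10, 0.1, 100)])
        truth = np.repeat([0, 1], 100)
        bm = fit_bins(x, max_components=3, random_state=0)
        assert bm.n_components == 2
        agreement = max(
            (bm.labels == truth).mean(), (bm.labels == 1 - truth).mean()
        )
        assert agreement >= 0.95

    def test_forced_single_component(self, rng):
        x = rng.normal(size=50)
        bm = fit_bins(x, max_components=1)
        assert bm.n_components == 1
        assert bm.proportions.sum() == pytest.approx(1.0)

    def test_every_bin_nonempty(self, rng):
        x = rng.normal(size=90)
        bm = fit_bins(x, max_components=3, random_state=0)
        assert set(bm.labels) == set(range(bm.n_components))


class TestMmi:
    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(0)
        z = rng.multivariate_normal([0, 0], [[1, 0.9], [0.9, 1]], size=2000)
        bx = fit_bins(z[:, 0], max_components=1)
        by = fit_bins(z[:, 1], max_components=1)
        expected = -0.5 * np.log(1 - 0.81)
        assert mmi(z[:, 0], z[:, 1], bx, by) == pytest.approx(expected, abs=0.05)

    def test_independent_inputs_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        bx = fit_bins(x, max_components=3, random_state=0)
        by = fit_bins(y, max_components=3, random_state=0)
        assert mmi(x, y, bx, by) < 0.02

    def test_symmetry_and_nonnegativity(self, rng):
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        bx = fit_bins(x, random_state=0)
        by = fit_bins(y, random_state=0)
        assert mmi(x, y, bx, by) == pytest.approx(mmi(y, x, by, bx))
        assert mmi(x, y, bx, by) >= 0.0

    def test_affine_invariance(self, rng):
        x = rng.normal(size=400)
        y = 0.7 * x + 0.5 * rng.normal(size=400)
        y2 = 3.0 * y + 7.0  # strictly monotone affine rescale
        bx = fit_bins(x, random_state=0)
        by = fit_bins(y, random_state=0)
        by2 = fit_bins(y2, random_state=0)
        assert mmi(x, y, bx, by) == pytest.approx(mmi(x, y2, bx, by2), abs=0.05)

    def test_length_mismatch(self, rng):
        x = rng.normal(size=20)
        bx = fit_bins(x)
        with pytest.raises(ValueError):
            mmi(x, x[:-1], bx, bx)


class TestClrNormalize:
    def test_flat_background_gives_zeros(self):
        M = pd.DataFrame(np.full((4, 4), 0.3) - 0.3 * np.eye(4))
        with pytest.warns(UserWarning, match="zero background"):
            out = clr_normalize(M)
        assert np.allclose(out.to_numpy(), 0.0)

    def test_planted_strong_pair_is_strict_maximum(self, rng):
        n = 8
        base = rng.uniform(0.0, 0.1, size=(n, n))
        M = (base + base.T) / 2
        np.fill_diagonal(M, 0.0)
        M[1, 4] = M[4, 1] = 5.0
        out = clr_normalize(pd.DataFrame(M)).to_numpy()
        # direct z-score verification of the planted entry
        off = ~np.eye(n, dtype=bool)
        z1 = (M[1, 4] - M[1, off[1]].mean()) / M[1, off[1]].std()
        z4 = (M[4, 1] - M[4, off[4]].mean()) / M[4, off[4]].std()
        assert out[1, 4] == pytest.approx(np.sqrt(max(z1, 0) ** 2 + max(z4, 0) ** 2))
        masked = out.copy()
        masked[1, 4] = masked[4, 1] = -np.inf
        assert out[1, 4] > masked.max()

    def test_symmetric_output_and_shift_invariance(self, rng):
        base = rng.normal(size=(6, 6))
        M = (base + base.T) / 2
        np.fill_diagonal(M, 0.0)
        out = clr_normalize(pd.DataFrame(M)).to_numpy()
        assert np.allclose(out, out.T, atol=1e-12)
        shifted = clr_normalize(pd.DataFrame(M + 3.7)).to_numpy()
        assert np.allclose(out, shifted, atol=1e-10)
        assert (out >= 0).all()


class TestMmiMatrix:
    def test_duplicated_pair_attains_minimum_distance(self):
        rng = np.random.default_rng(5)
        n = 120
        dup = rng.normal(size=n)
        rows = [dup, dup + 0.01 * rng.normal(size=n)] + [
            rng.normal(size=n) for _ in range(4)
        ]
        p = pd.DataFrame(rows, index=[f"f{i}" for i in range(6)])
        A, D = mmi_matrix(p, random_state=0)
        V = D.to_numpy()
        off = V[~np.eye(6, dtype=bool)]
        assert D.at["f0", "f1"] == pytest.approx(off.min())

    def test_distance_shape_properties(self, rng):
        p = pd.DataFrame(rng.normal(size=(5, 60)))
        A, D = mmi_matrix(p, random_state=0)
        V = D.to_numpy()
        assert np.allclose(V, V.T, atol=1e-10)
        assert np.allclose(np.diag(V), 0.0)
        assert (A.to_numpy() >= 0).all()


def test_mmi_ranking_agrees_with_pcc_on_unimodal_data():
    """For unimodal Gaussian pairs MMI is a monotone function of |rho|,
    so the pairwise rankings should almost coincide."""
    rng = np.random.default_rng(42)
    n = 300
    latent = rng.normal(size=n)
    X = np.array(
        [
            a * latent + np.sqrt(max(1e-9, 1 - a * a)) * rng.normal(size=n)
            for a in np.linspace(0.1, 0.95, 10)
        ]
    )
    bins = [fit_bins(x, max_components=3, random_state=0) for x in X]
    pc, mm = [], []
    for i, j in itertools.combinations(range(10), 2):
        pc.append(abs(np.corrcoef(X[i], X[j])[0, 1]))
        mm.append(mmi(X[i], X[j], bins[i], bins[j]))
    assert spearmanr(pc, mm).statistic >= 0.9
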