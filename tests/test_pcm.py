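import numpy as np
import pandas as pd
import pytest

from tugpcm.io import load_fixture
from tugpcm.pcm import (
    AdequacyError,
    PCMConfig,
    PrincipalComponentModel,
    bartlett_sphericity,
    build_tug_pcm,
    fit_phase_pcm,
    kmo_statistic,
    pca_correlation,
    total_explained_variance,
    tucker_congruence,
    varimax_rotate,
)


def one_factor_data(rng, n=80, p=6, loading=0.8):
    z = rng.standard_normal(n)
    x = loading * z[:, None] + np.sqrt(1 - loading**2) * rng.standard_normal((n, p))
    return pd.DataFrame(x, columns=[f"v{i}" for i in range(p)]), z


def kmo_oracle(corr):
    """Brute-force KMO: for every pair, the partial correlation given all
    remaining variables is computed from the pairwise regression (Schur
    complement of the remaining block), never from the anti-image inverse."""
    p = corr.shape[0]
    r2 = 0.0
    q2 = 0.0
    for j in range(p):
        for k in range(p):
            if j == k:
                continue
            r2 += corr[j, k] ** 2
            others = [m for m in range(p) if m not in (j, k)]
            if others:
                s_oo = corr[np.ix_(others, others)]
                s_po = corr[np.ix_([j, k], others)]
                resid = corr[np.ix_([j, k], [j, k])] - s_po @ np.linalg.solve(
                    s_oo, s_po.T
                )
                partial = resid[0, 1] / np.sqrt(resid[0, 0] * resid[1, 1])
            else:
                partial = corr[j, k]
            q2 += partial**2
    return r2 / (r2 + q2)


class TestKMO:
    def test_two_variables_have_kmo_half(self):
        corr = np.array([[1.0, 0.9], [0.9, 1.0]])
        assert kmo_statistic(corr) == pytest.approx(0.5, abs=1e-12)

    def test_identity_matrix_is_degenerate(self):
        with pytest.warns(UserWarning, match="KMO undefined"):
            out = kmo_statistic(np.eye(4))
        assert np.isnan(out)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_partial_correlation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.integers(4, 9)
        lam = rng.uniform(0.5, 0.8, p)
        corr = np.outer(lam, lam)
        np.fill_diagonal(corr, 1.0)
        assert kmo_statistic(corr) == pytest.approx(kmo_oracle(corr), abs=1e-10)

    def test_singular_matrix_suggests_reduction(self):
        corr = np.ones((3, 3))
        with pytest.raises(ValueError, match="singular"):
            kmo_statistic(corr)


class TestBartlett:
    def test_identity_gives_zero_statistic(self):
        chi2, df, p = bartlett_sphericity(np.eye(5), 40)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert df == 10

    def test_direct_formula_for_two_variables(self):
        corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        chi2, df, p = bartlett_sphericity(corr, 50)
        assert chi2 == pytest.approx(-(49 - 9 / 6) * np.log(0.75), abs=1e-12)
        assert df == 1

    def test_one_factor_data_is_clearly_non_spherical(self):
        rng = np.random.default_rng(5)
        data, _ = one_factor_data(rng, n=58)
        corr = np.corrcoef(data.to_numpy(), rowvar=False)
        chi2, df, p = bartlett_sphericity(corr, 58)
        assert p < 0.001

    def test_requires_more_subjects_than_variables(self):
        with pytest.raises(ValueError):
            bartlett_sphericity(np.eye(10), 10)


class TestPCACorrelation:
    def test_two_perfectly_correlated_variables(self):
        x = np.linspace(0, 1, 50)
        data = pd.DataFrame({"a": x, "b": 3 * x + 1})
        eigval, loadings = pca_correlation(data)
        np.testing.assert_allclose(eigval, [2.0, 0.0], atol=1e-10)

    def test_trace_conservation(self, feature_table):
        sub = feature_table.iloc[:, :30]
        eigval, _ = pca_correlation(sub)
        assert eigval.sum() == pytest.approx(30.0, abs=1e-8)

    def test_constant_variable_named_in_error(self, feature_table):
        bad = feature_table.iloc[:, :5].copy()
        bad["frozen"] = 1.0
        with pytest.raises(ValueError, match="frozen"):
            pca_correlation(bad)


class TestVarimax:
    @staticmethod
    def _criterion(L):
        s = L**2
        return float((s.var(axis=0)).sum())

    @staticmethod
    def _jacobi_oracle(L, sweeps=200):
        """Classic pairwise-rotation varimax (no row normalization)."""
        L = L.copy()
        p, k = L.shape
        for _ in range(sweeps):
            changed = False
            for i in range(k - 1):
                for j in range(i + 1, k):
                    x, y = L[:, i], L[:, j]
                    u = x**2 - y**2
                    v = 2 * x * y
                    num = 2 * (p * (u * v).sum() - u.sum() * v.sum())
                    den = p * (u**2 - v**2).sum() - (u.sum() ** 2 - v.sum() ** 2)
                    phi = 0.25 * np.arctan2(num, den)
                    if abs(phi) > 1e-10:
                        c, s = np.cos(phi), np.sin(phi)
                        L[:, i], L[:, j] = c * x + s * y, -s * x + c * y
                        changed = True
            if not changed:
                break
        return L

    def test_block_diagonal_structure_is_a_fixed_point(self):
        L = np.zeros((6, 2))
        L[:3, 0] = 0.9
        L[3:, 1] = 0.8
        rotated = varimax_rotate(L)
        # unchanged up to column permutation and sign
        got = np.sort(np.abs(rotated).max(axis=0))
        np.testing.assert_allclose(got, [0.8, 0.9], atol=1e-8)
        assert self._criterion(rotated) >= self._criterion(L) - 1e-10

    def test_communalities_preserved(self):
        rng = np.random.default_rng(8)
        L = rng.normal(size=(12, 4))
        rotated = varimax_rotate(L)
        np.testing.assert_allclose(
            (rotated**2).sum(axis=1), (L**2).sum(axis=1), atol=1e-8
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_criterion_matches_pairwise_jacobi_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = rng.normal(size=(8, 3)) * 0.5
        ours = varimax_rotate(L, normalize=False)
        oracle = self._jacobi_oracle(L)
        assert self._criterion(ours) >= self._criterion(L) - 1e-10
        assert self._criterion(ours) == pytest.approx(
            self._criterion(oracle), abs=1e-6
        )

    def test_agrees_with_statsmodels_rotation(self):
        from statsmodels.multivariate.factor_rotation import rotate_factors

        rng = np.random.default_rng(3)
        L = rng.normal(size=(10, 3)) * 0.6
        ours = varimax_rotate(L, normalize=False)
        theirs, _ = rotate_factors(L, "varimax")
        assert self._criterion(ours) == pytest.approx(
            self._criterion(theirs), abs=1e-6
        )

    def test_single_component_is_a_warned_no_op(self):
        L = np.array([[0.5], [0.7]])
        with pytest.warns(UserWarning, match="single component"):
            out = varimax_rotate(L)
        np.testing.assert_array_equal(out, L)


class TestModelFit:
    def test_score_means_vanish_on_the_fitted_sample(self, feature_table):
        model = PrincipalComponentModel(
            feature_table.iloc[:, :30], PCMConfig(check_adequacy=False)
        )
        res = model.fit()
        assert res.scores().mean().abs().max() < 1e-8

    def test_duplicated_subject_gets_identical_scores(self, feature_table):
        model = PrincipalComponentModel(
            feature_table.iloc[:, :30], PCMConfig(check_adequacy=False)
        )
        res = model.fit()
        twice = feature_table.iloc[[0, 0], :30]
        twice.index = ["a", "b"]
        s = res.scores(twice)
        np.testing.assert_allclose(s.loc["a"], s.loc["b"], atol=1e-12)

    def test_one_factor_scores_track_the_latent(self):
        rng = np.random.default_rng(17)
        data, z = one_factor_data(rng, n=120, p=8, loading=0.85)
        res = PrincipalComponentModel(data, PCMConfig(check_adequacy=False)).fit()
        r = np.corrcoef(res.scores().iloc[:, 0], z)[0, 1]
        assert abs(r) > 0.95

    def test_explained_variance_ordered_and_bounded(self, feature_table):
        res = PrincipalComponentModel(
            feature_table.iloc[:, 30:60], PCMConfig(check_adequacy=False)
        ).fit()
        ev = res.explained_variance_pct
        assert (np.diff(ev) <= 1e-9).all()
        assert res.total_explained_variance <= 100.0
        # communalities equal row sums of squared loadings
        np.testing.assert_allclose(
            res.communalities,
            (res.rotated_loadings**2).sum(axis=1),
            atol=1e-8,
        )

    def test_summary_mentions_the_key_statistics(self, feature_table):
        res = PrincipalComponentModel(
            feature_table.iloc[:, :30], PCMConfig(check_adequacy=False)
        ).fit()
        text = res.summary()
        assert "KMO" in text and "Bartlett" in text
        assert "Explained variance" in text


class TestPhaseAndTaskModels:
    def test_independent_noise_fails_the_adequacy_screen(self):
        rng = np.random.default_rng(23)
        noise = pd.DataFrame(
            rng.standard_normal((58, 30)),
            columns=[f"v{i}_turn" for i in range(30)],
        )
        model = PrincipalComponentModel(noise, PCMConfig())
        with pytest.raises(AdequacyError):
            model.fit()

    def test_phase_fit_enforces_communality_on_retained_variables(
        self, feature_table
    ):
        res = fit_phase_pcm(feature_table, "walk_back")
        kept = res.communalities.loc[res.retained_variables]
        assert (kept >= 0.800).all()
        assert res.kmo > 0.5
        # removal log only ever names variables from this phase
        assert all(v.endswith("walk_back") for v in res.excluded_low_communality)

    def test_removal_loop_terminates_within_p_iterations(self, feature_table):
        res = fit_phase_pcm(feature_table, "turn")
        assert len(res.excluded_low_communality) <= 30

    def test_pooling_a_single_phase_reproduces_that_phase_model(
        self, feature_table
    ):
        phase = fit_phase_pcm(feature_table, "walk_forward")
        pooled = build_tug_pcm(
            feature_table,
            list(phase.rotated_loadings.index),
        )
        # same variables, same eigenvalues, loadings equal up to
        # column permutation and sign
        np.testing.assert_allclose(
            pooled.eigenvalues, phase.eigenvalues, atol=1e-8
        )
        a = np.abs(phase.rotated_loadings.to_numpy())
        b = np.abs(pooled.rotated_loadings.to_numpy())
        cong = np.zeros((a.shape[1], b.shape[1]))
        for i in range(a.shape[1]):
            for j in range(b.shape[1]):
                cong[i, j] = tucker_congruence(a[:, i], b[:, j])
        assert (cong.max(axis=1) > 0.999).all()

    def test_empty_retained_list_is_rejected(self, feature_table):
        with pytest.raises(ValueError, match="no retained"):
            build_tug_pcm(feature_table, [])


class TestTotalExplainedVariance:
    def test_published_eleven_components_sum_to_the_abstract_value(self):
        ev = load_fixture("table3_loadings").attrs["explained_variance_pct"]
        assert total_explained_variance(ev) == pytest.approx(84.33, abs=1e-9)

    def test_single_component_equals_its_own_percentage(self):
        assert total_explained_variance([22.21]) == pytest.approx(22.21)
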