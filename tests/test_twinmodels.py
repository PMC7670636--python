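"""ACE maximum-likelihood machinery: implied covariances, likelihood oracle,
nesting, Falconer closed-form recovery, Cholesky formulas, and profile CIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pvstwin.twinmodels import (
    RELATEDNESS,
    CholeskyFit,
    _suffstats,
    _uni_negloglik,
    _biv_negloglik,
    compare_models,
    confidence_interval,
    falconer_estimates,
    fit_bivariate,
    fit_univariate,
    genetic_correlation,
    pair_covariance_biv,
    pair_covariance_uni,
    pairs_by_group,
    shared_heritability,
)
from pvstwin.twinsim import TwinSimSpec, simulate_twin_cohort


# ---------------------------------------------------------------------------
# implied covariances
# ---------------------------------------------------------------------------

class TestPairCovariance:
    def test_pure_genetic_mz(self):
        np.testing.assert_allclose(pair_covariance_uni(1, 0, 0, 1.0), [[1, 1], [1, 1]])

    def test_paper_path_values(self):
        sigma = pair_covariance_uni(0.9497, 0.1414, 0.2793, 0.5)
        assert sigma[0, 0] == pytest.approx(0.9998, abs=5e-4)
        assert sigma[0, 1] == pytest.approx(0.4709, abs=5e-4)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0, 2), st.floats(0, 2), st.floats(0, 2))
    def test_relatedness_difference_identity(self, a, c, e):
        """off-diag(r_A=1) - off-diag(r_A=0.5) = a^2 / 2 for any paths."""
        d = pair_covariance_uni(a, c, e, 1.0)[0, 1] - pair_covariance_uni(a, c, e, 0.5)[0, 1]
        assert d == pytest.approx(0.5 * a**2, rel=1e-9, abs=1e-12)

    def test_bivariate_identity_genetic_only(self):
        sigma = pair_covariance_biv(np.eye(2), np.zeros((2, 2)), np.zeros((2, 2)), 1.0)
        expected = np.array(
            [[1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1]], dtype=float
        )
        np.testing.assert_allclose(sigma, expected)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-1.5, 1.5), min_size=9, max_size=9))
    def test_bivariate_psd_and_cross_block_identity(self, vals):
        v = np.abs(vals)
        L_A = np.array([[v[0], 0], [vals[1], v[2]]])
        L_C = np.array([[v[3], 0], [vals[4], v[5]]])
        L_E = np.array([[v[6], 0], [vals[7], v[8]]])
        sigma = pair_covariance_biv(L_A, L_C, L_E, 0.5)
        assert np.linalg.eigvalsh(sigma).min() >= -1e-10
        # cross-person block difference between r_A=1 and r_A=0.5 is A/2
        s1 = pair_covariance_biv(L_A, L_C, L_E, 1.0)
        A = L_A @ L_A.T
        np.testing.assert_allclose(s1[:2, 2:] - sigma[:2, 2:], 0.5 * A, atol=1e-10)

    def test_non_lower_triangular_rejected(self):
        with pytest.raises(ValueError, match="lower triangular"):
            pair_covariance_biv(np.ones((2, 2)), np.eye(2), np.eye(2), 1.0)


# ---------------------------------------------------------------------------
# likelihood oracle
# ---------------------------------------------------------------------------

def _brute_force_loglik_uni(theta, pairs):
    a, c, e, mu = theta
    ll = 0.0
    for g, x in pairs.items():
        sigma = pair_covariance_uni(a, c, e, RELATEDNESS[g])
        ll += stats.multivariate_normal(mean=[mu, mu], cov=sigma).logpdf(x).sum()
    return ll


def _brute_force_loglik_biv(theta, pairs):
    L_A = np.array([[theta[0], 0], [theta[1], theta[2]]])
    L_C = np.array([[theta[3], 0], [theta[4], theta[5]]])
    L_E = np.array([[theta[6], 0], [theta[7], theta[8]]])
    mu = np.tile(theta[9:11], 2)
    ll = 0.0
    for g, x in pairs.items():
        sigma = pair_covariance_biv(L_A, L_C, L_E, RELATEDNESS[g])
        ll += stats.multivariate_normal(mean=mu, cov=sigma).logpdf(x).sum()
    return ll


class TestLikelihoodOracle:
    def test_univariate_matches_per_pair_density_sum(self, univariate_cohort):
        pairs = pairs_by_group(univariate_cohort, "trait")
        st_ = _suffstats(pairs)
        rng = np.random.default_rng(5)
        for _ in range(5):
            theta = np.array([rng.uniform(0.2, 1), rng.uniform(0.05, 1),
                              rng.uniform(0.2, 1), rng.normal(scale=0.3)])
            fast = -_uni_negloglik(theta, "ACE", st_, RELATEDNESS)
            brute = _brute_force_loglik_uni(theta, pairs)
            assert fast == pytest.approx(brute, abs=1e-8)

    def test_bivariate_matches_per_pair_density_sum(self, bivariate_cohort):
        pairs = pairs_by_group(bivariate_cohort, ["trait1", "trait2"])
        st_ = _suffstats(pairs)
        rng = np.random.default_rng(6)
        for _ in range(3):
            theta = np.concatenate([
                rng.uniform(0.2, 0.9, size=1), rng.normal(scale=0.3, size=1),
                rng.uniform(0.2, 0.9, size=1), rng.uniform(0.1, 0.6, size=1),
                rng.normal(scale=0.2, size=1), rng.uniform(0.1, 0.6, size=1),
                rng.uniform(0.2, 0.9, size=1), rng.normal(scale=0.2, size=1),
                rng.uniform(0.2, 0.9, size=1), rng.normal(scale=0.2, size=2),
            ])
            fast = -_biv_negloglik(theta, st_, RELATEDNESS)
            brute = _brute_force_loglik_biv(theta, pairs)
            assert fast == pytest.approx(brute, abs=1e-8)


# ---------------------------------------------------------------------------
# univariate fitting
# ---------------------------------------------------------------------------

class TestFitUnivariate:
    def test_falconer_closed_form_recovery_large_n(self):
        """With many pairs the ML estimates approach the Falconer closed-form
        solution a^2 = 2(r_MZ - r_0.5), c^2 = 2 r_0.5 - r_MZ, e^2 = 1 - r_MZ."""
        spec = TwinSimSpec(
            n_mz=4000, n_dz=2000, n_nt=2000,
            paths_a=np.sqrt(0.8), paths_c=np.sqrt(0.1), paths_e=np.sqrt(0.1),
            covariate_effects={}, seed=77,
        )
        df = simulate_twin_cohort(spec)
        fit = fit_univariate(df, "trait")
        assert fit.h2 == pytest.approx(0.8, abs=0.03)
        assert fit.c2 / fit.variance == pytest.approx(0.1, abs=0.03)

    def test_no_familial_resemblance_zero_h2(self):
        spec = TwinSimSpec(n_mz=1000, n_dz=500, n_nt=500, paths_a=0.0, paths_c=0.0,
                           paths_e=1.0, covariate_effects={}, seed=13)
        fit = fit_univariate(simulate_twin_cohort(spec), "trait")
        assert fit.h2 < 0.05

    def test_single_group_unidentified(self, univariate_cohort):
        mz_only = univariate_cohort[univariate_cohort["group"] == "MZ"]
        with pytest.raises(ValueError, match="identifiability"):
            fit_univariate(mz_only, "trait")

    def test_scale_invariance(self, univariate_cohort):
        f1 = fit_univariate(univariate_cohort, "trait")
        scaled = univariate_cohort.copy()
        scaled["trait"] = scaled["trait"] * 37.5
        f2 = fit_univariate(scaled, "trait")
        assert f2.h2 == pytest.approx(f1.h2, abs=1e-4)

    def test_missing_pair_members_dropped(self, univariate_cohort):
        df = univariate_cohort.copy()
        fam = df["family_id"].iloc[0]
        df.loc[(df["family_id"] == fam) & (df["member"] == 2), "trait"] = np.nan
        fit = fit_univariate(df, "trait")
        full = fit_univariate(univariate_cohort, "trait")
        assert sum(fit.n_pairs.values()) == sum(full.n_pairs.values()) - 1


@pytest.fixture(scope="module")
def comparison(univariate_cohort):
    return compare_models(univariate_cohort, "trait")


class TestModelComparison:
    def test_loglik_nesting(self, comparison):
        f = comparison.fits
        assert f["ACE"].loglik >= f["AE"].loglik - 1e-6
        assert f["ACE"].loglik >= f["CE"].loglik - 1e-6
        assert f["AE"].loglik >= f["E"].loglik - 1e-6
        assert f["CE"].loglik >= f["E"].loglik - 1e-6

    def test_lrt_nonnegative_with_df(self, comparison):
        stat, df, p = comparison.lrt("ACE", "CE")
        assert stat >= 0 and df == 1 and 0 <= p <= 1

    def test_aic_penalty(self, comparison):
        f = comparison.fits
        # AIC = -2 loglik + 2k; equal logliks would differ by exactly 2 per df
        assert f["ACE"].aic == pytest.approx(-2 * f["ACE"].loglik + 8)
        assert f["AE"].aic == pytest.approx(-2 * f["AE"].loglik + 6)

    def test_non_nested_pair_rejected(self, comparison):
        with pytest.raises(ValueError, match="not nested"):
            comparison.lrt("AE", "CE")

    def test_ace_vs_ce_power_at_high_heritability(self):
        """a^2 = 0.9 at the study's group sizes: the genetic factor is detected
        (ACE vs CE LRT, p < .05) in essentially every replicate."""
        reject = 0
        n_rep = 40
        for s in range(n_rep):
            spec = TwinSimSpec(paths_a=np.sqrt(0.9), paths_c=np.sqrt(0.02),
                               paths_e=np.sqrt(0.08), covariate_effects={}, seed=900 + s)
            comp = compare_models(simulate_twin_cohort(spec), "trait", ("ACE", "CE"))
            _, _, p = comp.lrt("ACE", "CE")
            reject += p < 0.05
        assert reject / n_rep > 0.95


# ---------------------------------------------------------------------------
# bivariate Cholesky
# ---------------------------------------------------------------------------

def _fit_from_paths(L_A, L_C, L_E):
    return CholeskyFit(np.asarray(L_A, float), np.asarray(L_C, float),
                       np.asarray(L_E, float), np.zeros(2), 0.0, {}, True)


class TestCholeskyFormulas:
    def test_rg_independent_genetic_effects(self):
        f = _fit_from_paths([[1, 0], [0, 1]], np.eye(2) * 0.1, np.eye(2) * 0.1)
        assert genetic_correlation(f) == 0.0

    def test_rg_single_shared_factor(self):
        f = _fit_from_paths([[0.7, 0], [0.5, 0]], np.eye(2) * 0.1, np.eye(2) * 0.1)
        assert genetic_correlation(f) == pytest.approx(1.0)

    def test_rg_paper_paths(self):
        f = _fit_from_paths([[0.8112, 0], [0.2850, 0.9064]], np.zeros((2, 2)), np.eye(2))
        assert genetic_correlation(f) == pytest.approx(0.300, abs=5e-4)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0.05, 2), st.floats(-2, 2), st.floats(0.0, 2))
    def test_rg_equals_A_matrix_correlation(self, a11, a12, a22):
        """Path formula a12/sqrt(a12^2+a22^2) == A-matrix correlation when a11 > 0."""
        f = _fit_from_paths([[a11, 0], [a12, a22]], np.zeros((2, 2)), np.eye(2))
        rg = genetic_correlation(f)
        A = f.A
        if A[0, 0] > 0 and A[1, 1] > 0:
            assert rg == pytest.approx(A[0, 1] / np.sqrt(A[0, 0] * A[1, 1]), abs=1e-9)

    def test_rg_undefined_when_no_genetic_paths_to_trait2(self):
        f = _fit_from_paths([[0.5, 0], [0, 0]], np.eye(2), np.eye(2))
        assert np.isnan(genetic_correlation(f))

    def test_shared_h2_pure_genetic(self):
        f = _fit_from_paths([[0.8, 0], [0.3, 0.5]], [[0.4, 0], [0, 0.4]],
                            [[0.4, 0], [0, 0.4]])
        assert shared_heritability(f) == 1.0

    def test_shared_h2_zero_genetic_cross_path(self):
        f = _fit_from_paths([[0.8, 0], [0, 0.5]], [[0.4, 0], [0.2, 0.4]],
                            [[0.4, 0], [0.1, 0.4]])
        assert shared_heritability(f) == 0.0

    def test_shared_h2_paper_paths(self):
        f = _fit_from_paths([[0.8112, 0], [0.2850, 0.9064]],
                            [[0.4000, 0], [0.0600, 0.3]],
                            [[0.4266, 0], [0.05634, 0.28]])
        assert shared_heritability(f) == pytest.approx(0.828, abs=5e-4)

    def test_shared_h2_absolute_vs_signed(self):
        f = _fit_from_paths([[0.8, 0], [-0.3, 0.5]], [[0.4, 0], [0.2, 0.4]],
                            [[0.4, 0], [0.1, 0.4]])
        assert 0 <= shared_heritability(f) <= 1
        assert shared_heritability(f, signed=True) != shared_heritability(f)


class TestFitBivariate:
    def test_independent_traits_small_rg(self):
        spec = TwinSimSpec(
            n_mz=500, n_dz=300, n_nt=300,
            paths_a=[[0.8, 0], [0.0, 0.8]], paths_c=[[0.3, 0], [0.0, 0.3]],
            paths_e=[[0.5, 0], [0.0, 0.5]], covariate_effects={}, seed=55,
        )
        fit = fit_bivariate(simulate_twin_cohort(spec), ["trait1", "trait2"])
        assert abs(genetic_correlation(fit)) < 0.15

    def test_duplicated_trait_unit_rg(self, univariate_cohort):
        df = univariate_cohort.copy()
        df["trait2"] = df["trait"] + 1e-3 * np.random.default_rng(0).normal(size=len(df))
        fit = fit_bivariate(df, ["trait", "trait2"])
        assert genetic_correlation(fit) > 0.98

    def test_rg_path_formula_equals_A_correlation_on_fit(self, bivariate_cohort):
        fit = fit_bivariate(bivariate_cohort, ["trait1", "trait2"])
        A = fit.A
        assert genetic_correlation(fit) == pytest.approx(
            A[0, 1] / np.sqrt(A[0, 0] * A[1, 1]), abs=1e-6
        )

    def test_scale_invariance(self, bivariate_cohort):
        f1 = fit_bivariate(bivariate_cohort, ["trait1", "trait2"])
        scaled = bivariate_cohort.copy()
        scaled["trait2"] = scaled["trait2"] * 12.0
        f2 = fit_bivariate(scaled, ["trait1", "trait2"])
        assert genetic_correlation(f2) == pytest.approx(genetic_correlation(f1), abs=0.01)
        assert shared_heritability(f2) == pytest.approx(shared_heritability(f1), abs=0.01)


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

class TestConfidenceIntervals:
    def test_contains_point_estimate(self, univariate_cohort):
        fit = fit_univariate(univariate_cohort, "trait")
        lo, hi = confidence_interval(fit, "h2")
        assert lo <= fit.h2 <= hi
        assert 0.0 <= lo and hi <= 1.0

    def test_width_shrinks_with_information(self):
        """79 vs 790 DZ pairs (other groups fixed): more pairs, tighter CI."""
        small = simulate_twin_cohort(TwinSimSpec(seed=61))
        big = simulate_twin_cohort(TwinSimSpec(n_dz=790, seed=61))
        ci_small = confidence_interval(fit_univariate(small, "trait"), "h2")
        ci_big = confidence_interval(fit_univariate(big, "trait"), "h2")
        assert ci_big[1] - ci_big[0] < ci_small[1] - ci_small[0]

    def test_profile_coverage_for_moderate_heritability(self):
        """Nominal 95% profile CI covers true h^2 = 0.6 between 90% and 99% of
        the time over 200 replicates at the study's group sizes."""
        a, c, e = np.sqrt(0.6), np.sqrt(0.1), np.sqrt(0.3)
        covered = 0
        n_rep = 200
        for s in range(n_rep):
            spec = TwinSimSpec(paths_a=a, paths_c=c, paths_e=e,
                               covariate_effects={}, seed=5000 + s)
            fit = fit_univariate(simulate_twin_cohort(spec), "trait")
            lo, hi = confidence_interval(fit, "h2")
            covered += lo <= 0.6 <= hi
        assert 0.90 <= covered / n_rep <= 0.99

    def test_bivariate_rg_interval_contains_estimate(self, bivariate_cohort):
        fit = fit_bivariate(bivariate_cohort, ["trait1", "trait2"])
        lo, hi = confidence_interval(fit, "r_g")
        assert lo <= genetic_correlation(fit) <= hi
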