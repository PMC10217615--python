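"""Delta-method covariances and the closed-form asymptotic laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad

from entrotest import (
    DegenerateSupportError,
    EntropySpec,
    ProbabilityVector,
    asymptotic_law,
    delta_covariance,
    entropy_gradient,
    law_sampler,
    multinomial_covariance,
    renyi_limit_cdf,
    renyi_limit_density,
)
from entrotest.asymptotics import closed_form_delta_covariance, fisher_paper_sigma_star
from entrotest.counts import linear_model, one_almost_zero_model

from conftest import random_simplex

SPECS_STR = [
    EntropySpec("shannon"),
    EntropySpec("tsallis", q=0.5),
    EntropySpec("tsallis", q=1.5),
    EntropySpec("renyi", q=1 / 3),
    EntropySpec("renyi", q=2 / 3),
]


class TestMultinomialCovariance:
    def test_two_category_closed_form(self):
        cov = multinomial_covariance(ProbabilityVector([0.5, 0.5]))
        np.testing.assert_allclose(cov, [[0.25, -0.25], [-0.25, 0.25]])

    @given(seed=st.integers(0, 500), k=st.integers(2, 15))
    @settings(max_examples=40, deadline=None)
    def test_rows_sum_to_zero_and_psd(self, seed, k):
        p = ProbabilityVector(random_simplex(np.random.default_rng(seed), k))
        cov = multinomial_covariance(p)
        np.testing.assert_allclose(cov.sum(axis=1), 0.0, atol=1e-14)
        assert np.min(np.linalg.eigvalsh(cov)) >= -1e-12


class TestEntropyGradient:
    def test_shannon_vanishes_at_one_over_e(self):
        p = ProbabilityVector([1 / np.e, 1 - 1 / np.e])
        B = entropy_gradient(p, EntropySpec("shannon"))
        assert B[0, 0] == pytest.approx(0.0, abs=1e-14)

    def test_fisher_zero_at_uniform(self):
        p = ProbabilityVector(np.full(5, 0.2))
        B = entropy_gradient(p, EntropySpec("fisher"))
        assert B.shape == (4, 5)
        np.testing.assert_allclose(B, 0.0)

    def test_tsallis_q2_diagonal(self, rng):
        v = random_simplex(rng, 6)
        B = entropy_gradient(ProbabilityVector(v), EntropySpec("tsallis", q=2.0))
        np.testing.assert_allclose(np.diag(B), 1.0 - 2.0 * v)

    def test_zero_probability_raises_for_divergent_families(self):
        p = ProbabilityVector([0.5, 0.0, 0.5])
        with pytest.raises(DegenerateSupportError):
            entropy_gradient(p, EntropySpec("shannon"))
        with pytest.raises(DegenerateSupportError):
            entropy_gradient(p, EntropySpec("renyi", q=0.5))


class TestDeltaCovariance:
    def test_shannon_two_categories_symbolic(self):
        c = 0.25 * (np.log(0.5) + 1.0) ** 2
        cov = delta_covariance(ProbabilityVector([0.5, 0.5]), EntropySpec("shannon"))
        np.testing.assert_allclose(cov, [[c, -c], [-c, c]], rtol=1e-14)

    @pytest.mark.parametrize("spec", SPECS_STR, ids=lambda s: s.label)
    @given(seed=st.integers(0, 500))
    @settings(max_examples=25, deadline=None)
    def test_matrix_product_matches_closed_form(self, spec, seed):
        k = 3 + seed % 8
        p = ProbabilityVector(random_simplex(np.random.default_rng(seed), k))
        prod = delta_covariance(p, spec)
        closed = closed_form_delta_covariance(p, spec)
        assert np.max(np.abs(prod - closed)) < 1e-12

    def test_fisher_uniform_gives_zero_matrix(self):
        p = ProbabilityVector(np.full(4, 0.25))
        np.testing.assert_allclose(delta_covariance(p, EntropySpec("fisher")), 0.0)

    def test_fisher_published_form_agrees_where_its_asymmetry_vanishes(self, rng):
        # the verbatim published Sigma* differs from 1'BSigmaB'1 only in terms
        # carrying the factor sqrt(p_k) - sqrt(p_{k-1}); with p_{k-1} = p_k the
        # two must coincide, which validates the shared core terms
        v = random_simplex(rng, 6)
        v[-1] = v[-2] = (v[-1] + v[-2]) / 2
        v = v / v.sum()
        p = ProbabilityVector(v)
        exact = float(delta_covariance(p, EntropySpec("fisher")).sum())
        assert fisher_paper_sigma_star(p) == pytest.approx(exact, rel=1e-9, abs=1e-12)

    def test_fisher_published_form_deviates_in_general(self, rng):
        v = random_simplex(rng, 5)
        p = ProbabilityVector(v)
        exact = float(delta_covariance(p, EntropySpec("fisher")).sum())
        assert fisher_paper_sigma_star(p) != pytest.approx(exact, rel=1e-6)


class TestVarianceContraction:
    """Both routes to each scalar variance agree: the double-sum form and the
    contraction sum p a^2 - (sum p a)^2."""

    @pytest.mark.parametrize("spec", SPECS_STR, ids=lambda s: s.label)
    def test_double_sum_equals_contraction(self, spec, rng):
        v = random_simplex(rng, 7)
        p = ProbabilityVector(v)
        n = 1000
        law = asymptotic_law(p, n, spec)
        # all-ones (Shannon: all-minus-ones) contraction of B Sigma_p B'
        direct = float(delta_covariance(p, spec).sum()) / n
        if spec.family == "tsallis":
            direct /= (spec.q - 1.0) ** 2
        if spec.family == "renyi":
            assert law.power_sum_sd**2 == pytest.approx(direct, rel=1e-12)
        else:
            assert law.variance == pytest.approx(direct, rel=1e-12)

    def test_fisher_delta_variance_equals_gradient_contraction(self, rng):
        v = random_simplex(rng, 6)
        p = ProbabilityVector(v)
        n = 500
        law = asymptotic_law(p, n, EntropySpec("fisher"))
        direct = 16.0 * float(delta_covariance(p, EntropySpec("fisher")).sum()) / n
        assert law.variance == pytest.approx(direct, rel=1e-12)


class TestAsymptoticLawValues:
    def test_shannon_survey_1998(self, gss_1998):
        law = asymptotic_law(
            gss_1998.proportions(), 1202, EntropySpec("shannon", normalized=True)
        )
        assert law.mean == pytest.approx(0.914, abs=5e-4)
        assert law.variance == pytest.approx(0.0000724, abs=1e-7)

    def test_renyi_power_sum_survey_1998(self, gss_1998):
        law = asymptotic_law(
            gss_1998.proportions(), 1202, EntropySpec("renyi", q=2 / 3, normalized=True)
        )
        assert law.variance == pytest.approx(0.0000317, abs=1e-7)

    def test_tsallis_survey_2018(self, gss_2018):
        law = asymptotic_law(
            gss_2018.proportions(), 1130, EntropySpec("tsallis", q=0.5, normalized=True)
        )
        assert law.variance == pytest.approx(0.0000842, abs=1e-7)

    @pytest.mark.parametrize(
        "spec",
        SPECS_STR + [EntropySpec("fisher")],
        ids=lambda s: s.label,
    )
    def test_variance_scales_exactly_as_one_over_n(self, spec, rng):
        p = ProbabilityVector(random_simplex(rng, 5))
        law1 = asymptotic_law(p, 1000, spec)
        law2 = asymptotic_law(p, 2000, spec)
        v1 = law1.power_sum_sd**2 if spec.family == "renyi" else law1.variance
        v2 = law2.power_sum_sd**2 if spec.family == "renyi" else law2.variance
        assert v2 == pytest.approx(v1 / 2, rel=1e-14)

    def test_point_mass_flagged_degenerate(self):
        p = ProbabilityVector([1.0, 0.0])
        law = asymptotic_law(p, 100, EntropySpec("tsallis", q=2.0))
        assert law.degenerate and law.variance == 0.0

    def test_zero_floor_excludes_divergent_cell(self):
        # the near-zero cell would blow up the q<1/2 power-sum variance
        p = one_almost_zero_model(24)
        with pytest.warns(RuntimeWarning):
            law = asymptotic_law(p, 2400, EntropySpec("renyi", q=1 / 3))
        assert np.isfinite(law.variance) and law.power_sum_sd < 1.0
        # literal evaluation without the floor keeps the near-divergent term
        literal = asymptotic_law(p, 2400, EntropySpec("renyi", q=1 / 3),
                                 zero_floor=None)
        assert literal.power_sum_sd > 100 * law.power_sum_sd
        # an exact zero with the floor disabled is an error
        zero = ProbabilityVector(np.array([0.5, 0.0, 0.5]))
        with pytest.raises(DegenerateSupportError):
            asymptotic_law(zero, 100, EntropySpec("renyi", q=1 / 3),
                           zero_floor=None)


@pytest.fixture(scope="module")
def renyi_third_law(gss_1998):
    return asymptotic_law(gss_1998.proportions(), 1202, EntropySpec("renyi", q=1 / 3))


class TestRenyiLimitLaw:
    @pytest.fixture
    def law(self, renyi_third_law):
        return renyi_third_law

    def entropy_scale_sd(self, law):
        return law.power_sum_sd / (abs(1 - law.q) * law.power_sum_mean)

    def test_density_integrates_to_one(self, law):
        se = self.entropy_scale_sd(law)
        total, _ = quad(
            lambda x: float(renyi_limit_density(x, law)),
            law.mean - 12 * se,
            law.mean + 12 * se,
            limit=200,
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_density_matches_transformed_normal_draws(self, law):
        rng = np.random.default_rng(99)
        s = rng.normal(law.power_sum_mean, law.power_sum_sd, size=10**6)
        h = np.log(np.abs(s)) / (1.0 - law.q)
        ks = stats.kstest(h, lambda x: renyi_limit_cdf(x, law))
        assert ks.statistic < 0.005

    def test_mode_location_consistent_with_power_sum_mean(self, law):
        # density peak sits at H = log(mu*)/(1-q) up to O(sigma*^2)
        x0 = np.log(law.power_sum_mean) / (1.0 - law.q)
        se = self.entropy_scale_sd(law)
        xs = np.linspace(law.mean - 6 * se, law.mean + 6 * se, 4001)
        dens = renyi_limit_density(xs, law)
        assert abs(xs[np.argmax(dens)] - x0) < se / 5

    def test_q_above_one_branch(self, gss_1998):
        law = asymptotic_law(
            gss_1998.proportions(), 1202, EntropySpec("renyi", q=2.0)
        )
        se = self.entropy_scale_sd(law)
        total, _ = quad(
            lambda x: float(renyi_limit_density(x, law)),
            law.mean - 12 * se,
            law.mean + 12 * se,
            limit=200,
        )
        assert total == pytest.approx(1.0, abs=1e-6)
        draws = law_sampler(law, 10**5, 5)
        assert stats.kstest(draws, lambda x: renyi_limit_cdf(x, law)).statistic < 0.01


class TestLawSampler:
    def test_normal_law_mean_and_determinism(self):
        law = asymptotic_law(linear_model(6), 600, EntropySpec("shannon"))
        a = law_sampler(law, 10**5, seed=3)
        b = law_sampler(law, 10**5, seed=3)
        assert np.array_equal(a, b)
        assert abs(a.mean() - law.mean) < 5 * law.sd / np.sqrt(10**5)

    def test_log_power_normal_self_consistency(self, gss_1998):
        law = asymptotic_law(
            gss_1998.proportions(), 1202,
            EntropySpec("renyi", q=1 / 3, normalized=True),
        )
        draws = law_sampler(law, 10**5, seed=21)
        ks = stats.kstest(draws, lambda x: renyi_limit_cdf(x, law))
        assert ks.statistic < 0.01

    def test_degenerate_law_warns_and_returns_constants(self):
        law = asymptotic_law(ProbabilityVector([1.0, 0.0]), 10, EntropySpec("shannon"))
        with pytest.warns(RuntimeWarning):
            draws = law_sampler(law, 10, seed=0)
        assert np.all(draws == law.mean)
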