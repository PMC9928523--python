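"""HKY transition probabilities and discrete-gamma rate categories."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.linalg import expm

import tipchron as tc
from tipchron.errors import ParameterError


def rate_matrix(model):
    """Normalized HKY generator, for the matrix-exponential oracle."""
    pi = model.base_freqs
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            transversion = (i in (0, 2)) != (j in (0, 2))
            q[i, j] = pi[j] * (1.0 if transversion else model.kappa)
    q -= np.diag(q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(q)))
    return q / mu


MODELS = [
    tc.SubstitutionModel(),
    tc.SubstitutionModel(kappa=10.0, base_freqs=np.array([0.34, 0.26, 0.13, 0.27])),
    tc.SubstitutionModel(kappa=0.5, base_freqs=np.array([0.1, 0.2, 0.3, 0.4])),
]


class TestHKY:
    @pytest.mark.parametrize("model", MODELS)
    def test_identity_at_zero(self, model):
        assert np.allclose(tc.hky_transition_probs(0.0, model), np.eye(4), atol=1e-12)

    @pytest.mark.parametrize("model", MODELS)
    def test_stationarity_limit(self, model):
        p = tc.hky_transition_probs(1e4, model)
        assert np.allclose(p, np.tile(model.base_freqs, (4, 1)), atol=1e-8)

    @pytest.mark.parametrize("model", MODELS)
    @pytest.mark.parametrize("t", [0.01, 0.1, 0.7, 3.0])
    def test_rows_sum_to_one_and_nonnegative(self, model, t):
        p = tc.hky_transition_probs(t, model)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(p >= 0)

    @pytest.mark.parametrize("model", MODELS)
    @pytest.mark.parametrize("t", [0.01, 0.3, 2.0])
    def test_matches_matrix_exponential(self, model, t):
        assert np.allclose(
            tc.hky_transition_probs(t, model), expm(rate_matrix(model) * t), atol=1e-12
        )

    def test_jukes_cantor_closed_form(self):
        model = tc.SubstitutionModel(kappa=1.0)
        t = 0.1
        p = tc.hky_transition_probs(t, model)
        diag = 0.25 + 0.75 * np.exp(-4 * t / 3)
        off = 0.25 - 0.25 * np.exp(-4 * t / 3)
        expected = np.full((4, 4), off) + np.eye(4) * (diag - off)
        assert np.allclose(p, expected, atol=1e-12)

    @pytest.mark.parametrize("model", MODELS)
    def test_chapman_kolmogorov(self, model):
        t1, t2 = 0.07, 0.23
        p1 = tc.hky_transition_probs(t1, model)
        p2 = tc.hky_transition_probs(t2, model)
        p12 = tc.hky_transition_probs(t1 + t2, model)
        assert np.allclose(p1 @ p2, p12, atol=1e-9)

    @pytest.mark.parametrize("model", MODELS)
    def test_detailed_balance(self, model):
        pi = model.base_freqs
        p = tc.hky_transition_probs(0.4, model)
        flux = pi[:, None] * p
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_expected_substitution_rate_is_one(self):
        for model in MODELS:
            q = rate_matrix(model)
            assert -float(np.dot(model.base_freqs, np.diag(q))) == pytest.approx(1.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ParameterError):
            tc.hky_transition_probs(-0.1, tc.SubstitutionModel())


class TestDiscreteGamma:
    def test_single_category(self):
        assert tc.discrete_gamma_rates(0.7, 1).tolist() == [1.0]

    def test_homogeneity_limit(self):
        rates = tc.discrete_gamma_rates(1e6, 4)
        assert np.allclose(rates, 1.0, atol=1e-2)

    @pytest.mark.parametrize("alpha,k", [(0.5, 4), (0.2, 4), (2.0, 8)])
    def test_matches_quadrature_oracle(self, alpha, k):
        # numerically integrate x * pdf over each equiprobable band
        dist = stats.gamma(a=alpha, scale=1.0 / alpha)
        bounds = dist.ppf(np.arange(k + 1) / k)
        bounds[-1] = np.inf
        expected = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            val, _ = integrate.quad(lambda x: x * dist.pdf(x), lo, hi, limit=200)
            expected.append(val * k)
        rates = tc.discrete_gamma_rates(alpha, k)
        assert np.allclose(rates, expected, rtol=1e-6)
        assert rates.mean() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            tc.discrete_gamma_rates(0.5, 0)
        with pytest.raises(ParameterError):
            tc.discrete_gamma_rates(-1.0, 4)
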