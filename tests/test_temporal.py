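"""Temporal-signal machinery: stepping-stone estimator and test plumbing."""

import numpy as np
import pytest

import tipchron as tc
from tipchron.errors import ParameterError
from tipchron.temporal import default_beta_grid

LOG_ML_TOY = -0.5 * np.log(4 * np.pi)  # N(0,1) prior, N(theta,1) likelihood, y=0


def toy_draw_loglik(beta, n, rng):
    """Exact power-posterior sampler for the conjugate normal toy."""
    theta = rng.normal(0.0, 1.0 / np.sqrt(1.0 + beta), size=n)
    return -0.5 * np.log(2 * np.pi) - 0.5 * theta**2


class TestSteppingStone:
    def test_conjugate_toy_matches_analytic_value(self):
        est = tc.power_posterior_logml(
            toy_draw_loglik, default_beta_grid(8), n_samples=40_000, rng=3
        )
        assert est == pytest.approx(LOG_ML_TOY, abs=0.05)

    def test_single_step_grid_coarse_but_close(self):
        est = tc.power_posterior_logml(toy_draw_loglik, [0.0, 1.0], n_samples=40_000, rng=4)
        assert est == pytest.approx(LOG_ML_TOY, abs=0.2)

    def test_likelihood_identically_one_gives_zero(self):
        est = tc.power_posterior_logml(
            lambda beta, n, rng: np.zeros(n), [0.0, 0.5, 1.0], n_samples=100, rng=0
        )
        assert est == 0.0

    def test_bias_shrinks_as_grid_refines(self):
        # average |error| over replicates: a 16-rung ladder beats 2 rungs
        errs = {}
        for rungs in (2, 16):
            vals = [
                tc.power_posterior_logml(
                    toy_draw_loglik, default_beta_grid(rungs), n_samples=4_000, rng=100 + r
                )
                for r in range(6)
            ]
            errs[rungs] = np.mean(np.abs(np.array(vals) - LOG_ML_TOY))
        assert errs[16] < errs[2]

    def test_grid_validation(self):
        with pytest.raises(ParameterError):
            tc.power_posterior_logml(toy_draw_loglik, [0.0, 0.5], 10, 0)
        with pytest.raises(ParameterError):
            tc.power_posterior_logml(toy_draw_loglik, [0.0, 0.7, 0.3, 1.0], 10, 0)

    def test_beta_grid_endpoints(self):
        grid = default_beta_grid(8)
        assert grid[0] == 0.0 and grid[-1] == 1.0
        assert np.all(np.diff(grid) > 0)


class TestDRTPlumbing:
    def test_too_few_distinct_dates_rejected(self):
        aln = tc.Alignment(["a", "b", "c"], ["ACGT"] * 3)
        with pytest.raises(ParameterError, match="distinct"):
            tc.date_randomization_test(aln, {"a": 0.0, "b": 0.0, "c": 5000.0}, n_perm=2)

    def test_zero_permutations_rejected(self):
        aln = tc.Alignment(["a", "b", "c"], ["ACGT"] * 3)
        with pytest.raises(ParameterError, match="n_perm"):
            tc.date_randomization_test(
                aln, {"a": 0.0, "b": 1000.0, "c": 5000.0}, n_perm=0
            )

    def test_report_describe_mentions_verdict(self):
        report = tc.TemporalSignalReport(
            verdict="signal", real_rate_hpd=(1e-8, 2e-8),
            randomized_rate_hpds=[(1e-9, 5e-9)], n_permutations=1,
        )
        assert "signal" in report.describe()


@pytest.fixture(scope="module")
def bets_data():
    cfg = tc.SimulationConfig(
        n_tips=10, seq_length=800, seed=21,
        tip_ages=[0.0, 0.0] + list(np.linspace(5000, 40000, 8)),
    )
    return tc.make_study_like_dataset(cfg, 7)


class TestBETSSmall:
    """BETS on a small dataset; directionality checks at reduced scale."""

    def test_same_dates_in_both_hypotheses_gives_bf_near_zero(self, bets_data):
        b = bets_data
        cfg = tc.MCMCConfig(chain_length=4_000, sample_every=10, seed=17)
        iso_ages = {t: 0.0 for t in b.alignment.taxa}
        from tipchron.temporal import model_log_marginal_likelihood
        from tipchron.mcmc import TipDate, TipDateModel
        from tipchron.model import TipDatingModel

        model = TipDatingModel(
            b.alignment, TipDateModel({t: TipDate.fixed(0.0) for t in b.alignment.taxa})
        )
        betas = tc.default_beta_grid(4)
        a = model_log_marginal_likelihood(model, cfg, betas)
        c = model_log_marginal_likelihood(model, cfg.replace(seed=91), betas)
        # same model twice: difference is pure Monte-Carlo noise
        assert abs(a - c) < 30.0

    def test_true_dates_beat_scrambled_dates(self, bets_data):
        b = bets_data
        cfg = tc.MCMCConfig(chain_length=6_000, sample_every=10, seed=19)
        betas = tc.default_beta_grid(6)
        true_ages = b.true_ages
        report = tc.bets_compare(b.alignment, true_ages, cfg, betas=betas)
        assert report.log_bayes_factor > 0
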