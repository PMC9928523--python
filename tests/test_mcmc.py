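"""Sampler contracts: determinism, prior recovery, trace invariants."""

import numpy as np
import pytest

import tipchron as tc
from tipchron.errors import ParameterError
from tipchron.priors import LogUniformPrior


def prior_only_fit(tip_mode, chain_length=40_000, seed=31):
    aln = tc.Alignment(["a", "b", "c"], ["ACGT", "ACGT", "ACGT"])
    dates = tc.TipDateModel(
        {
            "a": tc.TipDate.fixed(0.0),
            "b": tc.TipDate.fixed(0.0),
            "c": tip_mode,
        }
    )
    model = tc.TipDatingModel(aln, dates)
    return model.fit(
        tc.MCMCConfig(chain_length=chain_length, sample_every=10, seed=seed, prior_only=True)
    )


class TestPriorRecovery:
    def test_gamma_tip_age_mean(self):
        # Gamma(shape 2, scale 50000): mean 100000
        fit = prior_only_fit(tc.TipDate.gamma(2.0, 50_000.0))
        x = fit.samples("age_c")
        e = float(fit.ess("age_c"))
        sem = x.std(ddof=1) / np.sqrt(e)
        assert abs(x.mean() - 100_000.0) < 3 * sem

    def test_lognormal_tip_age_moments(self):
        fit = prior_only_fit(tc.TipDate.lognormal(10.0, 0.5), seed=77)
        logs = np.log(fit.samples("age_c"))
        e = float(fit.ess("age_c"))
        assert abs(logs.mean() - 10.0) < 3 * logs.std(ddof=1) / np.sqrt(e)
        assert abs(logs.std(ddof=1) - 0.5) < 0.05

    def test_clock_and_pop_size_log_uniform_moments(self):
        fit = prior_only_fit(tc.TipDate.gamma(2.0, 50_000.0), seed=55)
        for col, prior in [
            ("clock_rate", LogUniformPrior(1e-10, 1e-4)),
            ("pop_size", LogUniformPrior(1e2, 1e9)),
        ]:
            logs = np.log(fit.samples(col))
            e = float(fit.ess(col))
            sem = logs.std(ddof=1) / np.sqrt(e)
            assert abs(logs.mean() - prior.mean_log) < 3 * sem


class TestSamplerContracts:
    def test_same_seed_identical_traces(self, small_dataset):
        b = small_dataset
        dates = tc.TipDateModel({t: tc.TipDate.fixed(a) for t, a in b.true_ages.items()})
        model = tc.TipDatingModel(b.alignment, dates, substitution=b.config.model)
        cfg = tc.MCMCConfig(chain_length=2_000, sample_every=10, seed=5)
        f1 = model.fit(cfg)
        f2 = model.fit(cfg)
        assert f1.trace.df.equals(f2.trace.df)
        assert f1.trees == f2.trees

    def test_posterior_equals_likelihood_plus_prior(self, small_dataset):
        b = small_dataset
        dates = tc.TipDateModel({t: tc.TipDate.fixed(a) for t, a in b.true_ages.items()})
        model = tc.TipDatingModel(b.alignment, dates, substitution=b.config.model)
        fit = model.fit(tc.MCMCConfig(chain_length=3_000, sample_every=10, seed=6))
        gap = fit.trace["posterior"] - (fit.trace["likelihood"] + fit.trace["prior"])
        assert np.max(np.abs(gap)) < 1e-6

    def test_sampled_trees_valid_with_fixed_tip_ages(self, small_dataset):
        b = small_dataset
        dates = tc.TipDateModel({t: tc.TipDate.fixed(a) for t, a in b.true_ages.items()})
        model = tc.TipDatingModel(b.alignment, dates, substitution=b.config.model)
        fit = model.fit(tc.MCMCConfig(chain_length=2_000, sample_every=100, seed=7))
        for nwk in fit.trees[::3]:
            tree = tc.TimeTree.from_newick(nwk, tip_ages=b.true_ages)
            tree.validate()
            for lab, age in tree.tip_ages().items():
                assert age == pytest.approx(b.true_ages[lab], abs=1e-3)

    def test_acceptance_rates_strictly_between_zero_and_one(self, small_dataset):
        b = small_dataset
        dates = tc.TipDateModel({t: tc.TipDate.fixed(a) for t, a in b.true_ages.items()})
        model = tc.TipDatingModel(b.alignment, dates, substitution=b.config.model)
        fit = model.fit(tc.MCMCConfig(chain_length=8_000, seed=8))
        for name, (acc, prop) in fit.acceptance.items():
            assert prop > 0, name
            assert 0 < acc < prop, name

    def test_estimated_tip_tracked_in_trace(self, small_dataset):
        b = small_dataset
        undated = b.samples.of_type("undated")[0].id
        dates = {t: tc.TipDate.fixed(a) for t, a in b.true_ages.items()}
        dates[undated] = tc.TipDate.gamma(2.0, 50_000.0)
        model = tc.TipDatingModel(b.alignment, tc.TipDateModel(dates), substitution=b.config.model)
        fit = model.fit(tc.MCMCConfig(chain_length=2_000, sample_every=10, seed=9))
        assert f"age_{undated}" in fit.trace.columns
        est = fit.age_estimate(undated)
        assert est.hpd95[0] <= est.median <= est.hpd95[1]
        assert (fit.samples(f"age_{undated}") >= 0).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            tc.MCMCConfig(chain_length=5, sample_every=10)
        with pytest.raises(ParameterError):
            tc.MCMCConfig(burnin_fraction=1.0)
        with pytest.raises(ParameterError):
            tc.MCMCConfig(operator_weights={"clock_rate": 0.0})

    def test_missing_tip_date_rejected(self):
        aln = tc.Alignment(["a", "b"], ["ACGT", "ACGT"])
        dates = tc.TipDateModel({"a": tc.TipDate.fixed(0.0)})
        with pytest.raises(ParameterError, match="no tip date"):
            tc.TipDatingModel(aln, dates)

    def test_summary_mentions_all_parameters(self, small_dataset):
        b = small_dataset
        dates = tc.TipDateModel({t: tc.TipDate.fixed(a) for t, a in b.true_ages.items()})
        model = tc.TipDatingModel(b.alignment, dates, substitution=b.config.model)
        fit = model.fit(tc.MCMCConfig(chain_length=1_000, sample_every=10, seed=10))
        text = fit.summary()
        for col in ("posterior", "clock_rate", "pop_size", "root_age"):
            assert col in text
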