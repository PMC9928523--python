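"""Synthetic-data generator: coalescent moments, clock divergence, pileups."""

import numpy as np
import pytest

import tipchron as tc
from tipchron.errors import ParameterError


class TestSerialCoalescent:
    def test_two_tip_expected_tmrca(self):
        ne = 10_000.0
        rng = np.random.default_rng(1)
        tmrcas = [
            tc.simulate_serial_coalescent_tree([0.0, 0.0], ne, rng).root_age
            for _ in range(2_000)
        ]
        assert abs(np.mean(tmrcas) - ne) < 700

    def test_ten_tip_expected_tmrca(self):
        # E[TMRCA] = 2 Ne (1 - 1/n)
        ne, n = 10_000.0, 10
        rng = np.random.default_rng(2)
        tmrcas = [
            tc.simulate_serial_coalescent_tree([0.0] * n, ne, rng).root_age
            for _ in range(2_000)
        ]
        assert abs(np.mean(tmrcas) - 2 * ne * (1 - 1 / n)) < 1_200

    def test_root_older_than_oldest_tip(self):
        for seed in range(20):
            tree = tc.simulate_serial_coalescent_tree([0.0, 50_000.0], 5_000.0, seed)
            assert tree.root_age > 50_000.0

    def test_single_tip_rejected(self):
        with pytest.raises(ParameterError):
            tc.simulate_serial_coalescent_tree([0.0], 1e4, 0)

    def test_trees_satisfy_invariants_and_are_seeded(self):
        ages = [0, 0, 1000, 20_000, 35_000]
        a = tc.simulate_serial_coalescent_tree(ages, 2e4, 42)
        b = tc.simulate_serial_coalescent_tree(ages, 2e4, 42)
        a.validate()
        assert a.to_newick() == b.to_newick()


class TestSequenceSimulation:
    def test_zero_rate_gives_identical_sequences(self):
        tree = tc.simulate_serial_coalescent_tree([0, 0, 5000], 1e4, 3)
        aln = tc.simulate_alignment(tree, 0.0, tc.SubstitutionModel(), 300, 3)
        assert len(set(aln.sequences)) == 1

    def test_jukes_cantor_divergence(self):
        # two tips, total path 0.02 subs/site under JC: expected p-distance
        # 3/4 (1 - exp(-4*0.02/3)) ~ 0.0197
        model = tc.SubstitutionModel(kappa=1.0, gamma_shape=1e6, n_categories=1)
        tree = tc.TimeTree([2, 2, -1], [0.0, 0.0, 10_000.0], ["a", "b"])
        rate = 1e-6  # 2 * 10000 * 1e-6 = 0.02 total path
        aln = tc.simulate_alignment(tree, rate, model, 100_000, 7)
        p = np.mean([x != y for x, y in zip(*aln.sequences)])
        expected = 0.75 * (1 - np.exp(-4 * 0.02 / 3))
        sd = np.sqrt(expected * (1 - expected) / aln.length)
        assert abs(p - expected) < 3 * sd

    def test_long_branch_reaches_stationarity(self):
        freqs = np.array([0.34, 0.26, 0.13, 0.27])
        model = tc.SubstitutionModel(kappa=4.0, base_freqs=freqs, gamma_shape=1e6, n_categories=1)
        tree = tc.TimeTree([2, 2, -1], [0.0, 0.0, 1e7], ["a", "b"])
        aln = tc.simulate_alignment(tree, 1e-6, model, 50_000, 11)  # 10 subs/site each branch
        counts = np.array([[s.count(b) for b in "ACGT"] for s in aln.sequences]).sum(axis=0)
        total = counts.sum()
        for obs, pi in zip(counts, freqs):
            sd = np.sqrt(total * pi * (1 - pi))
            assert abs(obs - total * pi) < 3 * sd

    def test_zero_length_rejected(self, three_tip_tree):
        with pytest.raises(ParameterError):
            tc.simulate_alignment(three_tip_tree, 1e-7, tc.SubstitutionModel(), 0, 1)


class TestPileups:
    def test_clean_reads_match_truth(self):
        truth = "ACGT" * 50
        p = tc.simulate_pileup(truth, 5.0, 0.0, 0.0, 9)
        for pos, base in enumerate(truth):
            cov = p.coverage[pos]
            assert p.counts[pos, "ACGT".index(base)] == cov

    def test_poisson_mean_coverage(self):
        p = tc.simulate_pileup("A" * 10_000, 8.0, 0.0, 0.0, 13)
        assert 7.7 <= p.coverage.mean() <= 8.3

    def test_consensus_recovers_truth_at_high_coverage(self):
        rng = np.random.default_rng(17)
        truth = "".join(rng.choice(list("ACGT"), 500))
        p = tc.simulate_pileup(truth, 30.0, 0.0, 0.0, 17)
        called = tc.call_consensus(p)
        covered = p.coverage >= 3
        assert all(c == t for c, t, ok in zip(called, truth, covered) if ok)

    def test_damage_produces_c_to_t_excess(self):
        p = tc.simulate_pileup("C" * 5_000, 10.0, 0.3, 0.0, 23)
        t_frac = p.counts[:, 3].sum() / p.counts.sum()
        assert 0.25 < t_frac < 0.35

    def test_negative_rates_rejected(self):
        with pytest.raises(ParameterError):
            tc.simulate_pileup("ACGT", 5.0, -0.1, 0.0, 1)


class TestStudyDataset:
    def test_dated_shape_mirrors_study(self):
        cfg = tc.SimulationConfig(n_tips=17, seed=4, tip_ages=[0.0] * 6 + list(np.linspace(3000, 45000, 11)))
        bundle = tc.make_study_like_dataset(cfg, 11)
        assert len(bundle.samples.of_type("radiocarbon")) == 11
        assert len(bundle.samples.of_type("modern")) == 6
        assert bundle.alignment.n_taxa == 17

    def test_same_seed_same_bundle(self):
        cfg = tc.SimulationConfig(n_tips=10, seq_length=200, seed=8)
        a = tc.make_study_like_dataset(cfg, 4)
        b = tc.make_study_like_dataset(cfg, 4)
        assert a.alignment.sequences == b.alignment.sequences
        assert a.tree.to_newick() == b.tree.to_newick()
        assert a.samples.to_frame().equals(b.samples.to_frame())

    def test_all_dated_rejected(self):
        cfg = tc.SimulationConfig(n_tips=10, seq_length=100, seed=8)
        with pytest.raises(ParameterError):
            tc.make_study_like_dataset(cfg, 10)

    def test_calibrated_medians_recover_true_ages(self):
        cfg = tc.SimulationConfig(n_tips=10, seq_length=100, seed=15)
        bundle = tc.make_study_like_dataset(cfg, 5)
        for rec in bundle.samples.of_type("radiocarbon"):
            cal = tc.calibrate_14c(rec.c14_age, rec.c14_error, bundle.curve)
            assert cal.median == pytest.approx(bundle.true_ages[rec.id], abs=15)
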