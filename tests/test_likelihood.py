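"""Pruning likelihood vs exhaustive internal-state enumeration."""

import itertools

import numpy as np
import pytest

import tipchron as tc
from tipchron.errors import ParameterError, TreeConstraintError
from tipchron.likelihood import CHAR_PARTIALS


def enumeration_loglik(aln, tree, clock_rate, model):
    """Brute force: sum over all internal-state assignments, per site."""
    cm = tree.children_map()
    n_tips = tree.n_tips
    internals = list(range(n_tips, tree.n_nodes))
    root = tree.root
    cat_rates = model.category_rates
    pmats = {}
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        if p >= 0:
            t = (tree.ages[p] - tree.ages[node]) * clock_rate
            pmats[node] = [tc.hky_transition_probs(t * r, model) for r in cat_rates]

    total = 0.0
    for site in range(aln.length):
        chars = [aln.sequences[i][site] for i in range(n_tips)]
        site_lik = 0.0
        for ci in range(len(cat_rates)):
            lik_c = 0.0
            for assignment in itertools.product(range(4), repeat=len(internals)):
                state = dict(zip(internals, assignment))
                term = model.base_freqs[state[root]]
                for node in range(tree.n_nodes):
                    p = tree.parent[node]
                    if p < 0:
                        continue
                    if node < n_tips:
                        compat = CHAR_PARTIALS[chars[node]]
                        term *= float(pmats[node][ci][state[p]] @ compat)
                    else:
                        term *= pmats[node][ci][state[p], state[node]]
                lik_c += term
            site_lik += lik_c / len(cat_rates)
        total += np.log(site_lik)
    return total


class TestTrivialCases:
    def test_two_identical_tips_zero_branches(self):
        tree = tc.TimeTree([2, 2, -1], [0.0, 0.0, 1e-12], ["a", "b"])
        aln = tc.Alignment(["a", "b"], ["A", "A"])
        model = tc.SubstitutionModel(base_freqs=np.array([0.4, 0.2, 0.2, 0.2]))
        ll = tc.tree_log_likelihood(aln, tree, 1e-12, model)
        assert ll == pytest.approx(np.log(0.4), abs=1e-6)

    def test_conflicting_tips_zero_branches_is_log_zero(self):
        tree = tc.TimeTree([2, 2, -1], [0.0, 0.0, 1e-12], ["a", "b"])
        aln = tc.Alignment(["a", "b"], ["A", "C"])
        ll = tc.tree_log_likelihood(aln, tree, 1e-12, tc.SubstitutionModel())
        assert ll < -20  # effectively log 0

    def test_label_mismatch_rejected(self, three_tip_tree):
        aln = tc.Alignment(["a", "b", "z"], ["A", "A", "A"])
        with pytest.raises(ParameterError, match="labels"):
            tc.tree_log_likelihood(aln, three_tip_tree, 1e-7, tc.SubstitutionModel())

    def test_child_older_than_parent_rejected(self):
        tree = tc.TimeTree([2, 2, -1], [0.0, 100.0, 500.0], ["a", "b"])
        tree.ages[1] = 800.0  # corrupt after construction
        aln = tc.Alignment(["a", "b"], ["A", "A"])
        with pytest.raises(TreeConstraintError):
            tc.tree_log_likelihood(aln, tree, 1e-7, tc.SubstitutionModel())


def random_time_tree(n_tips, rng):
    ages = rng.uniform(0, 30_000, n_tips)
    ages[rng.integers(n_tips)] = 0.0
    return tc.simulate_serial_coalescent_tree(ages, 50_000, rng), ages


class TestEnumerationOracle:
    @pytest.mark.parametrize("n_tips", [2, 3, 4, 5])
    def test_matches_brute_force(self, n_tips, rng):
        model = tc.SubstitutionModel(
            kappa=5.0, base_freqs=np.array([0.34, 0.26, 0.13, 0.27]), gamma_shape=0.4
        )
        tree, _ = random_time_tree(n_tips, rng)
        aln = tc.simulate_alignment(tree, 2e-7, model, 50, rng)
        fast = tc.tree_log_likelihood(aln, tree, 2e-7, model)
        slow = enumeration_loglik(aln, tree, 2e-7, model)
        assert fast == pytest.approx(slow, abs=1e-8)

    def test_with_ambiguity_and_gaps(self, rng):
        tree, _ = random_time_tree(4, rng)
        model = tc.SubstitutionModel()
        aln = tc.simulate_alignment(tree, 2e-7, model, 30, rng)
        seqs = [list(s) for s in aln.sequences]
        seqs[0][0] = "N"
        seqs[1][1] = "-"
        seqs[2][2] = "R"
        seqs[3][3] = "Y"
        aln = tc.Alignment(aln.taxa, ["".join(s) for s in seqs])
        fast = tc.tree_log_likelihood(aln, tree, 2e-7, model)
        slow = enumeration_loglik(aln, tree, 2e-7, model)
        assert fast == pytest.approx(slow, abs=1e-8)


class TestInvariances:
    def test_column_order_invariance(self, rng):
        tree, _ = random_time_tree(5, rng)
        model = tc.SubstitutionModel()
        aln = tc.simulate_alignment(tree, 3e-7, model, 200, rng)
        perm = rng.permutation(aln.length)
        shuffled = tc.Alignment(aln.taxa, ["".join(s[i] for i in perm) for s in aln.sequences])
        a = tc.tree_log_likelihood(aln, tree, 3e-7, model)
        b = tc.tree_log_likelihood(shuffled, tree, 3e-7, model)
        assert a == pytest.approx(b, abs=1e-9)

    def test_all_missing_sites_contribute_zero(self):
        tree = tc.TimeTree([2, 2, -1], [0.0, 1000.0, 5000.0], ["a", "b"])
        model = tc.SubstitutionModel()
        base = tc.Alignment(["a", "b"], ["ACGT", "ACGT"])
        padded = tc.Alignment(["a", "b"], ["ACGTNN--", "ACGTN-N-"])
        assert tc.tree_log_likelihood(padded, tree, 1e-7, model) == pytest.approx(
            tc.tree_log_likelihood(base, tree, 1e-7, model), abs=1e-9
        )

    def test_stable_for_long_alignments(self, rng):
        # 10 kb, 30 tips: finite, reproducible log-likelihood
        cfg = tc.SimulationConfig(n_tips=30, seq_length=10_000, seed=11,
                                  tip_ages=tc.default_tip_ages(30))
        b = tc.make_study_like_dataset(cfg, 8)
        model = cfg.model
        ll = tc.tree_log_likelihood(b.alignment, b.tree, cfg.clock_rate, model)
        assert np.isfinite(ll)
        assert ll < 0
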