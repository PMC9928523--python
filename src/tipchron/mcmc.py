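"""Metropolis-Hastings sampler over tree, clock rate, population size and
unknown tip ages.

One operator is drawn per iteration with probability proportional to its
weight.  Scale operators use multiplier proposals ``x' = x exp(l (u - 1/2))``
with Hastings ratio ``x'/x``; node-age moves redraw an internal node's age
uniformly between its oldest child and its parent (symmetric); topology is
sampled by narrow exchange; tip-age moves are reflected random walks on
``[0, parent age)``.  Proposal widths adapt toward 23.4% acceptance during
burn-in only and are frozen afterwards, preserving detailed balance for the
retained samples.

The sampler also runs *power posteriors*: the sequence likelihood enters
the target raised to ``power`` (beta in [0, 1]), which is what the
stepping-stone marginal-likelihood estimator needs.

Prior-only mode (``prior_only=True``) replaces both the sequence likelihood
and the genealogy density with zero and freezes the tree's internal nodes:
clock rate, population size and estimated tip ages are then sampled from
their marginal parameter priors, which gives analytically known moments for
validating the proposal machinery.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import CoalescentModel, coalescent_log_density
from .errors import ParameterError, TreeConstraintError
from .likelihood import PruningLikelihood
from .priors import GammaPrior, LogNormalPrior, LogUniformPrior, Prior
from .traceio import Trace
from .trees import TimeTree

TARGET_ACCEPT = 0.234


@dataclass
class TipDate:
    """Age specification for one tip: fixed, gamma-prior or lognormal-prior."""

    mode: str
    age: float | None = None
    shape: float | None = None
    scale: float | None = None
    ln_mu: float | None = None
    ln_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "fixed":
            if self.age is None or self.age < 0:
                raise ParameterError("fixed tip date needs age >= 0")
        elif self.mode == "gamma":
            if not (self.shape and self.scale) or self.shape <= 0 or self.scale <= 0:
                raise ParameterError("gamma tip date needs shape > 0 and scale > 0")
        elif self.mode == "lognormal":
            if self.ln_mu is None or not self.ln_sigma or self.ln_sigma <= 0:
                raise ParameterError("lognormal tip date needs ln_mu and ln_sigma > 0")
        else:
            raise ParameterError(f"unknown tip date mode '{self.mode}'")

    @classmethod
    def fixed(cls, age: float) -> "TipDate":
        return cls("fixed", age=age)

    @classmethod
    def gamma(cls, shape: float, scale: float) -> "TipDate":
        return cls("gamma", shape=shape, scale=scale)

    @classmethod
    def lognormal(cls, ln_mu: float, ln_sigma: float) -> "TipDate":
        return cls("lognormal", ln_mu=ln_mu, ln_sigma=ln_sigma)

    def prior(self) -> Prior | None:
        if self.mode == "gamma":
            return GammaPrior(self.shape, self.scale)
        if self.mode == "lognormal":
            return LogNormalPrior(self.ln_mu, self.ln_sigma)
        return None

    def initial_age(self) -> float:
        if self.mode == "fixed":
            return self.age
        return self.prior().median


class TipDateModel:
    """Per-tip age specifications for every tip in an analysis."""

    def __init__(self, dates: dict[str, TipDate]):
        self.dates = dict(dates)

    def __getitem__(self, tip: str) -> TipDate:
        return self.dates[tip]

    def __contains__(self, tip: str) -> bool:
        return tip in self.dates

    @property
    def estimated_tips(self) -> list[str]:
        return [t for t, d in self.dates.items() if d.mode != "fixed"]

    @property
    def fixed_tips(self) -> list[str]:
        return [t for t, d in self.dates.items() if d.mode == "fixed"]

    def check_taxa(self, taxa: list[str]) -> None:
        missing = sorted(set(taxa) - set(self.dates))
        if missing:
            raise ParameterError(f"no tip date specified for: {missing}")
        extra = sorted(set(self.dates) - set(taxa))
        if extra:
            raise ParameterError(f"tip dates for unknown taxa: {extra}")


def default_operator_weights(estimate_topology: bool, n_estimated_tips: int) -> dict[str, float]:
    weights = {
        "clock_rate": 1.0,
        "pop_size": 1.0,
        "node_ages": 3.0,
        "root_age": 1.0,
        # joint rate/height move along the rate-time ridge
        "rate_height": 2.0,
    }
    if estimate_topology:
        weights["narrow_exchange"] = 3.0
    if n_estimated_tips > 0:
        # a single free tip age gets the boosted weight used for
        # one-specimen-at-a-time dating runs
        weights["tip_ages"] = 5.0 if n_estimated_tips == 1 else float(n_estimated_tips)
        # occasional independence draws from the tip-age prior let the
        # chain jump between prior- and data-supported modes
        weights["tip_ages_prior"] = weights["tip_ages"] / 4.0
    return weights


@dataclass
class MCMCConfig:
    chain_length: int = 20000
    sample_every: int | None = None  # default: chain_length / 10000, min 1
    burnin_fraction: float = 0.1
    seed: int = 0
    operator_weights: dict[str, float] | None = None
    clock_rate_prior: Prior = field(default_factory=lambda: LogUniformPrior(1e-10, 1e-4))
    pop_size_prior: Prior = field(default_factory=lambda: LogUniformPrior(1e2, 1e9))
    estimate_topology: bool = True
    prior_only: bool = False
    power: float = 1.0
    init_clock_rate: float = 1e-7
    init_pop_size: float = 1e5

    def __post_init__(self) -> None:
        if self.sample_every is None:
            self.sample_every = max(1, self.chain_length // 10000)
        if self.chain_length < self.sample_every:
            raise ParameterError("chain_length must be >= sample_every")
        if not (0 <= self.burnin_fraction < 1):
            raise ParameterError("burnin_fraction must be in [0, 1)")
        if not (0 <= self.power <= 1):
            raise ParameterError("power (beta) must be in [0, 1]")
        if self.operator_weights is not None:
            for name, w in self.operator_weights.items():
                if w <= 0:
                    raise ParameterError(f"operator weight '{name}' must be > 0")

    def replace(self, **kwargs) -> "MCMCConfig":
        return dataclasses.replace(self, **kwargs)

    def digest(self) -> str:
        return hashlib.sha1(repr(self).encode()).hexdigest()[:12]


@dataclass
class MCMCOutput:
    trace: Trace
    trees: list[str]  # newick, same cadence as the trace
    acceptance: dict[str, tuple[int, int]]  # op -> (accepted, proposed)


class _TunableOp:
    def __init__(self, width: float):
        self.width = width
        self.accepted = 0
        self.proposed = 0
        self._adapt_count = 0

    def adapt(self, accepted: bool) -> None:
        self._adapt_count += 1
        step = 1.0 / (10 + self._adapt_count) ** 0.6
        self.width *= np.exp(step * ((1.0 if accepted else 0.0) - TARGET_ACCEPT))
        self.width = float(np.clip(self.width, 1e-8, 1e8))


class MCMCSampler:
    """The engine behind :meth:`tipchron.model.TipDatingModel.fit`."""

    def __init__(
        self,
        engine: PruningLikelihood | None,
        init_tree: TimeTree,
        tip_model: TipDateModel,
        config: MCMCConfig,
    ):
        self.config = config
        self.tree = init_tree.copy()
        self.tip_model = tip_model
        self.engine = engine
        tip_model.check_taxa(self.tree.labels)

        self.est_tip_idx = [self.tree.labels.index(t) for t in tip_model.estimated_tips]
        self.est_tip_priors = [tip_model[t].prior() for t in tip_model.estimated_tips]
        # pin fixed tips exactly
        for t in tip_model.fixed_tips:
            self.tree.ages[self.tree.labels.index(t)] = tip_model[t].age
        self.tree.validate()

        self.rng = np.random.default_rng(config.seed)
        self.clock_rate = config.init_clock_rate
        self.pop_size = config.init_pop_size

        n_internal_nonroot = self.tree.n_tips - 2
        weights = config.operator_weights
        if weights is None:
            weights = default_operator_weights(
                config.estimate_topology and not config.prior_only,
                len(self.est_tip_idx),
            )
        weights = dict(weights)
        if config.prior_only:
            weights.pop("node_ages", None)
            weights.pop("root_age", None)
            weights.pop("narrow_exchange", None)
            weights.pop("rate_height", None)
        if n_internal_nonroot == 0:
            weights.pop("node_ages", None)
            weights.pop("narrow_exchange", None)
        if not self.est_tip_idx:
            weights.pop("tip_ages", None)
            weights.pop("tip_ages_prior", None)
        if not weights:
            raise ParameterError("no applicable MCMC operators")
        self.op_names = sorted(weights)
        w = np.array([weights[n] for n in self.op_names])
        self.op_probs = w / w.sum()

        init_widths = {
            "clock_rate": 1.0,
            "pop_size": 1.0,
            "root_age": 0.7,
            "node_ages": 1.0,  # unused (uniform redraw), kept for bookkeeping
            "narrow_exchange": 1.0,
            "rate_height": 0.3,
            "tip_ages": 10000.0,
            "tip_ages_prior": 1.0,  # untuned independence sampler
        }
        self.ops = {name: _TunableOp(init_widths[name]) for name in self.op_names}

    # -- target evaluation -------------------------------------------------

    def _seq_loglik(self) -> float:
        if self.config.prior_only or self.engine is None:
            return 0.0
        return self.engine.loglik(self.tree, self.clock_rate)

    def _coal_logp(self) -> float:
        if self.config.prior_only:
            return 0.0
        return coalescent_log_density(self.tree, CoalescentModel(self.pop_size), validate=False)

    def _param_prior(self) -> float:
        lp = self.config.clock_rate_prior.log_pdf(self.clock_rate)
        lp += self.config.pop_size_prior.log_pdf(self.pop_size)
        for idx, prior in zip(self.est_tip_idx, self.est_tip_priors):
            lp += prior.log_pdf(self.tree.ages[idx])
        return lp

    # -- proposals ---------------------------------------------------------
    # Each returns (log_hastings, lik_changed, coal_changed, undo) or None
    # for an immediately invalid proposal (counted as rejected).

    def _propose_clock_rate(self, op):
        old = self.clock_rate
        factor = np.exp(op.width * (self.rng.random() - 0.5))
        self.clock_rate = old * factor

        def undo():
            self.clock_rate = old

        return np.log(factor), True, False, undo

    def _propose_pop_size(self, op):
        old = self.pop_size
        factor = np.exp(op.width * (self.rng.random() - 0.5))
        self.pop_size = old * factor

        def undo():
            self.pop_size = old

        return np.log(factor), False, True, undo

    def _propose_node_ages(self, op):
        tree = self.tree
        n = tree.n_tips
        candidates = [i for i in range(n, tree.n_nodes) if tree.parent[i] >= 0]
        node = candidates[self.rng.integers(len(candidates))]
        kids = tree.children_map()[node]
        lo = max(tree.ages[k] for k in kids)
        hi = tree.ages[tree.parent[node]]
        old = tree.ages[node]
        tree.ages[node] = self.rng.uniform(lo, hi)

        def undo():
            tree.ages[node] = old

        return 0.0, True, True, undo

    def _propose_root_age(self, op):
        tree = self.tree
        root = tree.root
        kids = tree.children_map()[root]
        base = max(tree.ages[k] for k in kids)
        old = tree.ages[root]
        x = old - base
        if x <= 0:
            return None
        factor = np.exp(op.width * (self.rng.random() - 0.5))
        tree.ages[root] = base + x * factor

        def undo():
            tree.ages[root] = old

        return np.log(factor), True, True, undo

    def _propose_rate_height(self, op):
        """Scale every internal node age by m and the clock rate by 1/m.

        Moves along the rate-time ridge that a strict clock induces.  The
        Jacobian of (n_internal ages, rate) -> m-scaled state gives a log
        Hastings ratio of (n_internal - 1) log m... minus one more for the
        rate, i.e. (n_tips - 2) log m in total.
        """
        tree = self.tree
        n = tree.n_tips
        factor = np.exp(op.width * (self.rng.random() - 0.5))
        old_ages = tree.ages[n:].copy()
        old_rate = self.clock_rate
        tree.ages[n:] = old_ages * factor
        self.clock_rate = old_rate / factor
        # validity: every internal node must stay older than all children
        cm = tree.children_map()
        for node in range(n, tree.n_nodes):
            if any(tree.ages[node] <= tree.ages[c] for c in cm[node]):
                tree.ages[n:] = old_ages
                self.clock_rate = old_rate
                return None

        def undo():
            tree.ages[n:] = old_ages
            self.clock_rate = old_rate

        n_internal = n - 1
        return (n_internal - 1) * np.log(factor), True, True, undo

    def _propose_narrow_exchange(self, op):
        tree = self.tree
        n = tree.n_tips
        root = tree.root
        candidates = [i for i in range(n, tree.n_nodes) if i != root]
        if not candidates:
            return None
        p = candidates[self.rng.integers(len(candidates))]
        g = int(tree.parent[p])
        g_kids = tree.children_map()[g]
        u = g_kids[0] if g_kids[1] == p else g_kids[1]
        if tree.ages[u] >= tree.ages[p]:
            return None
        p_kids = tree.children_map()[p]
        c = p_kids[self.rng.integers(2)]
        tree.parent[c] = g
        tree.parent[u] = p
        tree.invalidate_topology()

        def undo():
            tree.parent[c] = p
            tree.parent[u] = g
            tree.invalidate_topology()

        return 0.0, True, True, undo

    def _propose_tip_ages(self, op):
        tree = self.tree
        which = self.rng.integers(len(self.est_tip_idx))
        idx = self.est_tip_idx[which]
        old = tree.ages[idx]
        new = old + op.width * (self.rng.random() - 0.5) * 2.0
        if new < 0:
            new = -new  # reflect at the present
        if not self.config.prior_only and new >= tree.ages[tree.parent[idx]]:
            return None
        tree.ages[idx] = new

        def undo():
            tree.ages[idx] = old

        lik_changed = not self.config.prior_only
        return 0.0, lik_changed, lik_changed, undo

    def _propose_tip_ages_prior(self, op):
        """Independence proposal: redraw one estimated tip age from its
        prior; the Hastings ratio cancels the prior term exactly."""
        tree = self.tree
        which = self.rng.integers(len(self.est_tip_idx))
        idx = self.est_tip_idx[which]
        prior = self.est_tip_priors[which]
        old = tree.ages[idx]
        new = prior.sample(self.rng)
        if not self.config.prior_only and new >= tree.ages[tree.parent[idx]]:
            return None
        tree.ages[idx] = new

        def undo():
            tree.ages[idx] = old

        log_hastings = prior.log_pdf(old) - prior.log_pdf(new)
        lik_changed = not self.config.prior_only
        return log_hastings, lik_changed, lik_changed, undo

    # -- main loop ---------------------------------------------------------

    def run(self) -> MCMCOutput:
        cfg = self.config
        cur_lik = self._seq_loglik()
        cur_coal = self._coal_logp()
        cur_pp = self._param_prior()
        if not np.isfinite(cur_coal + cur_pp):
            raise TreeConstraintError("initial state has zero prior probability")

        proposers = {
            "clock_rate": self._propose_clock_rate,
            "pop_size": self._propose_pop_size,
            "node_ages": self._propose_node_ages,
            "root_age": self._propose_root_age,
            "rate_height": self._propose_rate_height,
            "narrow_exchange": self._propose_narrow_exchange,
            "tip_ages": self._propose_tip_ages,
            "tip_ages_prior": self._propose_tip_ages_prior,
        }

        n_burn = int(cfg.burnin_fraction * cfg.chain_length)
        rows = []
        trees: list[str] = []

        def record(state: int) -> None:
            row = {
                "state": state,
                "posterior": cfg.power * cur_lik + cur_coal + cur_pp,
                "likelihood": cur_lik,
                "prior": cur_coal + cur_pp,
                "clock_rate": self.clock_rate,
                "pop_size": self.pop_size,
                "root_age": self.tree.root_age,
            }
            for idx in self.est_tip_idx:
                row[f"age_{self.tree.labels[idx]}"] = self.tree.ages[idx]
            rows.append(row)
            trees.append(self.tree.to_newick(precision=6))

        record(0)
        for it in range(1, cfg.chain_length + 1):
            name = self.op_names[
                self.rng.choice(len(self.op_names), p=self.op_probs)
            ]
            op = self.ops[name]
            op.proposed += 1
            result = proposers[name](op)
            accepted = False
            if result is not None:
                log_hastings, lik_changed, coal_changed, undo = result
                new_lik = self._seq_loglik() if lik_changed else cur_lik
                new_coal = self._coal_logp() if coal_changed else cur_coal
                new_pp = self._param_prior()
                log_alpha = (
                    cfg.power * (new_lik - cur_lik)
                    + (new_coal - cur_coal)
                    + (new_pp - cur_pp)
                    + log_hastings
                )
                if log_alpha >= 0 or np.log(self.rng.random()) < log_alpha:
                    accepted = True
                    cur_lik, cur_coal, cur_pp = new_lik, new_coal, new_pp
                    op.accepted += 1
                else:
                    undo()
            if it <= n_burn:
                op.adapt(accepted)
            if it % cfg.sample_every == 0:
                record(it)

        df = pd.DataFrame(rows)
        trace = Trace(
            df,
            metadata={
                "seed": cfg.seed,
                "config": cfg.digest(),
                "power": cfg.power,
                "prior_only": cfg.prior_only,
                "topology": "estimated" if "narrow_exchange" in self.op_names else "fixed",
            },
        )
        acceptance = {n: (self.ops[n].accepted, self.ops[n].proposed) for n in self.op_names}
        return MCMCOutput(trace, trees, acceptance)
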