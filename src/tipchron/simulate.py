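"""Synthetic serially sampled data with known truth.

The generator emulates the statistical shape of an ancient-mitogenome
tip-dating study at desk scale: a heterochronous Kingman coalescent
genealogy over tips spanning the last glacial period, sequences evolved
under a strict clock with HKY+Gamma, pseudo-radiocarbon determinations for
a minority of the ancient tips, and pileup-level read observations (Poisson
coverage, uniform sequencing error, terminal-style C->T damage applied
uniformly) to exercise consensus calling.

Pseudo-14C ages are generated through an identity calibration curve
(mu(theta) = theta), so calibrated medians coincide with true ages by
construction and clock-inference error is isolated from calibration error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, SampleRecord, SampleTable
from .calcurve import CalCurve, make_identity_curve
from .consensus import Pileup
from .errors import ParameterError
from .substitution import STATES, SubstitutionModel, hky_transition_probs
from .trees import TimeTree


def default_tip_ages(n_tips: int, n_modern: int | None = None, max_age: float = 50_000.0) -> list[float]:
    """Study-shaped tip ages: a few modern (age 0) samples plus ancient tips
    spread evenly across the sampled interval."""
    if n_tips < 2:
        raise ParameterError("need at least 2 tips")
    if n_modern is None:
        n_modern = max(2, n_tips // 6)
    n_ancient = n_tips - n_modern
    if n_ancient < 1:
        raise ParameterError("need at least one ancient tip")
    ancient = np.linspace(max_age / n_ancient, max_age, n_ancient)
    return [0.0] * n_modern + [float(a) for a in ancient]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults give a 20-tip, 2 kb dataset spanning 0-50 kyr BP under a
    strict clock of 2e-7 substitutions/site/year on a constant coalescent
    background of Ne = 100 kyr, with aDNA-like pileups (mean coverage 8,
    0.5% sequencing error, 5% uniform C->T damage).
    """

    n_tips: int = 20
    tip_ages: list[float] | None = None
    pop_size: float = 100_000.0
    clock_rate: float = 2e-7
    seq_length: int = 2000
    model: SubstitutionModel = field(
        default_factory=lambda: SubstitutionModel(
            kappa=10.0, base_freqs=np.array([0.34, 0.26, 0.13, 0.27]), gamma_shape=0.5
        )
    )
    coverage_mean: float = 8.0
    damage_rate: float = 0.05
    error_rate: float = 0.005
    c14_error: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tip_ages is None:
            self.tip_ages = default_tip_ages(self.n_tips)
        if len(self.tip_ages) != self.n_tips:
            raise ParameterError("tip_ages length must equal n_tips")
        for name in ("pop_size", "clock_rate", "seq_length", "coverage_mean", "c14_error"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("damage_rate", "error_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ParameterError(f"{name} must be in [0, 1]")


def simulate_serial_coalescent_tree(tip_ages, pop_size: float, seed) -> TimeTree:
    """Simulate a heterochronous Kingman genealogy.

    Lineages activate at their sampling ages; with k active lineages the
    next coalescence occurs after an Exp(k(k-1)/(2 Ne)) waiting time, capped
    by the next sampling event.  ``seed`` may be an int or a Generator.
    """
    ages = np.asarray(tip_ages, dtype=float)
    n = len(ages)
    if n < 2:
        raise ParameterError("need at least 2 tips to coalesce")
    if pop_size <= 0:
        raise ParameterError("pop_size must be > 0")
    if np.any(ages < 0):
        raise ParameterError("tip ages must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    order = np.argsort(ages, kind="stable")
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    node_ages = np.zeros(2 * n - 1)
    node_ages[:n] = ages

    pending = list(order)  # tips not yet sampled, by increasing age
    active: list[int] = []
    t = float(ages[order[0]])
    next_internal = n
    while next_internal < 2 * n - 1:
        # admit all tips sampled at or before the current time
        while pending and ages[pending[0]] <= t:
            active.append(int(pending.pop(0)))
        k = len(active)
        t_next = ages[pending[0]] if pending else np.inf
        if k >= 2:
            wait = rng.exponential(2.0 * pop_size / (k * (k - 1)))
            if t + wait <= t_next:
                t += wait
                i, j = rng.choice(k, size=2, replace=False)
                a, b = active[i], active[j]
                node = next_internal
                next_internal += 1
                parent[a] = node
                parent[b] = node
                node_ages[node] = t
                active = [x for x in active if x not in (a, b)] + [node]
                continue
        if not pending:  # k < 2 and nothing left to sample: cannot happen
            raise ParameterError("simulation stalled before full coalescence")
        t = float(t_next)
    return TimeTree(parent, node_ages, [f"t{i}" for i in range(n)])


def _draw_states(probs_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized categorical draw: one row of probabilities per site."""
    cum = np.cumsum(probs_rows, axis=1)
    u = rng.random(probs_rows.shape[0])
    return (u[:, None] > cum).sum(axis=1)


def simulate_alignment(
    tree: TimeTree,
    clock_rate: float,
    model: SubstitutionModel,
    seq_length: int,
    seed,
) -> Alignment:
    """Evolve sequences down ``tree`` under the strict clock.

    The root sequence is drawn from the stationary frequencies; each site
    keeps one discrete-gamma rate category along the whole tree.
    """
    if seq_length < 1:
        raise ParameterError("seq_length must be >= 1")
    if clock_rate < 0:
        raise ParameterError("clock_rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    k = model.n_categories
    cat_rates = model.category_rates
    site_cat = rng.integers(k, size=seq_length)
    states = np.empty((tree.n_nodes, seq_length), dtype=np.int8)
    root = tree.root
    states[root] = _draw_states(
        np.broadcast_to(model.base_freqs, (seq_length, 4)), rng
    )

    for node in tree.postorder()[::-1]:  # preorder
        p = tree.parent[node]
        if p < 0:
            continue
        dt = (tree.ages[p] - tree.ages[node]) * clock_rate
        pmats = hky_transition_probs(dt * cat_rates, model)  # (k, 4, 4)
        rows = pmats[site_cat, states[p]]  # (sites, 4)
        states[node] = _draw_states(rows, rng)

    seqs = ["".join(STATES[s] for s in states[i]) for i in range(tree.n_tips)]
    return Alignment(list(tree.labels), seqs)


def simulate_pileup(
    true_seq: str,
    coverage_mean: float,
    damage_rate: float,
    error_rate: float,
    seed,
) -> Pileup:
    """Simulate per-site read counts over a known sequence.

    Reads per site are Poisson(coverage_mean); each read independently
    suffers a uniform sequencing error with probability ``error_rate`` and,
    if it then shows C, converts to T with probability ``damage_rate``.
    Sites whose true base is ambiguous contribute reads drawn uniformly from
    the compatible bases.
    """
    if coverage_mean < 0 or damage_rate < 0 or error_rate < 0:
        raise ParameterError("rates must be non-negative")
    if damage_rate > 1 or error_rate > 1:
        raise ParameterError("rates must be <= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    from .alignment import AMBIGUITY

    base_idx = {b: i for i, b in enumerate(STATES)}
    length = len(true_seq)
    counts = np.zeros((length, 4), dtype=np.int64)
    depths = rng.poisson(coverage_mean, size=length)
    for pos, (truth, n_reads) in enumerate(zip(true_seq, depths)):
        if n_reads == 0:
            continue
        compatible = AMBIGUITY.get(truth, "ACGT")
        reads = rng.choice([base_idx[b] for b in compatible], size=n_reads)
        err = rng.random(n_reads) < error_rate
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum()))
            reads[err] = (reads[err] + shift) % 4
        is_c = reads == base_idx["C"]
        if is_c.any():
            dmg = rng.random(int(is_c.sum())) < damage_rate
            reads[np.flatnonzero(is_c)[dmg]] = base_idx["T"]
        np.add.at(counts[pos], reads, 1)
    return Pileup(counts)


@dataclass
class StudyDataset:
    """A simulated dataset bundle with its generating truth."""

    alignment: Alignment
    samples: SampleTable
    tree: TimeTree
    true_ages: dict[str, float]
    curve: CalCurve
    config: SimulationConfig


def make_study_like_dataset(config: SimulationConfig, n_dated: int) -> StudyDataset:
    """Simulate a full study-shaped input bundle.

    ``n_dated`` ancient tips receive pseudo-radiocarbon determinations
    (14C age = true age +/- the configured error through an identity
    calibration curve); the remaining ancient tips are "undated"; tips of
    age 0 are "modern".  Truth (tree and ages) is retained for scoring.
    """
    if n_dated >= config.n_tips:
        raise ParameterError("n_dated must be smaller than n_tips")
    if n_dated < 0:
        raise ParameterError("n_dated must be >= 0")
    rng = np.random.default_rng(config.seed)
    tree = simulate_serial_coalescent_tree(config.tip_ages, config.pop_size, rng)
    aln = simulate_alignment(tree, config.clock_rate, config.model, config.seq_length, rng)

    ancient = [i for i, a in enumerate(config.tip_ages) if a > 0]
    if n_dated > len(ancient):
        raise ParameterError(f"only {len(ancient)} ancient tips available for dating")
    dated = set(rng.choice(ancient, size=n_dated, replace=False).tolist())

    records = []
    for i, label in enumerate(tree.labels):
        age = float(tree.ages[i])
        if age == 0:
            records.append(SampleRecord(label, "simulated", "modern"))
        elif i in dated:
            records.append(
                SampleRecord(label, "simulated", "radiocarbon", c14_age=age, c14_error=config.c14_error)
            )
        else:
            records.append(SampleRecord(label, "simulated", "undated"))
    curve = make_identity_curve(0.0, max(config.tip_ages) * 3 + 10 * config.c14_error, step=10.0, sigma=1.0)
    true_ages = {label: float(tree.ages[i]) for i, label in enumerate(tree.labels)}
    return StudyDataset(aln, SampleTable(records), tree, true_ages, curve, config)
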