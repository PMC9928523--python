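"""Model/Results interface for Bayesian tip-dating.

:class:`TipDatingModel` binds an alignment, per-tip age specifications and
the evolutionary model (HKY+Gamma strict clock over a constant-size
heterochronous coalescent); :meth:`TipDatingModel.fit` runs the MCMC
sampler and returns a :class:`TipDatingResults` carrying the trace, sampled
trees, operator acceptance statistics, and diagnostic summaries (ESS, HPD
intervals, per-tip age estimates with the ESS >= 200 convergence flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .alignment import Alignment
from .calcurve import CalCurve, calibrate_14c
from .diagnostics import ess, hpd_interval
from .errors import ParameterError
from .likelihood import PruningLikelihood
from .mcmc import MCMCConfig, MCMCOutput, MCMCSampler, TipDate, TipDateModel
from .substitution import SubstitutionModel
from .traceio import Trace
from .trees import TimeTree

CONVERGENCE_ESS = 200.0  # ESS threshold below which an estimate is flagged


@dataclass
class AgeEstimate:
    """Posterior summary for one tip's age."""

    tip_id: str
    median: float
    hpd95: tuple[float, float]
    ess: float
    converged: bool

    def __post_init__(self) -> None:
        lo, hi = self.hpd95
        if not (lo <= self.median <= hi):
            raise ParameterError("median must lie inside its HPD interval")
        if self.ess < 0:
            raise ParameterError("ess must be >= 0")


def _pairwise_jc_distances(aln: Alignment) -> np.ndarray:
    """Jukes-Cantor-corrected pairwise distances; ambiguity treated as missing."""
    plain = {"A": 0, "C": 1, "G": 2, "T": 3}
    coded = np.full((aln.n_taxa, aln.length), -1, dtype=np.int8)
    for i, seq in enumerate(aln.sequences):
        for j, ch in enumerate(seq):
            if ch in plain:
                coded[i, j] = plain[ch]
    n = aln.n_taxa
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (coded[i] >= 0) & (coded[j] >= 0)
            m = ok.sum()
            p = float(np.mean(coded[i][ok] != coded[j][ok])) if m else 0.0
            p = min(p, 0.70)  # guard the JC correction against saturation
            d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            dist[i, j] = dist[j, i] = d
    return dist


def starting_tree(aln: Alignment, tip_ages: dict[str, float], init_clock_rate: float = 1e-7) -> TimeTree:
    """A rough UPGMA-based time tree used to initialize the sampler.

    Topology comes from average-linkage clustering of JC distances; internal
    node ages are the linkage heights converted through the initial clock
    rate, pushed up wherever needed so that every parent is strictly older
    than its children.
    """
    n = aln.n_taxa
    if n < 2:
        raise ParameterError("need at least 2 taxa")
    ages = np.zeros(2 * n - 1)
    for i, t in enumerate(aln.taxa):
        if t not in tip_ages:
            raise ParameterError(f"no age for taxon '{t}'")
        ages[i] = tip_ages[t]
    if n == 2:
        parent = np.array([2, 2, -1])
        ages[2] = max(ages[0], ages[1]) * 1.1 + max(1000.0, 0.1 * (ages[:2].max() + 1000.0))
        return TimeTree(parent, ages, list(aln.taxa))

    dist = _pairwise_jc_distances(aln)
    linkage = average(squareform(dist, checks=False))
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    eps = max(1.0, 0.01 * (ages[:n].max() + 1.0))
    for row in range(n - 1):
        a, b, height, _ = linkage[row]
        node = n + row
        a, b = int(a), int(b)
        parent[a] = node
        parent[b] = node
        ages[node] = max(
            height / 2.0 / init_clock_rate,
            ages[a] + eps,
            ages[b] + eps,
        )
    return TimeTree(parent, ages, list(aln.taxa))


class TipDatingModel:
    """Bayesian tip-dating model for a serially sampled alignment.

    Parameters
    ----------
    alignment : Alignment
        The sequence data; every taxon needs an entry in ``tip_dates``.
    tip_dates : TipDateModel
        Per-tip age specification: ``fixed`` (radiocarbon-calibrated median
        or 0 for modern samples), ``gamma`` or ``lognormal`` prior for tips
        whose age is estimated.
    substitution : SubstitutionModel, optional
        Defaults to HKY with kappa 2, equal frequencies, Gamma(0.5) in 4
        categories.
    init_tree : TimeTree, optional
        Starting genealogy; by default a UPGMA guess is built from the data.
    """

    def __init__(
        self,
        alignment: Alignment,
        tip_dates: TipDateModel,
        substitution: SubstitutionModel | None = None,
        init_tree: TimeTree | None = None,
    ):
        self.alignment = alignment
        self.tip_dates = tip_dates
        tip_dates.check_taxa(alignment.taxa)
        self.substitution = substitution if substitution is not None else SubstitutionModel()
        self.init_tree = init_tree
        self._engine: PruningLikelihood | None = None

    @classmethod
    def from_sample_table(
        cls,
        alignment: Alignment,
        samples,
        curve: CalCurve | None = None,
        undated_priors: dict[str, TipDate] | None = None,
        default_undated: TipDate | None = None,
        **kwargs,
    ) -> "TipDatingModel":
        """Build a model from sample metadata.

        Radiocarbon tips enter as fixed point ages at the median of their
        calibrated density (``curve`` required if any are present); modern
        tips are fixed at 0; undated tips take their prior from
        ``undated_priors`` or ``default_undated`` (the single-specimen
        default is Gamma(shape=2, scale=50000)).
        """
        samples.check_against(alignment)
        if default_undated is None:
            default_undated = TipDate.gamma(2.0, 50_000.0)
        dates: dict[str, TipDate] = {}
        for rec in samples:
            if rec.date_type == "modern":
                dates[rec.id] = TipDate.fixed(0.0)
            elif rec.date_type == "radiocarbon":
                if curve is None:
                    raise ParameterError("a calibration curve is required for radiocarbon samples")
                cal = calibrate_14c(rec.c14_age, rec.c14_error, curve)
                dates[rec.id] = TipDate.fixed(cal.median)
            else:
                if undated_priors and rec.id in undated_priors:
                    dates[rec.id] = undated_priors[rec.id]
                else:
                    dates[rec.id] = default_undated
        extra = set(alignment.taxa) - set(dates)
        if extra:
            raise ParameterError(f"alignment taxa missing from sample table: {sorted(extra)}")
        return cls(alignment, TipDateModel(dates), **kwargs)

    def _build_init_tree(self, config: MCMCConfig) -> TimeTree:
        if self.init_tree is not None:
            tree = self.init_tree.copy()
            # overwrite tip ages with the model's initial values
            for i, t in enumerate(tree.labels):
                tree.ages[i] = self.tip_dates[t].initial_age()
            _repair_ages(tree)
            return tree
        init_ages = {t: self.tip_dates[t].initial_age() for t in self.alignment.taxa}
        return starting_tree(self.alignment, init_ages, config.init_clock_rate)

    def engine(self) -> PruningLikelihood:
        if self._engine is None:
            self._engine = PruningLikelihood(self.alignment, self.substitution)
        return self._engine

    def fit(self, config: MCMCConfig | None = None, **overrides) -> "TipDatingResults":
        """Run the MCMC sampler and return results.

        Keyword overrides are applied on top of ``config`` (or the default
        configuration), e.g. ``model.fit(chain_length=50000, seed=7)``.
        """
        config = (config or MCMCConfig()).replace(**overrides) if overrides else (config or MCMCConfig())
        engine = None if config.prior_only else self.engine()
        sampler = MCMCSampler(engine, self._build_init_tree(config), self.tip_dates, config)
        output = sampler.run()
        return TipDatingResults(self, config, output)


def _repair_ages(tree: TimeTree) -> None:
    """Push internal node ages up where tip-age edits broke the ordering."""
    cm = tree.children_map()
    eps = max(1.0, 0.001 * (tree.ages.max() + 1.0))
    for node in tree.postorder():
        if node < tree.n_tips:
            continue
        top = max(tree.ages[c] for c in cm[node])
        if tree.ages[node] <= top:
            tree.ages[node] = top + eps
    tree.validate()


class TipDatingResults:
    """Posterior sample from a tip-dating run, with diagnostics."""

    def __init__(self, model: TipDatingModel, config: MCMCConfig, output: MCMCOutput):
        self.model = model
        self.config = config
        self.trace: Trace = output.trace
        self.trees: list[str] = output.trees
        self.acceptance = output.acceptance

    @property
    def posterior_trace(self) -> Trace:
        """The trace with the configured burn-in removed."""
        return self.trace.burned_in(self.config.burnin_fraction)

    def samples(self, column: str) -> np.ndarray:
        return self.posterior_trace[column]

    def ess(self, column: str):
        return ess(self.samples(column))

    def hpd(self, column: str, mass: float = 0.95) -> tuple[float, float]:
        return hpd_interval(self.samples(column), mass)

    def median(self, column: str) -> float:
        return float(np.median(self.samples(column)))

    def age_estimate(self, tip_id: str) -> AgeEstimate:
        column = f"age_{tip_id}"
        if column not in self.trace.df.columns:
            raise ParameterError(f"tip '{tip_id}' has no estimated age in this run")
        x = self.samples(column)
        e = ess(x)
        lo, hi = hpd_interval(x, 0.95)
        med = float(np.median(x))
        med = min(max(med, lo), hi)
        return AgeEstimate(tip_id, med, (lo, hi), float(e.ess), bool(e.ess >= CONVERGENCE_ESS))

    def age_estimates(self) -> list[AgeEstimate]:
        return [self.age_estimate(t) for t in self.model.tip_dates.estimated_tips]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for col in self.trace.columns:
            x = self.samples(col)
            e = ess(x)
            if e.degenerate:
                lo = hi = float(x[0]) if len(x) else float("nan")
            else:
                lo, hi = hpd_interval(x, 0.95)
            rows.append(
                {
                    "parameter": col,
                    "mean": float(np.mean(x)),
                    "median": float(np.median(x)),
                    "hpd95_low": lo,
                    "hpd95_high": hi,
                    "ess": e.ess,
                    "converged": bool(e.ess >= CONVERGENCE_ESS),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable run summary."""
        df = self.summary_frame()
        lines = [
            "Tip-dating MCMC summary",
            f"  chain length {self.config.chain_length}, "
            f"sampled every {self.config.sample_every}, "
            f"burn-in {self.config.burnin_fraction:.0%}, seed {self.config.seed}",
            f"  topology: {self.trace.metadata.get('topology', '?')}; "
            f"power beta = {self.config.power:g}; prior-only: {self.config.prior_only}",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.6g}"),
            "",
            "operator acceptance:",
        ]
        for name, (acc, prop) in self.acceptance.items():
            rate = acc / prop if prop else float("nan")
            lines.append(f"  {name:16s} {acc:>7d}/{prop:<7d} ({rate:.3f})")
        return "\n".join(lines)

    def plot_trace(self, columns=None, axes=None):
        import matplotlib.pyplot as plt

        columns = list(columns) if columns else ["posterior", "clock_rate", "root_age"]
        if axes is None:
            _, axes = plt.subplots(len(columns), 1, figsize=(7, 2.2 * len(columns)), sharex=True)
        axes = np.atleast_1d(axes)
        states = self.posterior_trace["state"]
        for ax, col in zip(axes, columns):
            ax.plot(states, self.samples(col), lw=0.6)
            ax.set_ylabel(col)
        axes[-1].set_xlabel("state")
        return axes


def run_mcmc(
    aln: Alignment,
    init_tree: TimeTree,
    tip_model: TipDateModel,
    config: MCMCConfig,
    substitution: SubstitutionModel | None = None,
) -> TipDatingResults:
    """Functional wrapper: fit a tip-dating model from explicit pieces."""
    model = TipDatingModel(aln, tip_model, substitution=substitution, init_tree=init_tree)
    return model.fit(config)
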