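"""Heterochronous constant-size Kingman coalescent tree prior.

Time runs into the past in years BP.  Tips enter the process at their
sampling ages; with k active lineages each pair coalesces at rate
``1 / Ne`` (total rate ``k (k-1) / (2 Ne)``), where ``Ne`` is the effective
population size pre-multiplied by generation time, in years.  The density
of a labelled genealogy is the product over coalescent events of ``1/Ne``
times the exponential of minus the integrated pairwise coalescent rate over
every inter-event interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, TreeConstraintError
from .trees import TimeTree


@dataclass
class CoalescentModel:
    """Constant-through-time effective population size, in years."""

    pop_size: float

    def __post_init__(self) -> None:
        if self.pop_size <= 0:
            raise ParameterError("pop_size must be > 0")


def coalescent_log_density(tree: TimeTree, coal: CoalescentModel, validate: bool = True) -> float:
    """Log density of ``tree`` under the serial-sampling Kingman coalescent.

    ``validate=False`` skips the full tree-invariant check (the MCMC sampler
    only ever proposes valid trees and calls this on every iteration).
    """
    if validate:
        tree.validate()
    ne = coal.pop_size
    n = tree.n_tips
    ages = tree.ages
    # events sorted by age; at ties, sampling events activate before coalescences
    kind = np.zeros(tree.n_nodes, dtype=np.int8)
    kind[n:] = 1
    order = np.lexsort((kind, ages))
    t_sorted = ages[order]
    k_sorted = kind[order]
    # active lineage count just after each event
    k_after = np.cumsum(1 - 2 * k_sorted.astype(np.int64))
    if np.any((k_sorted == 1) & (k_after < 1)):
        raise TreeConstraintError("coalescence with fewer than 2 active lineages")
    dt = np.diff(t_sorted)
    pair_rate = k_after[:-1] * (k_after[:-1] - 1) / 2.0
    return float(-(pair_rate * dt).sum() / ne - (n - 1) * np.log(ne))
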