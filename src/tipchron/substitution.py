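"""Nucleotide substitution model: HKY with discrete-gamma rate variation.

States are indexed A=0, C=1, G=2, T=3.  Transition probabilities use the
closed-form HKY solution (the Tamura–Nei solution with both transition
classes equal), with the rate matrix normalized so that one unit of branch
length corresponds to one expected substitution per site at stationarity.
Branch lengths handed to :func:`hky_transition_probs` are therefore
``(years elapsed) x (clock rate in substitutions/site/year)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .errors import ParameterError

STATES = "ACGT"
PURINES = (0, 2)  # A, G
PYRIMIDINES = (1, 3)  # C, T


@dataclass
class SubstitutionModel:
    """HKY+Gamma site model.

    Parameters
    ----------
    kappa : float
        Transition/transversion rate ratio (> 0).
    base_freqs : array-like of 4 floats
        Stationary frequencies (A, C, G, T); must be positive and sum to 1.
    gamma_shape : float
        Shape of the gamma distribution of among-site rate multipliers.
    n_categories : int
        Number of equiprobable discrete rate categories (>= 1).
    """

    kappa: float = 2.0
    base_freqs: np.ndarray = field(
        default_factory=lambda: np.array([0.25, 0.25, 0.25, 0.25])
    )
    gamma_shape: float = 0.5
    n_categories: int = 4

    def __post_init__(self) -> None:
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if self.kappa <= 0:
            raise ParameterError("kappa must be > 0")
        if self.base_freqs.shape != (4,):
            raise ParameterError("base_freqs must have length 4")
        if np.any(self.base_freqs <= 0):
            raise ParameterError("base frequencies must be positive")
        if abs(self.base_freqs.sum() - 1.0) > 1e-12:
            raise ParameterError("base frequencies must sum to 1 within 1e-12")
        if self.gamma_shape <= 0:
            raise ParameterError("gamma_shape must be > 0")
        if self.n_categories < 1:
            raise ParameterError("n_categories must be >= 1")

    @property
    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)


def _hky_scale(kappa: float, freqs: np.ndarray) -> float:
    """Normalizing constant beta such that the mean substitution rate is 1."""
    pi_a, pi_c, pi_g, pi_t = freqs
    pi_r = pi_a + pi_g
    pi_y = pi_c + pi_t
    return 1.0 / (2.0 * (pi_r * pi_y + kappa * (pi_a * pi_g + pi_c * pi_t)))


def hky_transition_probs(t, model: SubstitutionModel) -> np.ndarray:
    """HKY transition-probability matrices P(t).

    ``t`` is branch length in expected substitutions per site; it may be a
    scalar or an array, in which case the result has shape ``t.shape + (4, 4)``.
    Entry ``[i, j]`` is the probability of ending in state j given start i.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ParameterError("branch length t must be >= 0")

    pi = model.base_freqs
    pi_a, pi_c, pi_g, pi_t = pi
    pi_r = pi_a + pi_g
    pi_y = pi_c + pi_t
    beta = _hky_scale(model.kappa, pi)
    alpha = model.kappa * beta

    e2 = np.exp(-beta * t_arr)  # transversion decay
    e_r = np.exp(-(pi_r * alpha + pi_y * beta) * t_arr)  # within purines
    e_y = np.exp(-(pi_y * alpha + pi_r * beta) * t_arr)  # within pyrimidines

    out = np.empty(t_arr.shape + (4, 4), dtype=float)
    for i in range(4):
        i_purine = i in PURINES
        for j in range(4):
            j_purine = j in PURINES
            if i_purine != j_purine:
                out[..., i, j] = pi[j] * (1.0 - e2)
            elif j_purine:
                out[..., i, j] = (
                    pi[j]
                    + pi[j] * (pi_y / pi_r) * e2
                    + (((i == j) * pi_r - pi[j]) / pi_r) * e_r
                )
            else:
                out[..., i, j] = (
                    pi[j]
                    + pi[j] * (pi_r / pi_y) * e2
                    + (((i == j) * pi_y - pi[j]) / pi_y) * e_y
                )
    return out


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of k equiprobable bands of a mean-1 gamma distribution.

    The gamma has shape ``alpha`` and scale ``1/alpha``.  Category i covers
    the quantile band [i/k, (i+1)/k]; its rate is the conditional mean of the
    distribution within the band, computed from the incomplete-gamma identity
    ``E[X; X<=b] = mean * F_{alpha+1}(b)``.  The k rates are renormalized to
    average exactly 1.
    """
    if k < 1:
        raise ParameterError("number of categories must be >= 1")
    if alpha <= 0:
        raise ParameterError("gamma shape must be > 0")
    if k == 1:
        return np.array([1.0])
    scale = 1.0 / alpha
    bounds = _gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=scale)
    cdf_up = np.concatenate([_gamma_dist.cdf(bounds, a=alpha + 1, scale=scale), [1.0]])
    cdf_lo = np.concatenate([[0.0], cdf_up[:-1]])
    rates = k * (cdf_up - cdf_lo)  # mean within band / band mass (=1/k)
    return rates / rates.mean()
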