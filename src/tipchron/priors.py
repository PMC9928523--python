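"""Prior distributions for clock rate, population size and tip ages."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError


class Prior:
    def log_pdf(self, x: float) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def sample(self, rng: np.random.Generator) -> float:  # pragma: no cover
        raise NotImplementedError


@dataclass
class LogUniformPrior(Prior):
    """Uniform on log(x) over [lo, hi]; weakly informative scale prior."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ParameterError("log-uniform prior needs 0 < lo < hi")
        self._log_norm = np.log(np.log(self.hi / self.lo))

    def log_pdf(self, x: float) -> float:
        if x < self.lo or x > self.hi:
            return -np.inf
        return -np.log(x) - self._log_norm

    def sample(self, rng: np.random.Generator) -> float:
        return float(np.exp(rng.uniform(np.log(self.lo), np.log(self.hi))))

    @property
    def mean_log(self) -> float:
        return 0.5 * (np.log(self.lo) + np.log(self.hi))

    @property
    def var_log(self) -> float:
        return (np.log(self.hi) - np.log(self.lo)) ** 2 / 12.0


@dataclass
class GammaPrior(Prior):
    """Gamma(shape, scale); the tip-age prior used for undated specimens is
    Gamma(shape=2, scale=50000) years, mean 100 kyr."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ParameterError("gamma prior needs shape > 0 and scale > 0")

    def log_pdf(self, x: float) -> float:
        # direct formula: called once per MCMC iteration
        if x < 0:
            return -np.inf
        if x == 0:
            return -np.inf if self.shape > 1 else float(stats.gamma.logpdf(0, a=self.shape, scale=self.scale))
        return (
            (self.shape - 1) * math.log(x)
            - x / self.scale
            - self.shape * math.log(self.scale)
            - math.lgamma(self.shape)
        )

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.gamma(self.shape, self.scale))

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def var(self) -> float:
        return self.shape * self.scale**2

    @property
    def median(self) -> float:
        return float(stats.gamma.median(a=self.shape, scale=self.scale))


@dataclass
class LogNormalPrior(Prior):
    """Lognormal with given mean/sd of log(x) (natural log)."""

    ln_mu: float
    ln_sigma: float

    def __post_init__(self) -> None:
        if self.ln_sigma <= 0:
            raise ParameterError("lognormal prior needs ln_sigma > 0")

    def log_pdf(self, x: float) -> float:
        if x <= 0:
            return -np.inf
        z = (math.log(x) - self.ln_mu) / self.ln_sigma
        return -math.log(x) - math.log(self.ln_sigma) - 0.5 * math.log(2 * math.pi) - 0.5 * z * z

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.lognormal(self.ln_mu, self.ln_sigma))

    @property
    def mean(self) -> float:
        return float(np.exp(self.ln_mu + self.ln_sigma**2 / 2))

    @property
    def median(self) -> float:
        return float(np.exp(self.ln_mu))
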