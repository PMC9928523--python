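"""MCMC trace diagnostics: effective sample size and HPD intervals.

ESS follows the initial-monotone-sequence estimator: the integrated
autocorrelation time is ``tau = -1 + 2 * sum_k G_k`` over pair sums
``G_k = rho_{2k} + rho_{2k+1}``, truncated at the first non-positive pair
sum and forced non-increasing; ESS = n / tau, capped at n.  This matches
the convention used by BEAST-family tools whose ESS >= 200 rule of thumb is
adopted as the convergence flag throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError


def _autocorrelation(x: np.ndarray) -> np.ndarray:
    """Biased-normalization autocorrelation via FFT."""
    n = len(x)
    x = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    return acov / acov[0]


@dataclass
class EssResult:
    ess: float
    degenerate: bool = False

    def __float__(self) -> float:
        return float(self.ess)


def ess(samples) -> EssResult:
    """Effective sample size of one trace column.

    A constant (zero-variance) column is flagged degenerate with ESS 0.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 10:
        raise ParameterError("ESS needs at least 10 samples")
    if np.ptp(x) == 0 or not np.isfinite(x).all():
        return EssResult(0.0, degenerate=True)
    rho = _autocorrelation(x)
    # Geyer pair sums with initial-monotone truncation
    n_pairs = n // 2
    pair = rho[0 : 2 * n_pairs : 2] + rho[1 : 2 * n_pairs : 2]
    tau = -1.0
    prev = np.inf
    for g in pair:
        if g <= 0:
            break
        g = min(g, prev)
        prev = g
        tau += 2.0 * g
    tau = max(tau, 1.0)
    return EssResult(min(float(n), n / tau))


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` samples."""
    if not (0 < mass < 1):
        raise ParameterError("mass must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 2:
        raise ParameterError("HPD needs at least 2 samples")
    k = int(np.ceil(mass * n))
    k = min(k, n)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]
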