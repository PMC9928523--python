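"""Radiocarbon calibration against an IntCal20-format curve.

A calibration curve maps calendar age theta (cal BP) to the expected
radiocarbon determination mu(theta) with curve error sigma(theta).  A lab
determination ``age +/- error`` is calibrated by evaluating, on a yearly
calendar grid, the likelihood

    L(theta) ∝ exp(-(age - mu(theta))^2 / (2 (error^2 + sigma(theta)^2)))
               / sqrt(error^2 + sigma(theta)^2)

and normalizing it into a posterior density over calendar years (a uniform
calendar-age prior).  Ranges are reported at 95.4% as highest-density
regions, the radiocarbon community's conventional "2-sigma" level.  No
reservoir corrections or outlier models are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, ParameterError


@dataclass
class CalCurve:
    """Calibration-curve grid: calendar years BP vs 14C age and error."""

    cal_bp: np.ndarray
    c14_age: np.ndarray
    c14_sigma: np.ndarray

    def __post_init__(self) -> None:
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.c14_age = np.asarray(self.c14_age, dtype=float)
        self.c14_sigma = np.asarray(self.c14_sigma, dtype=float)
        if not (len(self.cal_bp) == len(self.c14_age) == len(self.c14_sigma)):
            raise FormatError("calibration-curve columns must have equal length")
        if len(self.cal_bp) < 2:
            raise FormatError("calibration curve needs at least 2 grid points")
        if np.any(np.diff(self.cal_bp) <= 0):
            raise FormatError("cal_bp grid must be strictly increasing")
        if np.any(self.c14_sigma <= 0):
            raise FormatError("curve errors must be positive")

    def interpolate(self, step: float = 1.0) -> "CalCurve":
        """Linear interpolation onto a regular grid of the given step (years)."""
        grid = np.arange(self.cal_bp[0], self.cal_bp[-1] + step / 2, step)
        return CalCurve(
            grid,
            np.interp(grid, self.cal_bp, self.c14_age),
            np.interp(grid, self.cal_bp, self.c14_sigma),
        )

    def __len__(self) -> int:
        return len(self.cal_bp)


def read_calibration_curve(path, interpolate_to_year: bool = False) -> CalCurve:
    """Read an IntCal20-dialect comma-separated curve.

    Lines starting with ``#`` are comments; data rows are
    ``CAL BP, 14C age, Error[, ...]`` (only the first three columns are
    used).  Rows may appear in either order; the result is sorted ascending
    in cal BP.
    """
    cal, age, err = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 comma-separated columns")
            try:
                row = [float(p) for p in parts[:3]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
            if row[2] <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive curve error {row[2]}")
            cal.append(row[0])
            age.append(row[1])
            err.append(row[2])
    if not cal:
        raise FormatError(f"empty curve: no data rows in {path}")
    order = np.argsort(cal)
    curve = CalCurve(np.array(cal)[order], np.array(age)[order], np.array(err)[order])
    return curve.interpolate(1.0) if interpolate_to_year else curve


def write_calibration_curve(curve: CalCurve, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("# CAL BP, 14C age, Error\n")
        for c, a, e in zip(curve.cal_bp, curve.c14_age, curve.c14_sigma):
            fh.write(f"{c:.1f},{a:.1f},{e:.4g}\n")


def make_identity_curve(lo: float, hi: float, step: float = 10.0, sigma: float = 1.0) -> CalCurve:
    """Synthetic curve with mu(theta) = theta; useful when calibrated medians
    should coincide with true calendar ages by construction."""
    grid = np.arange(lo, hi + step / 2, step)
    return CalCurve(grid, grid.copy(), np.full(len(grid), float(sigma)))


@dataclass
class CalibratedDate:
    """Posterior of a calibrated radiocarbon determination on a yearly grid."""

    grid: np.ndarray
    density: np.ndarray
    ranges_95: list[tuple[float, float]] = field(default_factory=list)
    median: float = float("nan")

    def mass_in_ranges(self) -> float:
        mass = 0.0
        for lo, hi in self.ranges_95:
            mask = (self.grid >= lo) & (self.grid <= hi)
            mass += float(self.density[mask].sum())
        return mass

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(self.grid, self.density, color="0.6")
        for lo, hi in self.ranges_95:
            ax.axvspan(lo, hi, color="tab:blue", alpha=0.15)
        ax.axvline(self.median, color="tab:red", lw=1)
        ax.set_xlabel("calendar age (cal BP)")
        ax.set_ylabel("posterior density / yr")
        ax.invert_xaxis()
        return ax


def _hdr_intervals(grid: np.ndarray, density: np.ndarray, mass: float) -> list[tuple[float, float]]:
    """Highest-density region: greedily accumulate grid cells by density."""
    order = np.argsort(density)[::-1]
    cum = np.cumsum(density[order])
    k = int(np.searchsorted(cum, mass)) + 1
    member = np.zeros(len(grid), dtype=bool)
    member[order[:k]] = True
    intervals = []
    start = None
    for i, m in enumerate(member):
        if m and start is None:
            start = i
        elif not m and start is not None:
            intervals.append((float(grid[start]), float(grid[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(grid[start]), float(grid[-1])))
    return intervals


def calibrate_14c(age: float, error: float, curve: CalCurve, mass: float = 0.954) -> CalibratedDate:
    """Calibrate a 14C determination ``age +/- error`` (years BP).

    Returns the calendar-age posterior on a 1-year grid with its median and
    disjoint highest-density ranges covering at least ``mass`` posterior
    probability (default 95.4%).
    """
    if error <= 0:
        raise ParameterError("14C error must be > 0")
    if not (0 < mass < 1):
        raise ParameterError("mass must be in (0, 1)")
    lo, hi = curve.c14_age.min(), curve.c14_age.max()
    if age < lo - 5 * error or age > hi + 5 * error:
        raise ParameterError(
            f"determination {age} +/- {error} lies outside calibration range "
            f"[{lo:.0f}, {hi:.0f}] 14C yr BP"
        )
    fine = curve.interpolate(1.0)
    var = error**2 + fine.c14_sigma**2
    log_like = -((age - fine.c14_age) ** 2) / (2 * var) - 0.5 * np.log(var)
    log_like -= log_like.max()
    density = np.exp(log_like)
    total = density.sum()
    if total == 0 or not np.isfinite(total):
        raise ParameterError("calibration produced a degenerate density")
    density /= total

    cdf = np.cumsum(density)
    median = float(fine.cal_bp[int(np.searchsorted(cdf, 0.5))])
    ranges = _hdr_intervals(fine.cal_bp, density, mass)
    return CalibratedDate(fine.cal_bp, density, ranges, median)
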