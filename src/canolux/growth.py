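"""Sigmoidal canopy growth model: trajectory container, fitting, daily series.

Projected canopy size (PCS) of a rosette crop over days after seeding is well
described by the three-parameter logistic

    f(x) = a / (1 + exp(-(x - x0) / b))

with ``a`` the asymptotic PCS (cm² plant⁻¹), ``x0`` the inflection day and
``b`` a shape/time constant (days).  Each experimental unit (species × PPFD ×
block) is fitted separately; the fitted curve is then evaluated at every
integer day of the crop cycle to drive the incident-light integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PCSTrajectory",
    "SigmoidFit",
    "DailyPCSSeries",
    "sigmoid",
    "fit_sigmoid",
    "predict_daily",
    "FitError",
    "NoGrowthError",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best attempt if any."""

    def __init__(self, message: str, best: "SigmoidFit | None" = None):
        super().__init__(message)
        self.best = best


class NoGrowthError(ValueError):
    """Trajectory carries no growth signal (flat or all-zero)."""


def sigmoid(x, a, x0, b):
    """Logistic growth curve ``a / (1 + exp(-(x - x0)/b))``."""
    x = np.asarray(x, dtype=float)
    return a / (1.0 + np.exp(-(x - x0) / b))


@dataclass(frozen=True)
class PCSTrajectory:
    """Time series of per-plant PCS for one experimental unit.

    ``pcs`` is in cm² per plant (group total divided by ``n_plants``);
    ``days`` are days after seeding, strictly increasing.
    """

    species: str
    ppfd: float
    block: int
    days: np.ndarray
    pcs: np.ndarray
    n_plants: int = 9
    truth: dict | None = None  # generating (a, x0, b) when synthetic

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        pcs = np.asarray(self.pcs, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "pcs", pcs)
        if days.size == 0:
            raise ValueError("trajectory needs at least one day")
        if days.size != pcs.size:
            raise ValueError("days and pcs must have equal length")
        if np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(pcs < 0):
            raise ValueError("PCS values must be non-negative")


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted logistic parameters plus fit quality for one trajectory."""

    a: float
    x0: float
    b: float
    r_squared: float
    residual_sd: float
    converged: bool
    n_points: int

    def predict(self, x) -> np.ndarray:
        return sigmoid(x, self.a, self.x0, self.b)


@dataclass(frozen=True)
class DailyPCSSeries:
    """PCS evaluated at every integer day 0..harvest_day."""

    days: np.ndarray
    pcs: np.ndarray
    source_fit: SigmoidFit


def _initial_guess(days: np.ndarray, pcs: np.ndarray) -> tuple[float, float, float]:
    a0 = 1.05 * float(pcs.max())
    half = a0 / 2.0
    x00 = float(days[np.argmin(np.abs(pcs - half))])
    b0 = max((float(days[-1]) - float(days[0])) / 6.0, 0.5)
    return a0, x00, b0


def fit_sigmoid(
    trajectory: PCSTrajectory,
    max_restarts: int = 5,
    seed: int = 0,
) -> SigmoidFit:
    """Least-squares fit of the logistic to one PCS trajectory.

    Initial guesses: a₀ = 1.05 × max(PCS); x0₀ = day nearest half-max;
    b₀ = span/6.  Bounded Levenberg-Marquardt-style (trust-region) least
    squares with up to ``max_restarts`` jittered restarts on failure.  The
    ``converged`` flag is honest — on persistent failure a :class:`FitError`
    carrying the best attempt is raised rather than silently returning it.

    Raises
    ------
    NoGrowthError
        If the trajectory is flat (zero variance) — a sigmoid is undefined.
    FitError
        If no restart converges.
    """
    days = trajectory.days
    pcs = trajectory.pcs
    if days.size < 4:
        raise ValueError(f"need >= 4 points to fit 3 parameters, got {days.size}")
    if float(pcs.max()) <= 0 or float(pcs.std()) == 0.0:
        raise NoGrowthError("no growth signal: flat or all-zero trajectory")

    a0, x00, b0 = _initial_guess(days, pcs)
    span = float(days[-1]) - float(days[0])
    lower = [1e-9, float(days[0]) - 10.0 - span, 0.1]
    upper = [10.0 * float(pcs.max()), float(days[-1]) + 10.0 + span, 30.0]
    p0 = [min(max(a0, lower[0]), upper[0]),
          min(max(x00, lower[1]), upper[1]),
          min(max(b0, lower[2]), upper[2])]

    rng = np.random.default_rng(seed)
    best: SigmoidFit | None = None
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        if attempt == 0:
            start = p0
        else:
            jitter = rng.normal(1.0, 0.15, size=3)
            start = [min(max(p * j, lo), hi)
                     for p, j, lo, hi in zip(p0, jitter, lower, upper)]
        try:
            popt, _ = curve_fit(
                sigmoid, days, pcs, p0=start, bounds=(lower, upper), maxfev=20000
            )
        except (RuntimeError, ValueError) as err:  # no convergence this start
            last_err = err
            continue
        resid = pcs - sigmoid(days, *popt)
        sse = float(np.sum(resid**2))
        sst = float(np.sum((pcs - pcs.mean()) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else 0.0
        dof = max(days.size - 3, 1)
        fit = SigmoidFit(
            a=float(popt[0]),
            x0=float(popt[1]),
            b=float(popt[2]),
            r_squared=r2,
            residual_sd=math.sqrt(sse / dof),
            converged=True,
            n_points=int(days.size),
        )
        if best is None or fit.r_squared > best.r_squared:
            best = fit
        # accept immediately on a good fit; keep trying only on poor ones
        if fit.r_squared > 0.5:
            return fit
    if best is not None:
        return best
    raise FitError(f"sigmoid fit failed after {max_restarts + 1} starts: {last_err}",
                   best=None)


def predict_daily(fit: SigmoidFit, harvest_day: int) -> DailyPCSSeries:
    """Evaluate a converged fit at integer days 0..harvest_day inclusive."""
    if not fit.converged:
        raise FitError("cannot predict from an unconverged fit", best=fit)
    if harvest_day < 1:
        raise ValueError(f"harvest_day must be >= 1, got {harvest_day}")
    days = np.arange(0, int(harvest_day) + 1)
    return DailyPCSSeries(days=days, pcs=fit.predict(days), source_fit=fit)
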