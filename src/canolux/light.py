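"""Light treatments, daily light integrals and per-plant incident-light budgets.

A treatment is characterised by the photosynthetic photon flux density
(PPFD, µmol m⁻² s⁻¹) measured at the centre of the growing area and the
photoperiod (h d⁻¹).  The daily light integral (DLI, mol m⁻² d⁻¹) follows by
unit conversion.  Combining the DLI with a daily projected-canopy-size (PCS)
series yields the light incident on one plant's canopy footprint per day, and
the sum over the crop cycle gives the total incident light (mol plant⁻¹) that
denominates light use efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .growth import DailyPCSSeries

__all__ = [
    "LightTreatment",
    "IncidentLightResult",
    "compute_dli",
    "integrate_incident_light",
    "MEASURED_PPFDS",
    "NOMINAL_PPFDS",
    "default_treatments",
]

#: Mean measured PPFDs at the tray centre for the six light treatments
#: (µmol m⁻² s⁻¹).  Calculations use these; the round nominal labels
#: (50 … 425) are display-only.
MEASURED_PPFDS: tuple[float, ...] = (53.0, 128.0, 210.0, 281.0, 345.0, 410.0)

#: Nominal set-point labels for the same six treatments.
NOMINAL_PPFDS: tuple[float, ...] = (50.0, 125.0, 200.0, 275.0, 350.0, 425.0)

_SECONDS_PER_HOUR = 3600.0
_UMOL_PER_MOL = 1e6
_CM2_PER_M2 = 1e4


def compute_dli(ppfd: float, photoperiod_h: float) -> float:
    """Daily light integral in mol m⁻² d⁻¹.

    ``dli = ppfd × photoperiod × 3600 / 10⁶`` — exact arithmetic, no
    rounding.

    Parameters
    ----------
    ppfd:
        Photosynthetic photon flux density, µmol m⁻² s⁻¹ (≥ 0).
    photoperiod_h:
        Hours of light per day, in (0, 24].
    """
    if ppfd < 0:
        raise ValueError(f"ppfd must be >= 0, got {ppfd}")
    if not 0 < photoperiod_h <= 24:
        raise ValueError(f"photoperiod must be in (0, 24] h, got {photoperiod_h}")
    return ppfd * photoperiod_h * _SECONDS_PER_HOUR / _UMOL_PER_MOL


@dataclass(frozen=True)
class LightTreatment:
    """One light treatment: PPFD at tray centre and photoperiod.

    ``dli`` is derived on construction and always consistent with the
    other two fields.
    """

    ppfd: float
    photoperiod_h: float = 16.0
    nominal_ppfd: float | None = None

    def __post_init__(self) -> None:
        # compute_dli validates ppfd and photoperiod
        compute_dli(self.ppfd, self.photoperiod_h)

    @property
    def dli(self) -> float:
        """Daily light integral, mol m⁻² d⁻¹."""
        return compute_dli(self.ppfd, self.photoperiod_h)

    @property
    def label(self) -> float:
        """Display label: the nominal PPFD if given, else the measured one."""
        return self.nominal_ppfd if self.nominal_ppfd is not None else self.ppfd


def default_treatments(photoperiod_h: float = 16.0) -> tuple[LightTreatment, ...]:
    """The six standard treatments (measured PPFDs, 16-h photoperiod)."""
    return tuple(
        LightTreatment(ppfd=m, photoperiod_h=photoperiod_h, nominal_ppfd=n)
        for m, n in zip(MEASURED_PPFDS, NOMINAL_PPFDS)
    )


@dataclass(frozen=True)
class IncidentLightResult:
    """Per-plant incident light derived from a daily PCS series.

    ``daily_incident[d]`` is the light intercepted by the canopy footprint on
    day ``d`` (mol plant⁻¹ d⁻¹); ``total_incident`` is the sum over days
    0..harvest_day inclusive (mol plant⁻¹).
    """

    days: np.ndarray
    daily_incident: np.ndarray
    total_incident: float
    harvest_day: int
    dli: float

    def __post_init__(self) -> None:
        if np.any(self.daily_incident < 0):
            raise ValueError("daily incident light must be non-negative")


def integrate_incident_light(
    series: "DailyPCSSeries", treatment: LightTreatment
) -> IncidentLightResult:
    """Integrate per-plant incident light over the growing cycle.

    Each day's PCS (cm² plant⁻¹) is converted to m² and multiplied by the
    treatment DLI to give that day's incident light; the total is the plain
    sum of the daily values over days 0..harvest_day — discrete daily
    summation, not continuous quadrature.
    """
    dli = treatment.dli
    pcs_m2 = np.asarray(series.pcs, dtype=float) / _CM2_PER_M2
    daily = pcs_m2 * dli
    return IncidentLightResult(
        days=np.asarray(series.days, dtype=int),
        daily_incident=daily,
        total_incident=float(daily.sum()),
        harvest_day=int(series.days[-1]),
        dli=dli,
    )
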