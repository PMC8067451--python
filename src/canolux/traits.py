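"""Harvest-derived traits: light use efficiency, specific leaf area, overlap.

All three traits are simple quotients of harvest measurements:

* LUE  = shoot dry weight / total incident light     (g mol⁻¹)
* SLA  = leaf area / shoot dry weight                (cm² g⁻¹)
* canopy overlap ratio = leaf area / PCS at harvest  (dimensionless, ≥ 1
  whenever leaves overlap; values < 1 are flagged, not rejected)

Traits are computed at the experimental-unit level (a group of nine plants),
never per individual plant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "TraitRecord",
    "compute_lue",
    "compute_sla",
    "compute_overlap_ratio",
    "build_trait_table",
]

log = logging.getLogger(__name__)


def compute_lue(dry_weight_g: float, total_incident_mol: float) -> float:
    """Light use efficiency: g of shoot dry weight per mol of incident light."""
    if total_incident_mol <= 0:
        raise ValueError(
            f"total incident light must be > 0 mol, got {total_incident_mol}"
        )
    if dry_weight_g < 0:
        raise ValueError(f"dry weight must be >= 0 g, got {dry_weight_g}")
    return dry_weight_g / total_incident_mol


def compute_sla(leaf_area_cm2: float, dry_weight_g: float) -> float:
    """Specific leaf area: leaf area per gram of shoot dry weight (cm² g⁻¹)."""
    if dry_weight_g <= 0:
        raise ValueError(f"dry weight must be > 0 g, got {dry_weight_g}")
    if leaf_area_cm2 < 0:
        raise ValueError(f"leaf area must be >= 0 cm², got {leaf_area_cm2}")
    return leaf_area_cm2 / dry_weight_g


def compute_overlap_ratio(leaf_area_cm2: float, pcs_at_harvest_cm2: float) -> float:
    """Canopy overlap ratio: total leaf area over projected canopy size.

    A ratio ≥ 1 means leaves overlie each other within the canopy footprint
    (intra-canopy shading).  Ratios < 1 are physically odd but can arise from
    measurement error; they are logged as warnings and returned as-is.
    """
    if pcs_at_harvest_cm2 <= 0:
        raise ValueError(f"PCS at harvest must be > 0 cm², got {pcs_at_harvest_cm2}")
    if leaf_area_cm2 < 0:
        raise ValueError(f"leaf area must be >= 0 cm², got {leaf_area_cm2}")
    ratio = leaf_area_cm2 / pcs_at_harvest_cm2
    if ratio < 1.0:
        log.warning("canopy overlap ratio %.3f < 1 (leaf area %.1f, PCS %.1f)",
                    ratio, leaf_area_cm2, pcs_at_harvest_cm2)
    return ratio


@dataclass(frozen=True)
class TraitRecord:
    """All harvest-derived quantities for one experimental unit."""

    species: str
    ppfd: float
    block: int
    dry_weight_g: float
    leaf_area_cm2: float
    pcs_at_harvest_cm2: float
    total_incident_mol: float
    lue: float
    sla: float
    overlap_ratio: float


def build_trait_table(
    harvest: pd.DataFrame,
    incident: pd.DataFrame,
    pcs_at_harvest: pd.DataFrame,
) -> pd.DataFrame:
    """Join harvest records with incident light and harvest-day PCS and
    compute LUE, SLA and the overlap ratio per experimental unit.

    Parameters
    ----------
    harvest:
        Columns ``species, ppfd, block, leaf_area_cm2, dry_weight_g``
        (per-plant values).
    incident:
        Columns ``species, ppfd, block, total_incident_mol``.
    pcs_at_harvest:
        Columns ``species, ppfd, block, pcs_at_harvest_cm2`` — by default the
        sigmoid prediction at the harvest day, for consistency with the daily
        incident-light series.
    """
    keys = ["species", "ppfd", "block"]
    df = harvest.merge(incident, on=keys, validate="one_to_one")
    df = df.merge(pcs_at_harvest, on=keys, validate="one_to_one")
    df["lue_g_mol"] = [
        compute_lue(dw, ti)
        for dw, ti in zip(df["dry_weight_g"], df["total_incident_mol"])
    ]
    df["sla_cm2_g"] = [
        compute_sla(la, dw)
        for la, dw in zip(df["leaf_area_cm2"], df["dry_weight_g"])
    ]
    df["overlap_ratio"] = [
        compute_overlap_ratio(la, pcs)
        for la, pcs in zip(df["leaf_area_cm2"], df["pcs_at_harvest_cm2"])
    ]
    return df
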