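"""Segmentation of top-down canopy images into projected canopy size.

Bright plant tissue against a dark background (the contrast a chlorophyll
fluorescence imaging setup produces) is separated by intensity thresholding:
Otsu's method on the histogram by default, or a fixed threshold for
reproducibility across batches.  Speckle smaller than ``min_object_px`` is
removed.  The projected canopy size (PCS) per plant is the total foreground
area divided by the number of plants in the group — plants are not
individually delineated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .growth import PCSTrajectory

__all__ = [
    "CanopyImage",
    "SegmentationResult",
    "SegmentationError",
    "segment_canopy",
    "build_trajectories",
    "load_manifest",
    "segment_manifest",
]


class SegmentationError(ValueError):
    """Raised when an image cannot be meaningfully segmented."""


@dataclass(frozen=True)
class CanopyImage:
    """A single-channel top-down canopy image with its metadata.

    ``pixel_scale`` is the isotropic ground sampling distance in cm per
    pixel; ``capture_day`` counts days after seeding (day 0 = seeding).
    """

    pixels: np.ndarray
    pixel_scale: float
    capture_day: int
    species: str = ""
    ppfd: float = float("nan")
    block: int = 0
    n_plants: int = 9

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if np.any(px < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_scale <= 0:
            raise ValueError(f"pixel_scale must be > 0, got {self.pixel_scale}")
        if self.capture_day < 0:
            raise ValueError(f"capture_day must be >= 0, got {self.capture_day}")
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class SegmentationResult:
    """Binary mask plus derived areas for one canopy image."""

    mask: np.ndarray
    foreground_pixels: int
    total_area_cm2: float
    pcs_per_plant_cm2: float
    threshold_used: float
    method: str
    image: CanopyImage

    def __post_init__(self) -> None:
        if not 0 <= self.foreground_pixels <= self.mask.size:
            raise ValueError("foreground pixel count out of range")


def segment_canopy(
    image: CanopyImage,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    min_object_px: int = 25,
) -> SegmentationResult:
    """Threshold an image into plant / background and measure the PCS.

    The mask is ``pixels > threshold`` with 8-connected components smaller
    than ``min_object_px`` removed.  ``total_area = foreground_pixels ×
    pixel_scale²`` and ``pcs_per_plant = total_area / n_plants``.

    Raises
    ------
    SegmentationError
        Under ``method='otsu'`` on a blank image (zero intensity range):
        there is no bimodality to threshold, and silently returning zero
        area would hide a acquisition failure.
    """
    px = image.pixels
    if method == "otsu":
        if float(px.max()) == float(px.min()):
            raise SegmentationError(
                "no bimodality: image has zero intensity range"
            )
        threshold = float(threshold_otsu(px))
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        threshold = float(fixed_threshold)
    else:
        raise ValueError(f"unknown method {method!r}; use 'otsu' or 'fixed'")

    mask = px > threshold
    if min_object_px > 0:
        mask = remove_small_objects(mask, max_size=min_object_px - 1,
                                    connectivity=2)
    fg = int(mask.sum())
    total = fg * image.pixel_scale**2
    return SegmentationResult(
        mask=mask,
        foreground_pixels=fg,
        total_area_cm2=total,
        pcs_per_plant_cm2=total / image.n_plants,
        threshold_used=threshold,
        method=method,
        image=image,
    )


def build_trajectories(results: list[SegmentationResult]) -> list[PCSTrajectory]:
    """Group segmentation results into per-unit PCS time series.

    One trajectory per (species, PPFD, block), sorted by capture day.
    Duplicate (unit, day) pairs are an error — each unit is imaged once per
    imaging day.
    """
    groups: dict[tuple, list[SegmentationResult]] = {}
    for r in results:
        key = (r.image.species, r.image.ppfd, r.image.block)
        groups.setdefault(key, []).append(r)
    out = []
    for (species, ppfd, block), rs in groups.items():
        rs = sorted(rs, key=lambda r: r.image.capture_day)
        days = [r.image.capture_day for r in rs]
        if len(set(days)) != len(days):
            raise ValueError(
                f"duplicate capture day for unit ({species}, {ppfd}, {block})"
            )
        out.append(PCSTrajectory(
            species=species,
            ppfd=ppfd,
            block=block,
            days=np.asarray(days, dtype=float),
            pcs=np.asarray([r.pcs_per_plant_cm2 for r in rs]),
            n_plants=rs[0].image.n_plants,
        ))
    return out


def load_manifest(manifest_csv: str | Path) -> list[CanopyImage]:
    """Load images listed in a manifest CSV.

    Required columns: ``path, species, ppfd, block, day, pixel_scale_cm,
    n_plants``; ``path`` is relative to the manifest's directory.
    """
    manifest_csv = Path(manifest_csv)
    df = pd.read_csv(manifest_csv)
    base = manifest_csv.parent
    images = []
    for row in df.itertuples(index=False):
        px = iio.imread(base / row.path)
        if px.ndim == 3:  # tolerate accidental RGB saves of greyscale data
            px = px[..., 0]
        images.append(CanopyImage(
            pixels=np.asarray(px),
            pixel_scale=float(row.pixel_scale_cm),
            capture_day=int(row.day),
            species=str(row.species),
            ppfd=float(row.ppfd),
            block=int(row.block),
            n_plants=int(row.n_plants),
        ))
    return images


def segment_manifest(
    manifest_csv: str | Path,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    min_object_px: int = 25,
) -> pd.DataFrame:
    """Segment every image in a manifest; return the long-format PCS table.

    Columns: ``species, ppfd, block, day, pcs_cm2_per_plant,
    threshold_used``.
    """
    rows = []
    for image in load_manifest(manifest_csv):
        res = segment_canopy(image, method=method,
                             fixed_threshold=fixed_threshold,
                             min_object_px=min_object_px)
        rows.append({
            "species": image.species,
            "ppfd": image.ppfd,
            "block": image.block,
            "day": image.capture_day,
            "pcs_cm2_per_plant": res.pcs_per_plant_cm2,
            "threshold_used": res.threshold_used,
        })
    return pd.DataFrame(rows).sort_values(
        ["species", "ppfd", "block", "day"]
    ).reset_index(drop=True)
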