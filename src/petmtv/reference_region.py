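"""Liver / aorta reference-VOI statistics and the PERCIST threshold.

The PERCIST-style baseline segmentation threshold is derived from a
reference region: a cuboid VOI of volume 3 cm³ in the right lobe of the
liver, or — when the liver is extensively involved by lymphoma — a
1 × 1 × 2 cm VOI in the descending thoracic aorta.  The threshold is

    T = multiplier × mean_SUV + sd_factor × SD_SUV

with defaults multiplier = 1.5, sd_factor = 2.0; multiplier = 1.0 encodes
the exploratory (over-sensitive) variant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .image_model import BoxVOI, EmptyVOIError, SUVImage, voi_values

__all__ = [
    "ReferenceStats",
    "PercistConfig",
    "ReferenceVOIError",
    "LIVER_VOI_EDGE_MM",
    "AORTA_VOI_SIZE_MM",
    "liver_stats",
    "aorta_stats",
    "percist_threshold",
    "choose_reference",
    "load_reference_annotations",
]

#: Edge of the cubic liver VOI: the protocol specifies only the volume
#: (3 cm³), so the default is a cube of that volume, edge 3000^(1/3) mm.
LIVER_VOI_EDGE_MM: float = 3000.0 ** (1.0 / 3.0)

#: Fixed aorta VOI: 1 × 1 × 2 cm.
AORTA_VOI_SIZE_MM: Tuple[float, float, float] = (10.0, 10.0, 20.0)


class ReferenceVOIError(ValueError):
    """Reference VOI out of bounds or containing fewer than 2 voxels."""


@dataclass(frozen=True)
class ReferenceStats:
    """Mean/SD SUV of a reference VOI and its provenance."""

    mean_suv: float
    sd_suv: float
    site: str  # "liver" | "aorta"
    n_voxels: int

    def __post_init__(self):
        if self.site not in ("liver", "aorta"):
            raise ValueError(f"site must be 'liver' or 'aorta', got {self.site!r}")
        if self.sd_suv < 0:
            raise ValueError("sd_suv must be >= 0")
        if self.n_voxels < 2:
            raise ValueError("n_voxels must be >= 2 (SD undefined below 2)")


@dataclass(frozen=True)
class PercistConfig:
    """Constants of the reference-region threshold.

    ``sd_ddof=1`` uses the sample (n−1) SD; 0 gives the population SD for
    parity with vendor software whose convention is unknown.
    """

    multiplier: float = 1.5
    sd_factor: float = 2.0
    sd_ddof: int = 1

    def __post_init__(self):
        if self.multiplier <= 0:
            raise ValueError("multiplier must be > 0")
        if self.sd_factor < 0:
            raise ValueError("sd_factor must be >= 0")
        if self.sd_ddof not in (0, 1):
            raise ValueError("sd_ddof must be 0 or 1")


def _voi_stats(
    image: SUVImage, box: BoxVOI, site: str, sd_ddof: int
) -> ReferenceStats:
    try:
        vals = voi_values(image, box, require_inside=True)
    except EmptyVOIError as exc:
        raise ReferenceVOIError(str(exc)) from exc
    if vals.size < 2:
        raise ReferenceVOIError(
            f"{site} VOI contains {vals.size} voxel(s); need >= 2 for an SD"
        )
    return ReferenceStats(
        mean_suv=float(np.mean(vals)),
        sd_suv=float(np.std(vals, ddof=sd_ddof)),
        site=site,
        n_voxels=int(vals.size),
    )


def liver_stats(
    image: SUVImage,
    center: Sequence[float],
    edge_mm: Optional[Sequence[float]] = None,
    cfg: PercistConfig = PercistConfig(),
) -> ReferenceStats:
    """Mean and SD SUV over a 3 cm³ cuboid VOI centred at ``center`` (mm).

    ``edge_mm`` overrides the default cubic geometry (three edge lengths);
    the default cube has edge :data:`LIVER_VOI_EDGE_MM`.
    """
    size = tuple(edge_mm) if edge_mm is not None else (LIVER_VOI_EDGE_MM,) * 3
    return _voi_stats(image, BoxVOI(tuple(center), size), "liver", cfg.sd_ddof)


def aorta_stats(
    image: SUVImage,
    center: Sequence[float],
    cfg: PercistConfig = PercistConfig(),
) -> ReferenceStats:
    """Mean and SD SUV over the fixed 10 × 10 × 20 mm aorta VOI."""
    return _voi_stats(
        image, BoxVOI(tuple(center), AORTA_VOI_SIZE_MM), "aorta", cfg.sd_ddof
    )


def percist_threshold(ref: ReferenceStats, cfg: PercistConfig = PercistConfig()) -> float:
    """Segmentation threshold: multiplier × mean + sd_factor × SD."""
    return cfg.multiplier * ref.mean_suv + cfg.sd_factor * ref.sd_suv


def choose_reference(
    liver_involved: bool,
    image: SUVImage,
    liver_center: Sequence[float],
    aorta_center: Sequence[float],
    cfg: PercistConfig = PercistConfig(),
) -> ReferenceStats:
    """Liver VOI normally; aorta VOI when the liver is involved by lymphoma.

    ``liver_involved`` is a clinical judgement supplied by the caller, never
    inferred from the image.  The provenance is recorded in ``site``.
    """
    if liver_involved:
        return aorta_stats(image, aorta_center, cfg)
    return liver_stats(image, liver_center, cfg=cfg)


def load_reference_annotations(path) -> dict:
    """Read the per-patient reference-VOI sidecar JSON.

    Expected keys: ``patient_id``, ``liver_center_mm``, ``aorta_center_mm``,
    ``liver_involved``.
    """
    with open(path) as fh:
        ann = json.load(fh)
    missing = {"patient_id", "liver_center_mm", "aorta_center_mm", "liver_involved"} - set(ann)
    if missing:
        raise ValueError(f"reference annotation {path} missing keys: {sorted(missing)}")
    return ann
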