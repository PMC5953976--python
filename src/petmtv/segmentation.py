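"""The three MTV segmentation methods, label editing, and MTV/TLG totals.

Three thresholding rules delineate metabolically active tumour on an SUV
volume:

* **fixed25** — the connected component of ``SUV >= 2.5`` containing an
  operator-supplied seed voxel;
* **pct41** — within an operator-drawn constraining box, the connected
  component of ``SUV >= 0.41 × max SUV in box`` containing the argmax voxel
  (a two-stage process: outline, find the maximum, recontour);
* **percist** — every connected component of ``SUV >= T`` for a
  liver-referenced threshold ``T`` (see :mod:`petmtv.reference_region`),
  followed by operator editing to remove physiological uptake (brain,
  bladder) and carve uptake adjacent to tumour.

All thresholds are inclusive (``>=``).  Per-lesion volumes are summed to the
total metabolic tumour volume (MTV, cm³); total lesion glycolysis (TLG) is
the sum over lesions of volume × mean SUV within the lesion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage

from .image_model import (
    BoxVOI,
    CongruenceError,
    LabelMap,
    RegionMask,
    SeedPoint,
    SUVImage,
    box_mask,
    mask_volume_cm3,
    voxel_volume_cm3,
)

__all__ = [
    "SegmentationConfig",
    "MTVRecord",
    "SeedError",
    "DegenerateRegionError",
    "segment_fixed",
    "segment_pct_max",
    "heterogeneity_check",
    "percist_tumor_finder",
    "edit_labels",
    "total_mtv",
]


class SeedError(ValueError):
    """The operator's seed voxel lies below the segmentation threshold."""


class DegenerateRegionError(ValueError):
    """A constraining box contains no positive uptake to recontour."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds and connectivity shared by the segmentation methods.

    fixed_threshold
        Absolute SUV cut for the fixed method (default 2.5).
    max_fraction
        Fraction of the in-box maximum for the percentage method
        (default 0.41).
    heterogeneity_tolerance
        Relative difference between regional maxima above which the operator
        is advised to subdivide regions (default 0.10).
    connectivity
        3-D voxel adjacency: 6 (faces), 18 (+edges) or 26 (+vertices).
    """

    fixed_threshold: float = 2.5
    max_fraction: float = 0.41
    heterogeneity_tolerance: float = 0.10
    connectivity: int = 26

    def __post_init__(self):
        if self.fixed_threshold <= 0:
            raise ValueError("fixed_threshold must be > 0")
        if not 0 < self.max_fraction < 1:
            raise ValueError("max_fraction must be in (0, 1)")
        if not 0 < self.heterogeneity_tolerance < 1:
            raise ValueError("heterogeneity_tolerance must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @property
    def structure(self) -> np.ndarray:
        rank = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, rank)


@dataclass(frozen=True)
class MTVRecord:
    """Per-patient, per-method MTV summary row."""

    patient_id: str
    method: str  # {fixed25 | pct41 | percist}
    lesion_volumes: Tuple[float, ...]
    total_mtv: float
    tlg: float
    observer_id: str = "obs1"

    def __post_init__(self):
        if self.total_mtv < 0 or self.tlg < 0:
            raise ValueError("total_mtv and tlg must be >= 0")
        if not np.isclose(self.total_mtv, sum(self.lesion_volumes)):
            raise ValueError("total_mtv must equal the sum of lesion_volumes")


def _component_containing(supra: np.ndarray, index: Tuple[int, int, int],
                          structure: np.ndarray) -> np.ndarray:
    labels, _ = ndimage.label(supra, structure=structure)
    return labels == labels[index]


def segment_fixed(
    image: SUVImage, seed: SeedPoint, cfg: SegmentationConfig = SegmentationConfig()
) -> RegionMask:
    """Seed-grown fixed-threshold segmentation (``SUV >= fixed_threshold``).

    Returns the connected component of the supra-threshold set that contains
    the seed.  A seed below the threshold means the operator clicked outside
    avid disease and raises :class:`SeedError`.
    """
    seed.check_bounds(image)
    if image.values[seed.index] < cfg.fixed_threshold:
        raise SeedError(
            f"seed SUV {image.values[seed.index]:.3g} < threshold "
            f"{cfg.fixed_threshold:.3g}"
        )
    supra = image.values >= cfg.fixed_threshold
    return RegionMask(_component_containing(supra, seed.index, cfg.structure))


def segment_pct_max(
    image: SUVImage, box: BoxVOI, cfg: SegmentationConfig = SegmentationConfig()
) -> RegionMask:
    """Percentage-of-maximum recontouring within a constraining box.

    Let M be the maximum SUV among voxels whose centres lie in the box; the
    mask is the connected component of in-box voxels with
    ``SUV >= max_fraction × M`` that contains the (first, scan-order) argmax
    voxel.  Supra-threshold islands in the box not connected to the argmax
    are treated as separate lesions needing their own box.
    """
    inside = box_mask(image, box)
    in_vals = np.where(inside, image.values, -np.inf)
    m = float(in_vals.max())
    if m <= 0:
        raise DegenerateRegionError("constraining box contains no positive uptake")
    argmax = np.unravel_index(int(np.argmax(in_vals)), image.shape)
    supra = inside & (image.values >= cfg.max_fraction * m)
    return RegionMask(_component_containing(supra, argmax, cfg.structure))


def heterogeneity_check(
    image: SUVImage,
    boxes: Sequence[BoxVOI],
    cfg: SegmentationConfig = SegmentationConfig(),
) -> List[Tuple[int, int, bool]]:
    """Flag region pairs whose maxima differ by more than the tolerance.

    For every unordered pair of boxes (combinations order) the flag is true
    when ``|M_a − M_b| / max(M_a, M_b)`` exceeds ``heterogeneity_tolerance``,
    advising the operator to subdivide regions to avoid underestimating
    tumour volume with the percentage method.  No automatic re-segmentation
    is performed.
    """
    if len(boxes) < 2:
        raise ValueError("heterogeneity_check needs at least 2 boxes")
    maxima = []
    for box in boxes:
        inside = box_mask(image, box)
        maxima.append(float(np.where(inside, image.values, -np.inf).max()))
    flags = []
    for a in range(len(boxes)):
        for b in range(a + 1, len(boxes)):
            hi = max(maxima[a], maxima[b])
            rel = abs(maxima[a] - maxima[b]) / hi if hi > 0 else 0.0
            flags.append((a, b, rel > cfg.heterogeneity_tolerance))
    return flags


def percist_tumor_finder(
    image: SUVImage, threshold: float, cfg: SegmentationConfig = SegmentationConfig()
) -> LabelMap:
    """Whole-image 'tumour finder': all components with ``SUV >= threshold``.

    Components are labelled 1..K in decreasing volume order (ties broken by
    first-voxel scan order).  Physiological uptake (brain, bladder) is
    expected among the labels and removed later with :func:`edit_labels`.
    An empty result (K = 0) is valid.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    raw, k = ndimage.label(image.values >= threshold, structure=cfg.structure)
    if k == 0:
        return LabelMap(np.zeros(image.shape, dtype=np.int32))
    counts = np.bincount(raw.ravel(), minlength=k + 1)[1:]
    # first-voxel scan order: position of each label's first occurrence
    flat = raw.ravel()
    first = np.full(k + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier positions overwrite later ones
    first[flat[nz[::-1]]] = nz[::-1]
    order = sorted(range(1, k + 1), key=lambda lab: (-counts[lab - 1], first[lab]))
    remap = np.zeros(k + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return LabelMap(remap[raw])


def edit_labels(
    labels: LabelMap,
    excluded: Iterable[int] = (),
    carve_mask: Optional[RegionMask] = None,
) -> LabelMap:
    """Operator editing: drop physiological labels, carve adjacent uptake.

    ``excluded`` labels are set to background wholesale (regions containing
    only physiological uptake, e.g. brain or bladder); ``carve_mask`` voxels
    are set to background within all remaining labels (physiological uptake
    adjacent to tumour).  Remaining labels are renumbered contiguously,
    preserving their relative order.
    """
    excl: Set[int] = {int(e) for e in excluded}
    existing = set(range(1, labels.n_regions + 1))
    unknown = excl - existing
    if unknown:
        raise KeyError(f"unknown labels {sorted(unknown)}; existing: {sorted(existing)}")
    out = labels.labels.copy()
    if excl:
        out[np.isin(out, sorted(excl))] = 0
    if carve_mask is not None:
        if carve_mask.mask.shape != out.shape:
            raise CongruenceError("carve mask shape differs from label map")
        out[carve_mask.mask] = 0
    remaining = np.unique(out)
    remaining = remaining[remaining > 0]
    remap = np.zeros(labels.n_regions + 1, dtype=out.dtype)
    for new, old in enumerate(remaining, start=1):
        remap[old] = new
    return LabelMap(remap[out])


def total_mtv(
    lesions: Sequence[RegionMask],
    image: SUVImage,
    patient_id: str = "unknown",
    method: str = "fixed25",
    observer_id: str = "obs1",
) -> MTVRecord:
    """Sum individual lesion volumes into the total MTV and TLG.

    Lesions must be pairwise disjoint.  TLG accumulates per lesion as
    volume × mean SUV within the lesion.
    """
    vv = voxel_volume_cm3(image)
    volumes = []
    tlg = 0.0
    occupancy = np.zeros(image.shape, dtype=np.uint8)
    for les in lesions:
        if les.mask.shape != image.shape:
            raise CongruenceError("lesion mask shape differs from image")
        occupancy += les.mask
        vol = les.voxel_count * vv
        volumes.append(vol)
        if les.voxel_count:
            tlg += vol * float(image.values[les.mask].mean())
    if np.any(occupancy > 1):
        raise ValueError("lesion masks overlap; they must be pairwise disjoint")
    return MTVRecord(
        patient_id=patient_id,
        method=method,
        lesion_volumes=tuple(volumes),
        total_mtv=float(sum(volumes)),
        tlg=float(tlg),
        observer_id=observer_id,
    )
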