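"""Core volumetric data types, cuboid-VOI geometry and volume arithmetic.

All segmentation and reference-region statistics operate on a :class:`SUVImage`:
a 3-D scalar grid of standardised uptake values (SUV, dimensionless) with a
per-axis voxel spacing in millimetres.  Voxel indices are 0-based and the
physical position of the centre of voxel ``(i, j, k)`` is
``origin + index * spacing``.  No interpolation happens anywhere in the
package: every statistic is computed over original voxels on the native,
possibly anisotropic, grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SUVImage",
    "RegionMask",
    "LabelMap",
    "BoxVOI",
    "SeedPoint",
    "CongruenceError",
    "EmptyVOIError",
    "voxel_volume_cm3",
    "mask_volume_cm3",
    "voi_values",
    "voi_index_ranges",
    "load_nifti",
    "save_nifti",
]

# Tolerance (in voxel-index units) used when deciding whether a voxel centre
# lies on the closed boundary of a box: ties count as inside.
_BOUNDARY_EPS = 1e-9


class CongruenceError(ValueError):
    """A mask or label grid does not share its parent image's shape."""


class EmptyVOIError(ValueError):
    """A box VOI contains no voxel centres of the image grid."""


def _as_triple(x, name: str) -> Tuple[float, float, float]:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size != 3:
        raise ValueError(f"{name} must have 3 components, got {arr.size}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass(frozen=True)
class SUVImage:
    """A 3-D grid of SUV values with voxel spacing and physical origin.

    Parameters
    ----------
    values
        3-D array of SUV (dimensionless, g/mL-standardised body-weight SUV).
        Must be finite and non-negative.
    spacing
        Per-axis voxel edge length in mm, all components > 0.
    origin
        Physical coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 3 or min(vals.shape) < 1:
            raise ValueError(f"values must be a 3-D array, got shape {vals.shape}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("SUV values must be finite")
        if np.any(vals < 0):
            raise ValueError("SUV values must be non-negative")
        object.__setattr__(self, "values", vals)
        sp = _as_triple(self.spacing, "spacing")
        if any(s <= 0 for s in sp):
            raise ValueError(f"spacing components must be > 0, got {sp}")
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", _as_triple(self.origin, "origin"))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    def index_to_physical(self, index) -> np.ndarray:
        """Physical coordinate (mm) of a voxel centre."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)


@dataclass(frozen=True)
class RegionMask:
    """A binary voxel mask congruent with a parent :class:`SUVImage`."""

    mask: np.ndarray
    label: Optional[int] = None

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.dtype != bool:
            m = m.astype(bool)
        if m.ndim != 3:
            raise ValueError("mask must be 3-D")
        object.__setattr__(self, "mask", m)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class LabelMap:
    """Integer-labelled voxel grid: 0 = background, k > 0 = region k.

    Labels always form a contiguous set {0..K}; regions are pairwise
    disjoint by construction (one label per voxel).
    """

    labels: np.ndarray

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be an integer grid")
        if lab.ndim != 3:
            raise ValueError("labels must be 3-D")
        if lab.size and lab.min() < 0:
            raise ValueError("labels must be non-negative")
        present = np.unique(lab)
        present = present[present > 0]
        k = len(present)
        if k and not np.array_equal(present, np.arange(1, k + 1)):
            raise ValueError(f"labels must be contiguous 1..K, got {present}")
        object.__setattr__(self, "labels", lab)

    @property
    def n_regions(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    def region(self, label: int) -> RegionMask:
        if label < 1 or label > self.n_regions:
            raise ValueError(f"no region with label {label}")
        return RegionMask(self.labels == label, label=label)


@dataclass(frozen=True)
class BoxVOI:
    """Axis-aligned cuboid VOI given by physical centre and edge lengths (mm).

    A voxel belongs to the box iff its *centre* lies inside the closed box
    (boundary ties count as inside).
    """

    center: Tuple[float, float, float]
    size: Tuple[float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "center", _as_triple(self.center, "center"))
        sz = _as_triple(self.size, "size")
        if any(s <= 0 for s in sz):
            raise ValueError(f"size components must be > 0, got {sz}")
        object.__setattr__(self, "size", sz)


@dataclass(frozen=True)
class SeedPoint:
    """Integer voxel coordinate used as an operator 'click' inside a lesion."""

    index: Tuple[int, int, int]

    def __post_init__(self):
        idx = tuple(int(i) for i in self.index)
        if len(idx) != 3:
            raise ValueError("index must have 3 components")
        object.__setattr__(self, "index", idx)

    def check_bounds(self, image: SUVImage) -> None:
        for i, n in zip(self.index, image.shape):
            if not (0 <= i < n):
                raise IndexError(f"seed {self.index} outside image shape {image.shape}")


# ---------------------------------------------------------------------------
# Volume arithmetic
# ---------------------------------------------------------------------------

def voxel_volume_cm3(image: SUVImage) -> float:
    """Volume of one voxel in cm³ (product of spacings, mm³ → cm³)."""
    sx, sy, sz = image.spacing
    return sx * sy * sz / 1000.0


def mask_volume_cm3(mask: RegionMask, image: SUVImage) -> float:
    """Volume of a binary mask in cm³: voxel count × voxel volume."""
    if mask.mask.shape != image.shape:
        raise CongruenceError(
            f"mask shape {mask.mask.shape} != image shape {image.shape}"
        )
    return mask.voxel_count * voxel_volume_cm3(image)


# ---------------------------------------------------------------------------
# Box-VOI geometry
# ---------------------------------------------------------------------------

def voi_index_ranges(
    image: SUVImage, box: BoxVOI, require_inside: bool = False
) -> Tuple[Tuple[int, int], Tuple[int, int], Tuple[int, int]]:
    """Half-open index ranges ``(lo, hi)`` per axis of voxels whose centres
    lie in the closed box.

    With ``require_inside`` the box must lie entirely within the grid
    (reference-VOI contract); otherwise it is clipped to the grid and must
    merely overlap it.
    """
    lo = np.asarray(box.center) - np.asarray(box.size) / 2.0
    hi = np.asarray(box.center) + np.asarray(box.size) / 2.0
    sp = np.asarray(image.spacing)
    org = np.asarray(image.origin)
    # first/last voxel index whose centre is >= lo (resp. <= hi)
    imin = np.ceil((lo - org) / sp - _BOUNDARY_EPS).astype(int)
    imax = np.floor((hi - org) / sp + _BOUNDARY_EPS).astype(int)
    shape = np.asarray(image.shape)
    if require_inside and (np.any(imin < 0) or np.any(imax > shape - 1)):
        raise EmptyVOIError(
            f"VOI {box} extends outside the image grid (shape {image.shape})"
        )
    imin_c = np.clip(imin, 0, shape - 1)
    imax_c = np.clip(imax, -1, shape - 1)
    if np.any(imax < 0) or np.any(imin > shape - 1) or np.any(imin_c > imax_c):
        raise EmptyVOIError(f"VOI {box} contains no voxel centres")
    return tuple((int(a), int(b) + 1) for a, b in zip(imin_c, imax_c))


def voi_values(image: SUVImage, box: BoxVOI, require_inside: bool = False) -> np.ndarray:
    """SUV of every voxel whose centre lies in the closed box (flattened)."""
    (i0, i1), (j0, j1), (k0, k1) = voi_index_ranges(image, box, require_inside)
    return image.values[i0:i1, j0:j1, k0:k1].ravel()


def box_mask(image: SUVImage, box: BoxVOI) -> np.ndarray:
    """Boolean grid of voxels whose centres lie in the closed box."""
    (i0, i1), (j0, j1), (k0, k1) = voi_index_ranges(image, box)
    m = np.zeros(image.shape, dtype=bool)
    m[i0:i1, j0:j1, k0:k1] = True
    return m


# ---------------------------------------------------------------------------
# NIfTI I/O — values are already in SUV units; the affine must encode pure
# axis-aligned scaling + translation (no rotation/shear), else it is rejected.
# ---------------------------------------------------------------------------

def load_nifti(path) -> SUVImage:
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    lin = affine[:3, :3]
    if not np.allclose(lin - np.diag(np.diag(lin)), 0, atol=1e-6):
        raise ValueError(
            "NIfTI affine has rotation/shear terms; only axis-aligned "
            "scaling + translation volumes are supported"
        )
    diag = np.diag(lin)
    if np.any(diag == 0):
        raise ValueError("NIfTI affine has a zero scaling component")
    values = np.asarray(img.get_fdata(), dtype=float)
    # normalise negative scalings (RAS flips) to positive spacing by
    # reordering voxels so index increases with physical coordinate
    origin = affine[:3, 3].copy()
    for ax, d in enumerate(diag):
        if d < 0:
            values = np.flip(values, axis=ax)
            origin[ax] = origin[ax] + d * (values.shape[ax] - 1)
    return SUVImage(values, tuple(np.abs(diag)), tuple(origin))


def save_nifti(image: SUVImage, path) -> None:
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = np.diag(image.spacing)
    affine[:3, 3] = image.origin
    nib.save(nib.Nifti1Image(np.asarray(image.values, dtype=np.float32), affine), str(path))
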