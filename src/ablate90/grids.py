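"""Axis-aligned voxel grids, scalar fields, binary masks, and NIfTI I/O.

All volumes in the analysis — activity maps, absorbed-dose maps, temperature
and damage fields, tumor and organ masks — live on an axis-aligned 3D lattice
(:class:`VoxelGrid`).  Voxel indices are 0-based; world coordinates are in mm
and refer to voxel *centers*.  Oblique (non-axis-aligned) NIfTI affines are
rejected rather than resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "ScalarMap",
    "LabelMask",
    "read_volume",
    "read_mask",
    "write_volume",
    "mask_volume_cm3",
    "rebin_fine_to_coarse",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis (all >= 1).
    spacing : tuple of float
        Voxel edge lengths in mm (all > 0).
    origin : tuple of float
        World position (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("VoxelGrid is three-dimensional")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"all shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0 mm, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def center_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (sparse) meshgrid of voxel-center world coordinates."""
        ax = [self.axis_coords(i) for i in range(3)]
        return tuple(np.meshgrid(*ax, indexing="ij", sparse=True))

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer (face) bounding box of the lattice in mm."""
        lo = np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)
        hi = lo + np.asarray(self.spacing) * np.asarray(self.shape)
        return lo, hi

    def approx_equal(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def _require_same_grid(a: "VoxelGrid", b: "VoxelGrid") -> None:
    if not a.approx_equal(b):
        raise ValueError(f"grids differ: {a} vs {b}")


@dataclass
class ScalarMap:
    """One scalar per voxel on a :class:`VoxelGrid` (dose, activity, T, Omega)."""

    grid: VoxelGrid
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar map contains non-finite entries")

    def copy(self) -> "ScalarMap":
        return ScalarMap(self.grid, self.values.copy(), self.units)


@dataclass
class LabelMask:
    """Binary voxel membership on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def n_true(self) -> int:
        return int(np.count_nonzero(self.values))

    @property
    def volume_mm3(self) -> float:
        return self.n_true * self.grid.voxel_volume_mm3

    @property
    def volume_cm3(self) -> float:
        return self.volume_mm3 / 1000.0

    def __or__(self, other: "LabelMask") -> "LabelMask":
        _require_same_grid(self.grid, other.grid)
        return LabelMask(self.grid, self.values | other.values)

    def __and__(self, other: "LabelMask") -> "LabelMask":
        _require_same_grid(self.grid, other.grid)
        return LabelMask(self.grid, self.values & other.values)

    def __sub__(self, other: "LabelMask") -> "LabelMask":
        _require_same_grid(self.grid, other.grid)
        return LabelMask(self.grid, self.values & ~other.values)

    def __invert__(self) -> "LabelMask":
        return LabelMask(self.grid, ~self.values)


def mask_volume_cm3(mask: LabelMask) -> float:
    """Mask volume: count(true) x voxel volume, in cm^3."""
    return mask.volume_cm3


# ---------------------------------------------------------------------------
# NIfTI I/O


def _grid_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> VoxelGrid:
    rot = affine[:3, :3]
    # Axis-aligned: exactly one non-zero per column.  Negative scales (e.g.
    # RAS flips) are rejected too — the analysis assumes index order == world
    # order, which holds for volumes this package writes.
    offdiag = rot - np.diag(np.diag(rot))
    if np.any(np.abs(offdiag) > 1e-6 * max(1.0, np.abs(rot).max())):
        bad = sorted({int(j) for i, j in zip(*np.nonzero(np.abs(offdiag) > 1e-9))})
        raise ValueError(
            f"NIfTI affine is not axis-aligned (oblique axes {bad}); "
            "resample the volume before loading"
        )
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise ValueError(f"NIfTI affine has non-positive axis scales {spacing}")
    return VoxelGrid(tuple(int(s) for s in shape[:3]), tuple(spacing), tuple(affine[:3, 3]))


def read_volume(path: str | Path, units: str = "") -> ScalarMap:
    """Read an axis-aligned NIfTI-1 volume as a :class:`ScalarMap`."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        data = np.squeeze(data)
    grid = _grid_from_affine(img.affine, data.shape)
    return ScalarMap(grid, data, units)


def read_mask(path: str | Path, threshold: float = 0.5) -> LabelMask:
    """Read a NIfTI volume as a binary mask (binarized at ``value > threshold``)."""
    vol = read_volume(path)
    return LabelMask(vol.grid, vol.values > threshold)


def write_volume(vol: ScalarMap | LabelMask, path: str | Path) -> None:
    """Write a map or mask as NIfTI-1 (masks as 8-bit 0/1)."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vol.grid.spacing)
    affine[:3, 3] = vol.grid.origin
    if isinstance(vol, LabelMask):
        data = vol.values.astype(np.uint8)
    else:
        data = vol.values.astype(np.float64)
    nib.save(nib.Nifti1Image(data, affine), str(path))


# ---------------------------------------------------------------------------
# Rebinning between grids


def rebin_fine_to_coarse(
    fine: ScalarMap | LabelMask,
    coarse_grid: VoxelGrid,
    value_threshold: float = 0.5,
    occupancy: float = 0.5,
) -> LabelMask:
    """Rebin a fine-grid field onto a coarse grid as a binary mask.

    A coarse voxel is labeled true iff (a) it is fully covered by fine voxels
    and (b) the fraction of covering fine voxels with value >= ``value_threshold``
    is >= ``occupancy``.  Fine voxels are assigned to the coarse voxel that
    contains their center.

    Raises ``ValueError`` when the two lattices do not overlap at all, naming
    the uncovered region.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must be in [0, 1]")
    fgrid = fine.grid
    if any(fs > cs * (1 + 1e-9) for fs, cs in zip(fgrid.spacing, coarse_grid.spacing)):
        raise ValueError(
            f"fine spacing {fgrid.spacing} exceeds coarse spacing {coarse_grid.spacing}"
        )
    values = fine.values.astype(np.float64)

    # Per-axis coarse bin index of every fine voxel center; -1 marks out-of-grid.
    idx = []
    for ax in range(3):
        c = fgrid.axis_coords(ax)
        lo = coarse_grid.origin[ax] - 0.5 * coarse_grid.spacing[ax]
        k = np.floor((c - lo) / coarse_grid.spacing[ax]).astype(np.int64)
        k[(k < 0) | (k >= coarse_grid.shape[ax])] = -1
        idx.append(k)

    inb = (idx[0][:, None, None] >= 0) & (idx[1][None, :, None] >= 0) & (
        idx[2][None, None, :] >= 0
    )
    if not inb.any():
        flo, fhi = fgrid.bounds()
        clo, chi = coarse_grid.bounds()
        raise ValueError(
            "fine and coarse grids do not overlap: fine covers "
            f"[{flo}, {fhi}] mm but coarse voxels span [{clo}, {chi}] mm"
        )

    nx, ny, nz = coarse_grid.shape
    flat = (
        idx[0][:, None, None] * (ny * nz)
        + idx[1][None, :, None] * nz
        + idx[2][None, None, :]
    )
    flat = np.where(inb, flat, 0)
    w_in = inb.ravel().astype(np.float64)
    total = np.bincount(flat.ravel(), weights=w_in, minlength=nx * ny * nz)
    hot = np.bincount(
        flat.ravel(),
        weights=w_in * (values.ravel() >= value_threshold),
        minlength=nx * ny * nz,
    )

    # Full coverage: expected number of fine voxels per coarse voxel.
    expected = np.prod(
        [coarse_grid.spacing[a] / fgrid.spacing[a] for a in range(3)]
    )
    covered = total >= 0.99 * expected
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, hot / np.maximum(total, 1), 0.0)
    out = covered & (frac >= occupancy) & (total > 0)
    if occupancy == 0.0:
        out = covered & (total > 0)  # degenerate: any coverage labels true
    return LabelMask(coarse_grid, out.reshape(nx, ny, nz))
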