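"""Voxel phantoms and procedural test-phantom builders.

A :class:`VoxelPhantom` is a 3-D grid of Hounsfield units with an isotropic
voxel size and a world placement.  Axis convention, fixed package-wide:

* axis 0 -> x, lateral
* axis 1 -> y, vertical (source above, detector below; beam travels -y)
* axis 2 -> z, cranio-caudal

``origin_mm`` is the world position of the corner of voxel (0, 0, 0); voxel
``(i, j, k)`` occupies ``origin + [i, j, k] * voxel_size .. + voxel_size``.

The builders are deterministic pure functions of their parameters and stand
in for CT-derived anatomy: homogeneous slabs (the classic PMMA attenuation
block), a half-field edge block for point-spread calibration, and an
elliptic-cylinder torso surrogate with lungs and a vertebral column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "VoxelPhantom",
    "make_slab",
    "make_edge_phantom",
    "make_torso_surrogate",
    "read_nrrd",
    "write_nrrd",
    "HU_AIR",
    "HU_PMMA",
    "HU_SOFT_TISSUE",
    "HU_LUNG",
    "HU_BONE",
]

HU_AIR = -1000.0
#: nominal CT number for PMMA. PMMA is not a CT-calibrated tissue; this is a
#: documented convention — all physics flows through the HU->mu formula.
HU_PMMA = 120.0
HU_SOFT_TISSUE = 40.0
HU_LUNG = -750.0
HU_BONE = 700.0

DEFAULT_VOXEL_MM = 0.62


@dataclass
class VoxelPhantom:
    """3-D HU volume with isotropic voxels and world placement."""

    hu: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float32)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.hu.ndim != 3 or min(self.hu.shape) < 1:
            raise ValueError("hu must be a 3-D array with all dimensions >= 1")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("HU values must be finite")
        if self.origin_mm.shape != (3,):
            raise ValueError("origin must be a 3-vector (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> np.ndarray:
        """World-space edge lengths (x, y, z) in mm."""
        return np.asarray(self.hu.shape) * self.voxel_size_mm

    def centred_at(self, centre_mm) -> "VoxelPhantom":
        """Same volume, repositioned so its geometric centre is ``centre_mm``."""
        origin = np.asarray(centre_mm, dtype=float) - self.extent_mm / 2.0
        return VoxelPhantom(self.hu, self.voxel_size_mm, origin)

    def total_attenuating_mass_proxy(self) -> float:
        """Sum of (HU/1000 + 1) * voxel volume over all voxels (mm^3).

        Proportional to total mass under the affine HU-density model; used
        as a bookkeeping invariant by the builders' tests.
        """
        rho_rel = np.maximum(self.hu.astype(np.float64) / 1000.0 + 1.0, 0.0)
        return float(rho_rel.sum() * self.voxel_size_mm**3)


def _empty_volume(nx: int, ny: int, nz: int) -> np.ndarray:
    return np.full((nx, ny, nz), HU_AIR, dtype=np.float32)


def make_slab(
    material_hu: float = HU_PMMA,
    thickness_mm: float = 200.0,
    lateral_mm: float = 250.0,
    voxel_size_mm: float = DEFAULT_VOXEL_MM,
    air_margin_mm: float = 0.0,
) -> VoxelPhantom:
    """Homogeneous slab normal to the beam axis, surrounded by air.

    ``thickness_mm`` is along y (the source-detector axis); the block spans
    ``lateral_mm`` in both x and z.  World-space thickness matches the
    request to within one voxel.  The phantom is centred at the world origin.
    """
    if thickness_mm <= 0 or lateral_mm <= 0:
        raise ValueError("slab dimensions must be positive")
    if voxel_size_mm > min(thickness_mm, lateral_mm):
        raise ValueError("voxel size exceeds a requested dimension")
    n_thick = math.ceil(thickness_mm / voxel_size_mm)
    n_lat = math.ceil(lateral_mm / voxel_size_mm)
    n_margin = math.ceil(air_margin_mm / voxel_size_mm)
    nx = nz = n_lat + 2 * n_margin
    ny = n_thick + 2 * n_margin
    hu = _empty_volume(nx, ny, nz)
    sl = slice(n_margin, n_margin + n_lat)
    hu[sl, n_margin : n_margin + n_thick, sl] = material_hu
    phantom = VoxelPhantom(hu, voxel_size_mm, np.zeros(3))
    return phantom.centred_at(np.zeros(3))


def make_edge_phantom(
    material_hu: float = HU_PMMA,
    thickness_mm: float = 20.0,
    lateral_mm: float = 250.0,
    voxel_size_mm: float = DEFAULT_VOXEL_MM,
) -> VoxelPhantom:
    """Half-covered field: a slab occupying x < 0 with a straight edge.

    The edge plane is x = 0 (aligned with detector columns), producing a
    two-plateau projection for penumbra / point-spread measurements.
    """
    slab = make_slab(material_hu, thickness_mm, lateral_mm, voxel_size_mm)
    hu = slab.hu.copy()
    nx = hu.shape[0]
    hu[nx // 2 :, :, :] = HU_AIR
    return VoxelPhantom(hu, slab.voxel_size_mm, slab.origin_mm)


def make_torso_surrogate(
    body_halfaxes_mm: tuple[float, float] = (150.0, 100.0),
    length_mm: float = 200.0,
    lung_halfaxes_mm: tuple[float, float, float] = (55.0, 55.0, 70.0),
    lung_offset_x_mm: float = 75.0,
    spine_radius_mm: float = 20.0,
    spine_offset_y_mm: float = -55.0,
    voxel_size_mm: float = 2.0,
) -> VoxelPhantom:
    """Elliptic-cylinder torso with two lungs and a vertebral column.

    Soft-tissue body (HU +40) as an elliptic cylinder along z, two mirrored
    lung ellipsoids (HU -750) and a posterior bone cylinder (HU +700).
    Deterministic given its parameters; inserts must fit inside the body.
    The phantom is centred at the world origin, so its x-mirror symmetry
    makes on-axis projections symmetric as well.
    """
    ax, ay = body_halfaxes_mm
    if ax <= 0 or ay <= 0 or length_mm <= 0:
        raise ValueError("body dimensions must be positive")
    lx, ly, lz = lung_halfaxes_mm
    if lung_offset_x_mm + lx > ax or ly > ay or lz > length_mm / 2:
        raise ValueError("lung inserts exceed body bounds")
    if spine_radius_mm + abs(spine_offset_y_mm) > ay:
        raise ValueError("spine insert exceeds body bounds")

    margin = voxel_size_mm  # one-voxel air shell
    nx = math.ceil(2 * (ax + margin) / voxel_size_mm)
    ny = math.ceil(2 * (ay + margin) / voxel_size_mm)
    nz = math.ceil((length_mm + 2 * margin) / voxel_size_mm)
    nx += nx % 2  # even count keeps the x-mirror symmetry exact
    hu = _empty_volume(nx, ny, nz)

    # voxel-centre world coordinates for a volume centred at the origin
    def centres(n: int) -> np.ndarray:
        return (np.arange(n) - (n - 1) / 2.0) * voxel_size_mm

    X = centres(nx)[:, None, None]
    Y = centres(ny)[None, :, None]
    Z = centres(nz)[None, None, :]

    body = ((X / ax) ** 2 + (Y / ay) ** 2 <= 1.0) & (np.abs(Z) <= length_mm / 2)
    hu[body] = HU_SOFT_TISSUE
    for sign in (-1.0, 1.0):
        lung = ((X - sign * lung_offset_x_mm) / lx) ** 2 + (Y / ly) ** 2 + (
            Z / lz
        ) ** 2 <= 1.0
        hu[lung & body] = HU_LUNG
    spine = (X**2 + (Y - spine_offset_y_mm) ** 2 <= spine_radius_mm**2) & (
        np.abs(Z) <= length_mm / 2
    )
    hu[spine & body] = HU_BONE

    phantom = VoxelPhantom(hu, voxel_size_mm, np.zeros(3))
    return phantom.centred_at(np.zeros(3))


# ---------------------------------------------------------------------------
# NRRD I/O (SimpleITK backend)


def write_nrrd(phantom: VoxelPhantom, path: str | Path) -> None:
    """Write a phantom volume as NRRD, preserving voxel size and origin."""
    import SimpleITK as sitk

    # SimpleITK arrays are indexed (z, y, x); transpose to keep our (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(phantom.hu.T))
    img.SetSpacing([phantom.voxel_size_mm] * 3)
    img.SetOrigin(list(np.asarray(phantom.origin_mm, dtype=float)))
    sitk.WriteImage(img, str(path))


def read_nrrd(path: str | Path) -> VoxelPhantom:
    """Read a phantom volume written by :func:`write_nrrd`."""
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    spacing = img.GetSpacing()
    if not np.allclose(spacing, spacing[0]):
        raise ValueError(f"anisotropic voxels not supported: {spacing}")
    hu = sitk.GetArrayFromImage(img).T
    return VoxelPhantom(hu, float(spacing[0]), np.asarray(img.GetOrigin()))
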