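"""Image-stack I/O, density calibration, segmentation and cylindrical ROIs.

Scans arrive as stacks of 8-bit grayscale cross-sections (one BMP/TIFF/PNG
file per slice, or a single multi-page TIFF) ordered caudal to cranial along
the first axis.  Gray values are converted to mineral density (g/cm^3) by an
affine calibration fitted through two hydroxyapatite phantom anchors, bone is
segmented by a closed gray-level interval, and analysis is restricted to a
cylindrical trabecular region of interest.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "GrayStack",
    "DensityCalibration",
    "DensityStack",
    "SegmentationParams",
    "BinaryROI",
    "read_stack",
    "write_stack",
    "read_sidecar",
    "write_sidecar",
    "fit_density_calibration",
    "calibration_from_hu",
    "apply_calibration",
    "segment",
    "extract_cylinder",
    "restrict_density",
]

_IMAGE_SUFFIXES = (".bmp", ".tif", ".tiff", ".png")


class StackError(ValueError):
    """Raised for malformed or inconsistent image stacks."""


@dataclass(frozen=True)
class GrayStack:
    """3D grid of 8-bit attenuation values.

    Axis 0 is the slice index running caudal to cranial; axes 1 and 2 are the
    in-plane rows and columns.  ``voxel_size`` is the isotropic edge length in
    millimetres (18 um scans -> 0.018).
    """

    voxels: np.ndarray
    voxel_size: float
    axis_order: str = "slice-caudal-to-cranial"

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise StackError(f"expected a 3D stack, got ndim={v.ndim}")
        if v.dtype != np.uint8:
            if v.min() < 0 or v.max() > 255:
                raise StackError("gray values outside [0, 255]")
            v = v.astype(np.uint8)
        if not self.voxel_size > 0:
            raise StackError("voxel_size must be positive")
        object.__setattr__(self, "voxels", v)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class DensityCalibration:
    """Affine gray-level -> mineral density map through two anchors."""

    slope: float
    intercept: float
    anchors: tuple[tuple[float, float], tuple[float, float]]
    hu_anchors: tuple[float, float] | None = None  # (gray_air, gray_water)

    def __call__(self, gray: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(gray, dtype=float) + self.intercept

    def to_json(self) -> str:
        return json.dumps(
            {
                "slope": self.slope,
                "intercept": self.intercept,
                "anchors": [list(a) for a in self.anchors],
                "hu_anchors": list(self.hu_anchors) if self.hu_anchors else None,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DensityCalibration":
        d = json.loads(text)
        return cls(
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            anchors=tuple(tuple(a) for a in d["anchors"]),  # type: ignore[arg-type]
            hu_anchors=tuple(d["hu_anchors"]) if d.get("hu_anchors") else None,
        )


@dataclass(frozen=True)
class DensityStack:
    """Calibrated mineral density volume (g/cm^3), same shape as its source."""

    voxels: np.ndarray
    voxel_size: float

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class SegmentationParams:
    """Closed gray-level interval [lo, hi] that counts as bone."""

    lo: int = 70
    hi: int = 255

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi <= 255):
            raise ValueError(f"require 0 <= lo <= hi <= 255, got [{self.lo}, {self.hi}]")


@dataclass(frozen=True)
class Cylinder:
    """In-plane circle plus an axial slice range, all in voxel coordinates."""

    center_xy: tuple[float, float]  # (row, col) of the axis, voxel units
    diameter_mm: float
    z_start: int
    z_end: int


@dataclass
class BinaryROI:
    """Segmented bone mask restricted to a region of interest.

    ``mask`` covers the axial range ``[z_start, z_end)`` of the source stack
    (axis 0), full in-plane extent.  ``region`` is the boolean ROI membership
    grid of the same shape: for a cylindrical ROI it is the voxel-center
    in-circle disc repeated along the axis; for box ROIs (synthetic fixtures)
    it is all-true.  The mask is true only inside the region.
    """

    mask: np.ndarray
    voxel_size: float
    cylinder: Cylinder | None = None
    region: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("BinaryROI mask must be 3D")
        if self.region is None:
            self.region = np.ones_like(self.mask, dtype=bool)
        else:
            self.region = np.asarray(self.region, dtype=bool)
            if self.region.shape != self.mask.shape:
                raise ValueError("region and mask shapes differ")
        if np.any(self.mask & ~self.region):
            raise ValueError("mask contains voxels outside the ROI region")

    @property
    def n_slices(self) -> int:
        return self.mask.shape[0]

    @property
    def height_mm(self) -> float:
        return self.n_slices * self.voxel_size

    @property
    def diameter_mm(self) -> float:
        if self.cylinder is not None:
            return self.cylinder.diameter_mm
        # fall back on the in-plane extent for box ROIs
        return min(self.mask.shape[1], self.mask.shape[2]) * self.voxel_size

    @property
    def tv_mm3(self) -> float:
        """Total ROI volume (bone + marrow), mm^3."""
        return float(self.region.sum()) * self.voxel_size**3

    def bone_count(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# stack reading / writing


def _natural_key(name: str) -> list:
    return [int(t) if t.isdigit() else t.lower() for t in re.split(r"(\d+)", name)]


def read_stack(path: str | Path, voxel_size_mm: float) -> GrayStack:
    """Read an image stack from a directory of slices or a multi-page TIFF.

    Slices are ordered by natural (numeric-aware) filename sort; the first
    slice is the caudal end.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack path does not exist: {path}")
    if path.is_file():
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.dtype != np.uint8:
            raise StackError(f"non-8-bit data in {path} (dtype {arr.dtype})")
        return GrayStack(arr, voxel_size_mm)

    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
        key=lambda p: _natural_key(p.name),
    )
    if not files:
        raise StackError(f"no image files (BMP/TIFF/PNG) under {path}")
    slices = []
    shape = None
    for f in files:
        img = iio.imread(f)
        if img.ndim == 3:  # palette/RGB written by some tools; require gray
            if img.shape[2] in (3, 4) and np.all(img[..., :1] == img[..., :3]):
                img = img[..., 0]
            else:
                raise StackError(f"non-grayscale image: {f.name}")
        if img.dtype != np.uint8:
            raise StackError(f"non-8-bit image: {f.name} (dtype {img.dtype})")
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise StackError(
                f"inconsistent slice shape: {f.name} is {img.shape}, expected {shape}"
            )
        slices.append(img)
    return GrayStack(np.stack(slices, axis=0), voxel_size_mm)


def write_stack(stack: GrayStack | np.ndarray, path: str | Path, fmt: str = "png") -> None:
    """Write a stack as one file per slice (``fmt``) or a multi-page TIFF.

    ``fmt='tiff-multipage'`` writes a single file at ``path``; otherwise
    ``path`` is a directory receiving ``slice_0000.<fmt>`` files.
    """
    arr = stack.voxels if isinstance(stack, GrayStack) else np.asarray(stack, np.uint8)
    path = Path(path)
    if fmt == "tiff-multipage":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, arr)
        return
    path.mkdir(parents=True, exist_ok=True)
    for i, sl in enumerate(arr):
        iio.imwrite(path / f"slice_{i:04d}.{fmt}", sl)


def write_sidecar(path: str | Path, voxel_size_mm: float, **extra) -> None:
    """Write the key-value metadata sidecar (voxel size, orientation)."""
    lines = [f"voxel_size_mm = {voxel_size_mm}", "axis_order = slice-caudal-to-cranial"]
    lines += [f"{k} = {v}" for k, v in extra.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sidecar(path: str | Path) -> dict:
    meta: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        k, v = (t.strip() for t in line.split("=", 1))
        try:
            meta[k] = float(v) if "." in v or "e" in v.lower() else int(v)
        except ValueError:
            meta[k] = v
    return meta


# ---------------------------------------------------------------------------
# calibration


def fit_density_calibration(
    anchors: Sequence[tuple[float, float]],
) -> DensityCalibration:
    """Fit the affine gray -> density map through two (mean gray, density) anchors.

    The two anchors are typically hydroxyapatite phantoms of known density
    (0.250 and 0.750 g/cm^3).  The fitted map reproduces both anchors exactly.
    """
    if len(anchors) != 2:
        raise ValueError(f"exactly two anchors required, got {len(anchors)}")
    (g1, d1), (g2, d2) = anchors
    if g1 == g2:
        raise ValueError("degenerate calibration: anchor gray values are equal")
    slope = (d2 - d1) / (g2 - g1)
    intercept = d1 - slope * g1
    return DensityCalibration(slope, intercept, ((g1, d1), (g2, d2)))


def calibration_from_hu(
    anchors: Sequence[tuple[float, float]],
    gray_air: float,
    gray_water: float,
) -> DensityCalibration:
    """Fit the calibration through an intermediate Hounsfield-unit scale.

    Gray values are first mapped to HU by the affine map pinned at
    HU(air) = -1000 and HU(water) = 0, and the phantom anchors are then fitted
    on the HU axis.  The composition gray -> HU -> density is itself affine,
    so the returned object has the same form as a direct fit; the HU anchors
    are recorded for provenance.
    """
    if gray_air == gray_water:
        raise ValueError("degenerate HU calibration: gray_air == gray_water")
    hu_slope = 1000.0 / (gray_water - gray_air)

    def to_hu(g: float) -> float:
        return hu_slope * (g - gray_water)

    (g1, d1), (g2, d2) = anchors
    hu_fit = fit_density_calibration([(to_hu(g1), d1), (to_hu(g2), d2)])
    slope = hu_fit.slope * hu_slope
    intercept = hu_fit.intercept - hu_fit.slope * hu_slope * gray_water
    return DensityCalibration(
        slope, intercept, ((g1, d1), (g2, d2)), hu_anchors=(gray_air, gray_water)
    )


def apply_calibration(stack: GrayStack, calib: DensityCalibration) -> DensityStack:
    """Convert a gray stack to mineral density, clamping negatives to zero.

    Densities are physical quantities: marrow and air can fall below the
    affine fit's zero crossing, and those voxels are set to 0 g/cm^3.
    """
    dens = calib(stack.voxels.astype(float))
    np.clip(dens, 0.0, None, out=dens)
    return DensityStack(dens, stack.voxel_size)


# ---------------------------------------------------------------------------
# segmentation and ROI extraction


def segment(stack: GrayStack, params: SegmentationParams | None = None,
            despeckle: bool = False) -> np.ndarray:
    """Threshold the stack: a voxel is bone iff lo <= gray <= hi (inclusive).

    ``despeckle`` is accepted as an explicit no-op flag: no despeckling is
    applied before or after thresholding.
    """
    if params is None:
        params = SegmentationParams()
    if despeckle:
        raise NotImplementedError("despeckling is intentionally not applied")
    v = stack.voxels
    return (v >= params.lo) & (v <= params.hi)


def _disc(shape_yx: tuple[int, int], center_yx: tuple[float, float],
          radius_vox: float) -> np.ndarray:
    yy, xx = np.indices(shape_yx)
    return (yy - center_yx[0]) ** 2 + (xx - center_yx[1]) ** 2 <= radius_vox**2


def extract_cylinder(
    grid: np.ndarray,
    voxel_size: float,
    center_xy: tuple[float, float],
    diameter_mm: float,
    z_start: int,
    z_end: int,
) -> BinaryROI:
    """Restrict a boolean grid to a cylindrical ROI.

    Membership is by the voxel-center-in-circle test in-plane and the
    half-open slice range ``[z_start, z_end)`` axially.  The returned mask
    covers only the selected slices.
    """
    grid = np.asarray(grid, dtype=bool)
    nz, ny, nx = grid.shape
    if not (0 <= z_start < z_end <= nz):
        raise ValueError(f"z range [{z_start}, {z_end}) outside stack of {nz} slices")
    radius_vox = diameter_mm / voxel_size / 2.0
    cy, cx = center_xy
    eps = 1e-9  # tolerate diameter_mm/voxel_size round-off
    if (cy - radius_vox < -0.5 - eps or cy + radius_vox > ny - 0.5 + eps
            or cx - radius_vox < -0.5 - eps or cx + radius_vox > nx - 0.5 + eps):
        raise ValueError("cylinder exceeds the in-plane extent of the grid")
    disc = _disc((ny, nx), (cy, cx), radius_vox)
    region = np.broadcast_to(disc, (z_end - z_start, ny, nx)).copy()
    mask = grid[z_start:z_end] & region
    return BinaryROI(
        mask=mask,
        voxel_size=voxel_size,
        cylinder=Cylinder((cy, cx), diameter_mm, z_start, z_end),
        region=region,
    )


def restrict_density(density: DensityStack, roi: BinaryROI) -> DensityStack:
    """Crop a density stack to the ROI's axial range (in-plane kept full)."""
    if roi.cylinder is None:
        return density
    z0, z1 = roi.cylinder.z_start, roi.cylinder.z_end
    return DensityStack(density.voxels[z0:z1], density.voxel_size)
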