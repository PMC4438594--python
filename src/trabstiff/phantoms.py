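"""Synthetic phantoms with known geometry, and trabecular-like study data.

No scans ship with this package, so validation rests on two kinds of
synthetic input:

* geometric fixtures whose morphometry is known analytically (balls, tori,
  slabs, Menger sponges, solid cylinders, rod and plate lattices);
* Gaussian-random-field "trabecular" volumes: seeded white noise smoothed at
  a trabecular length scale and thresholded to a target bone volume
  fraction, cropped to a cylindrical ROI, optionally carrying a mid-height
  transverse channel that mimics the vascular foramen of a vertebral body.

An estrogen-depletion-like contrast (OVX) is emulated by raising the
threshold on the *same* underlying field, which erodes bone from the
surface inward: the transformed mask is a strict subset of its sham
sibling, bone volume and connectivity fall while the characteristic
thickness of surviving trabeculae is largely preserved — the architectural
signature of resorptive bone loss.

Every generator is deterministic under a fixed seed, and the seed is
recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .image_io import BinaryROI, Cylinder, GrayStack, extract_cylinder

__all__ = [
    "PhantomSpec",
    "StudySpec",
    "TrabecularPhantom",
    "SpecimenRecord",
    "make_fixture",
    "ball",
    "torus",
    "slab",
    "menger",
    "solid_cylinder",
    "rod_lattice",
    "plate_lattice",
    "gaussian_trabecular",
    "ovx_transform",
    "add_foramen",
    "gray_from_roi",
    "generate_study",
]

DEFAULT_VOXEL_MM = 0.018  # 18 um scans

# gray levels used when rendering masks as 8-bit stacks; bone sits inside the
# default [70, 255] segmentation window, marrow below it
BONE_GRAY = 160
MARROW_GRAY = 25


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative fixture request for :func:`make_fixture`."""

    kind: str
    dims: tuple[int, int, int]
    voxel_size: float = DEFAULT_VOXEL_MM
    seed: int = 0
    params: dict = field(default_factory=dict)


@dataclass
class TrabecularPhantom:
    """A thresholded random-field phantom keeping its generating field."""

    roi: BinaryROI
    grid: np.ndarray          # full-stack bone grid (before axial crop)
    field_values: np.ndarray  # smoothed noise field, same shape as grid
    threshold: float
    target_bv_tv: float
    seed: int

    @property
    def bv_tv(self) -> float:
        return 100.0 * self.roi.bone_count() / self.roi.region.sum()


# ---------------------------------------------------------------------------
# geometric fixtures


def ball(radius: int, pad: int = 2) -> np.ndarray:
    """Digital ball: voxels within `radius` of the center (boolean grid)."""
    n = 2 * (radius + pad) + 1
    c = (n - 1) / 2
    z, y, x = np.indices((n, n, n))
    return (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius**2


def torus(major: int, minor: int, pad: int = 2) -> np.ndarray:
    """Digital solid torus, axis along z (one handle, Euler characteristic 0)."""
    n = 2 * (major + minor + pad) + 1
    c = (n - 1) / 2
    z, y, x = np.indices((n, n, n))
    ring = np.sqrt((y - c) ** 2 + (x - c) ** 2) - major
    return ring**2 + (z - c) ** 2 <= minor**2


def slab(thickness: int, extent: int = 32, axis: int = 0,
         pad: int = 2) -> np.ndarray:
    """Plate of the given thickness spanning the grid in-plane."""
    shape = [extent] * 3
    shape[axis] = thickness + 2 * pad
    m = np.zeros(shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[axis] = slice(pad, pad + thickness)
    m[tuple(sl)] = True
    return m


def menger(level: int) -> np.ndarray:
    """Menger sponge of the given construction level (grid edge 3^level)."""
    m = np.ones((1, 1, 1), dtype=bool)
    for _ in range(level):
        n = m.shape[0]
        out = np.zeros((3 * n,) * 3, dtype=bool)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    if (i == 1) + (j == 1) + (k == 1) >= 2:
                        continue
                    out[i * n:(i + 1) * n, j * n:(j + 1) * n, k * n:(k + 1) * n] = m
        m = out
    return m


def _cylinder_roi(grid: np.ndarray, voxel_size: float,
                  diameter_vox: float | None = None) -> BinaryROI:
    nz, ny, nx = grid.shape
    d = diameter_vox if diameter_vox is not None else min(ny, nx)
    return extract_cylinder(grid, voxel_size, ((ny - 1) / 2, (nx - 1) / 2),
                            d * voxel_size, 0, nz)


def solid_cylinder(diameter: int, height: int,
                   voxel_size: float = DEFAULT_VOXEL_MM) -> BinaryROI:
    """Fully solid cylindrical ROI (BV/TV = 100%)."""
    grid = np.ones((height, diameter, diameter), dtype=bool)
    return _cylinder_roi(grid, voxel_size, diameter)


def rod_lattice(width: int, pitch: int, diameter: int, height: int,
                voxel_size: float = DEFAULT_VOXEL_MM,
                crop_cylinder: bool = True) -> BinaryROI:
    """Square lattice of vertical rods spanning the full height.

    Before any cylindrical crop the area fraction is exactly (width/pitch)^2.
    Rods are kept only if their full cross-section lies inside the circle, so
    every retained rod spans and carries load independently.
    """
    if not 0 < width <= pitch:
        raise ValueError("require 0 < width <= pitch")
    y, x = np.indices((diameter, diameter))
    cell = ((y % pitch) < width) & ((x % pitch) < width)
    if crop_cylinder:
        c = (diameter - 1) / 2
        r = diameter / 2.0
        inside = (y - c) ** 2 + (x - c) ** 2 <= (r - 0.5) ** 2
        # keep whole rods: drop any rod whose footprint leaves the circle
        lab, n = ndi.label(cell)
        keep = np.zeros_like(cell)
        for i in range(1, n + 1):
            rod = lab == i
            if inside[rod].all():
                keep |= rod
        cell = keep
        grid = np.broadcast_to(cell, (height, diameter, diameter)).copy()
        return _cylinder_roi(grid, voxel_size, diameter)
    grid = np.broadcast_to(cell, (height, diameter, diameter)).copy()
    return BinaryROI(grid, voxel_size)


def plate_lattice(thickness: int, pitch: int, diameter: int, height: int,
                  voxel_size: float = DEFAULT_VOXEL_MM) -> BinaryROI:
    """Stack of horizontal plates connected by a central vertical column."""
    if not 0 < thickness <= pitch:
        raise ValueError("require 0 < thickness <= pitch")
    z = np.arange(height)
    plates = (z % pitch) < thickness
    grid = np.zeros((height, diameter, diameter), dtype=bool)
    grid[plates] = True
    c = diameter // 2
    w = max(1, thickness)
    grid[:, c - w:c + w, c - w:c + w] = True
    return _cylinder_roi(grid, voxel_size, diameter)


def make_fixture(spec: PhantomSpec) -> tuple[BinaryROI, GrayStack]:
    """Build a fixture ROI plus its rendering as an 8-bit gray stack."""
    p = spec.params
    if spec.kind == "ball":
        roi = BinaryROI(ball(p.get("radius", 8)), spec.voxel_size)
    elif spec.kind == "torus":
        roi = BinaryROI(torus(p.get("major", 8), p.get("minor", 3)), spec.voxel_size)
    elif spec.kind == "slab":
        roi = BinaryROI(slab(p.get("thickness", 5), p.get("extent", 32)), spec.voxel_size)
    elif spec.kind == "menger":
        roi = BinaryROI(menger(p.get("level", 3)), spec.voxel_size)
    elif spec.kind == "solid_cylinder":
        roi = solid_cylinder(p.get("diameter", 40), p.get("height", 60), spec.voxel_size)
    elif spec.kind == "rod_lattice":
        roi = rod_lattice(p.get("width", 3), p.get("pitch", 6),
                          p.get("diameter", 40), p.get("height", 60), spec.voxel_size)
    elif spec.kind == "plate_lattice":
        roi = plate_lattice(p.get("thickness", 2), p.get("pitch", 8),
                            p.get("diameter", 40), p.get("height", 60), spec.voxel_size)
    elif spec.kind == "gaussian_trabecular":
        ph = gaussian_trabecular(
            dims=spec.dims, voxel_size=spec.voxel_size, seed=spec.seed,
            scale=p.get("scale", (4.0, 2.0, 2.0)),
            target_bv_tv=p.get("target_bv_tv", 0.35),
            foramen_radius_mm=p.get("foramen_radius_mm", 0.0))
        roi = ph.roi
    else:
        raise ValueError(f"unknown phantom kind: {spec.kind!r}")
    return roi, gray_from_roi(roi, seed=spec.seed)


# ---------------------------------------------------------------------------
# random-field trabecular phantoms


def gaussian_trabecular(dims: tuple[int, int, int] = (72, 48, 48),
                        scale: float | tuple[float, float, float] = (4.0, 2.0, 2.0),
                        target_bv_tv: float = 0.35,
                        voxel_size: float = DEFAULT_VOXEL_MM,
                        seed: int = 0,
                        foramen_radius_mm: float = 0.0) -> TrabecularPhantom:
    """Trabecular-like phantom from a thresholded smoothed noise field.

    ``scale`` is the Gaussian smoothing sigma in voxels (scalar, or one
    sigma per axis) and sets the characteristic trabecular scale.  The
    default is anisotropic — twice as smooth along the cylinder axis as
    in-plane — mimicking the vertical orientation of vertebral trabeculae;
    this keeps the structure axially load-bearing at low bone fractions,
    as real resorbed trabecular networks are.  The threshold is placed at
    the field quantile that makes the in-cylinder bone fraction hit
    ``target_bv_tv`` to within 0.5 percentage points (the field is
    continuous, so the quantile lands within one voxel of the target
    count).
    """
    if not 0.0 < target_bv_tv < 1.0:
        raise ValueError("target_bv_tv must be in (0, 1)")
    sigma = np.broadcast_to(np.asarray(scale, dtype=float), (3,))
    if np.any(sigma < 1.0):
        raise ValueError("smoothing scale must be at least one voxel")
    nz, ny, nx = dims
    rng = np.random.default_rng(seed)
    fld = ndi.gaussian_filter(rng.standard_normal(dims), sigma=sigma)
    diameter_vox = min(ny, nx)
    template = _cylinder_roi(np.ones(dims, dtype=bool), voxel_size, diameter_vox)
    region = template.region
    thr = float(np.quantile(fld[region], 1.0 - target_bv_tv))
    grid = fld > thr
    roi = BinaryROI(grid & region, voxel_size, template.cylinder, region)
    achieved = roi.bone_count() / region.sum()
    if abs(achieved - target_bv_tv) > 0.005:
        raise RuntimeError(
            f"threshold search missed target: {achieved:.4f} vs {target_bv_tv:.4f}")
    ph = TrabecularPhantom(roi, grid, fld, thr, target_bv_tv, seed)
    if foramen_radius_mm > 0.0:
        ph = TrabecularPhantom(add_foramen(roi, foramen_radius_mm), grid, fld,
                               thr, target_bv_tv, seed)
    return ph


def ovx_transform(phantom: TrabecularPhantom | BinaryROI,
                  delta_bv_tv: float, seed: int = 0) -> TrabecularPhantom:
    """Estrogen-depletion-like bone loss: raise the field threshold so the
    bone fraction drops by ``delta_bv_tv`` (fraction, e.g. 0.12 for twelve
    percentage points).  Output mask is a subset of the input mask.

    For a plain mask without a generating field, a surface-biased surrogate
    field (interior distance with seeded sub-voxel jitter) is used, which
    likewise erodes bone from the surface inward.
    """
    if isinstance(phantom, TrabecularPhantom):
        roi, fld = phantom.roi, phantom.field_values
        seed = phantom.seed
    else:
        roi = phantom
        rng = np.random.default_rng(seed)
        fld = ndi.distance_transform_edt(roi.mask) + rng.uniform(0.0, 0.5, roi.mask.shape)
        fld[~roi.mask] = -np.inf
    region = roi.region
    current = roi.bone_count() / region.sum()
    if delta_bv_tv < 0:
        raise ValueError("delta_bv_tv must be non-negative")
    if delta_bv_tv == 0:
        return TrabecularPhantom(roi, roi.mask.copy(), fld, -np.inf, current, seed)
    target = current - delta_bv_tv
    if target <= 0:
        raise ValueError(
            f"delta {delta_bv_tv:.3f} >= current bone fraction {current:.3f}")
    inside = fld[region & roi.mask]
    # threshold among current bone values so the new mask is a strict subset
    keep = target * region.sum() / inside.size
    thr = float(np.quantile(inside, 1.0 - keep))
    new_mask = roi.mask & (fld > thr)
    new_roi = BinaryROI(new_mask, roi.voxel_size, roi.cylinder, region)
    achieved = new_roi.bone_count() / region.sum()
    if abs(achieved - target) > 0.005:
        raise RuntimeError(
            f"threshold search missed target: {achieved:.4f} vs {target:.4f}")
    return TrabecularPhantom(new_roi, new_mask, fld, thr, target, seed)


def add_foramen(roi: BinaryROI, radius_mm: float) -> BinaryROI:
    """Clear a transverse channel at mid-height (a vascular-foramen stand-in).

    The channel runs along the second in-plane axis through the full width,
    centered on the cylinder axis.
    """
    if radius_mm == 0.0:
        return roi
    if radius_mm < 0:
        raise ValueError("radius must be non-negative")
    if radius_mm >= roi.diameter_mm / 2.0:
        raise ValueError("foramen radius must be smaller than the cylinder radius")
    nz, ny, nx = roi.mask.shape
    r_vox = radius_mm / roi.voxel_size
    zc = (nz - 1) / 2.0
    xc = roi.cylinder.center_xy[1] if roi.cylinder is not None else (nx - 1) / 2.0
    z, x = np.indices((nz, nx))
    channel = (z - zc) ** 2 + (x - xc) ** 2 <= r_vox**2
    mask = roi.mask & ~channel[:, None, :]
    return BinaryROI(mask, roi.voxel_size, roi.cylinder, roi.region)


def gray_from_roi(roi: BinaryROI, bone_gray: int = BONE_GRAY,
                  marrow_gray: int = MARROW_GRAY, noise_sd: float = 0.0,
                  seed: int = 0) -> GrayStack:
    """Render a mask as an 8-bit stack: uniform bone/marrow grays inside the
    ROI (optional Gaussian gray noise), zero outside."""
    vals = np.zeros(roi.mask.shape, dtype=float)
    vals[roi.region] = marrow_gray
    vals[roi.mask] = bone_gray
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals[roi.region] += rng.normal(0.0, noise_sd, int(roi.region.sum()))
    return GrayStack(np.clip(np.round(vals), 0, 255).astype(np.uint8),
                     roi.voxel_size)


# ---------------------------------------------------------------------------
# two-group study generation


@dataclass(frozen=True)
class StudySpec:
    """Design of a synthetic sham-vs-OVX study.

    Defaults emulate the reference conditions: 10 specimens per group, a
    twelve-percentage-point bone-volume deficit in the OVX-like group
    (roughly the 35% -> 23% contrast seen in rat lumbar vertebrae), 18 um
    voxels, and a mid-height foramen.  Cylinder size (48 voxels across,
    72 slices) is a scaled-down rodent vertebral ROI chosen so the whole
    pipeline runs on one CPU in minutes.
    """

    n_per_group: int = 10
    levels: tuple[str, ...] = ("L4",)
    dims: tuple[int, int, int] = (72, 48, 48)
    voxel_size: float = DEFAULT_VOXEL_MM
    scale: tuple[float, float, float] = (4.0, 2.0, 2.0)
    sham_bv_tv_mean: float = 0.35
    sham_bv_tv_sd: float = 0.03
    level_offsets: tuple[float, ...] = (0.0, 0.01, 0.03)  # L4 -> L6 drift
    delta_bv_tv_mean: float = 0.12
    delta_bv_tv_sd: float = 0.015
    foramen_radius_mm: float = 0.08
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if len(self.level_offsets) < len(self.levels):
            raise ValueError("need a level offset per level")


@dataclass
class SpecimenRecord:
    """One generated specimen-level volume with its ground truth."""

    specimen: str
    group: str          # 'sham' | 'ovx'
    level: str
    phantom: TrabecularPhantom
    seed: int
    true_bv_tv: float


def generate_study(spec: StudySpec) -> list[SpecimenRecord]:
    """Generate the paired sham / OVX-like study.

    Each sham specimen-level volume is an independent random-field phantom;
    its OVX sibling re-thresholds the *same* field at a higher level, so the
    two groups differ purely architecturally by the configured bone-volume
    deficit.  All per-specimen seeds derive deterministically from the
    master seed.
    """
    ss = np.random.SeedSequence(spec.master_seed)
    records: list[SpecimenRecord] = []
    n_cells = spec.n_per_group * len(spec.levels)
    children = ss.spawn(n_cells)
    idx = 0
    for i in range(spec.n_per_group):
        for j, level in enumerate(spec.levels):
            child = children[idx]
            idx += 1
            seed = int(child.generate_state(1)[0] % (2**31 - 1))
            rng = np.random.default_rng(child)
            target = float(np.clip(
                rng.normal(spec.sham_bv_tv_mean + spec.level_offsets[j],
                           spec.sham_bv_tv_sd), 0.10, 0.60))
            delta = float(np.clip(rng.normal(spec.delta_bv_tv_mean,
                                             spec.delta_bv_tv_sd), 0.02, target - 0.05))
            sham = gaussian_trabecular(
                dims=spec.dims, scale=spec.scale, target_bv_tv=target,
                voxel_size=spec.voxel_size, seed=seed,
                foramen_radius_mm=spec.foramen_radius_mm)
            # the sham ROI already carries the foramen; the OVX sibling is a
            # subset of it, so the channel is inherited
            ovx = ovx_transform(sham, delta)
            records.append(SpecimenRecord(f"S{i+1:02d}", "sham", level, sham,
                                          seed, sham.bv_tv))
            records.append(SpecimenRecord(f"O{i+1:02d}", "ovx", level, ovx,
                                          seed, ovx.bv_tv))
    return records
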