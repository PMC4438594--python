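"""Trabecular bone structural parameters, in 3D and slice-wise 2D.

The eight-parameter panel for a cylindrical trabecular region:

* BV/TV (%) — bone voxels over total ROI voxels.
* BMD (g/cm^3) — apparent density: mean calibrated density over the whole ROI
  including the marrow space (not a bone-tissue mean).
* Tb.Th / Tb.Sp (mm) — mean maximal-inscribed-sphere diameter of the bone /
  marrow phase (local thickness).
* FD — box-counting fractal dimension.
* Tb.Pf (1/mm) — trabecular bone pattern factor by the dilation method,
  (S1 - S2) / (V1 - V2) under a one-voxel dilation; positive for rod-like /
  predominantly convex structure, negative for concave, well-connected
  structure.
* DA — degree of anisotropy from the mean-intercept-length (MIL) ellipsoid,
  DA = 1 - MIL_min / MIL_max, so 0 is isotropic and values approach 1 for
  strongly oriented structure.
* Conn.Dn (1/mm^3) — connectivity density, (1 - Euler characteristic) of the
  foreground cubical complex per unit ROI volume.

All but Conn.Dn have slice-wise 2D analogs (area fraction, disc-based
thickness, exposed-edge perimeters, in-plane MIL) reported against the
normalized height of the cylinder, caudal (0) to cranial (1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .image_io import BinaryROI, DensityStack

__all__ = [
    "Morphometry3D",
    "SliceMorphometry",
    "bv_tv",
    "mean_bmd",
    "local_thickness_map",
    "local_thickness",
    "fractal_dimension",
    "tb_pf",
    "degree_of_anisotropy",
    "euler_characteristic",
    "connectivity_density",
    "analyze_3d",
    "analyze_slices",
]


@dataclass(frozen=True)
class Morphometry3D:
    """Volume-level structural parameter record (one specimen, one ROI)."""

    bv_tv: float          # %
    bmd: float            # g/cm^3 (apparent, whole ROI)
    tb_th: float          # mm
    tb_sp: float          # mm
    fd: float             # dimensionless
    tb_pf: float          # 1/mm
    da: float             # dimensionless, [0, 1)
    conn_dn: float        # 1/mm^3
    tv: float             # mm^3

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SliceMorphometry:
    """2D structural parameters of one cross-section (no Conn.Dn in 2D)."""

    slice_index: int
    normalized_height: float
    bv_tv: float
    bmd: float
    tb_th: float
    tb_sp: float
    fd: float
    tb_pf: float
    da: float


# ---------------------------------------------------------------------------
# volume fraction and density


def bv_tv(roi: BinaryROI) -> float:
    """Bone volume fraction of the ROI, percent."""
    tv = int(roi.region.sum())
    if tv == 0:
        raise ValueError("empty ROI: total volume is zero")
    return 100.0 * roi.bone_count() / tv


def mean_bmd(density: DensityStack, roi: BinaryROI) -> float:
    """Apparent mineral density: mean over every ROI voxel, bone and marrow."""
    if density.voxels.shape != roi.mask.shape:
        raise ValueError("density stack and ROI shapes differ")
    if not roi.region.any():
        raise ValueError("empty ROI")
    return float(density.voxels[roi.region].mean())


# ---------------------------------------------------------------------------
# local thickness (maximal inscribed spheres)


def local_thickness_map(phase: np.ndarray) -> np.ndarray:
    """Local thickness of a binary phase, in voxel units.

    For every phase voxel: the diameter of the largest sphere that contains
    the voxel and fits entirely inside the phase (distance transform ->
    sphere radii -> sphere assignment).  Sphere radii are taken as the
    Euclidean distance to the nearest background voxel center minus half a
    voxel, i.e. the distance to the phase boundary.

    Works for 2D (largest inscribed disc) and 3D arrays alike.
    """
    phase = np.asarray(phase, dtype=bool)
    if not phase.any():
        raise ValueError("empty phase: local thickness undefined")
    edt = ndi.distance_transform_edt(phase)
    out = np.zeros(phase.shape, dtype=float)
    # iterate distinct center radii from largest to smallest; at each level,
    # voxels within reach of a center of at least that radius get assigned.
    # EDT measures center-to-center distance, so a center of EDT value v
    # anchors a digital sphere of reach v whose diameter in voxels is 2v - 1
    # (a 1-voxel feature has EDT 1 and thickness 1).
    unassigned = phase.copy()
    for v in np.unique(edt[phase])[::-1]:
        if not unassigned.any():
            break
        centers = edt >= v
        d = ndi.distance_transform_edt(~centers)
        covered = unassigned & (d <= v + 1e-9)
        out[covered] = 2.0 * v - 1.0
        unassigned &= ~covered
    return out


def local_thickness(roi: BinaryROI, phase: str = "foreground") -> float:
    """Mean local thickness of the bone ('foreground') or marrow
    ('background') phase inside the ROI, in mm.

    The marrow phase is the ROI region minus bone; everything outside the ROI
    counts as background for both phases, so a phase touching the ROI wall is
    bounded there.
    """
    if phase == "foreground":
        m = roi.mask
    elif phase == "background":
        m = roi.region & ~roi.mask
    else:
        raise ValueError(f"unknown phase: {phase!r}")
    if not m.any():
        raise ValueError(f"empty {phase} phase")
    th = local_thickness_map(m)
    return float(th[m].mean()) * roi.voxel_size


# ---------------------------------------------------------------------------
# fractal dimension


def fractal_dimension(structure: np.ndarray, min_extent: int = 8) -> float:
    """Box-counting fractal dimension of a binary structure (2D or 3D).

    Boxes are laid on a grid anchored at the array corner; the dimension is
    the least-squares slope of log(occupied boxes) against log(1/box size).
    The size ladder uses every box edge from 2 up to floor(N/4) that tiles
    the grid exactly (divides all dimensions), so no partial boundary boxes
    bias the counts; if the grid admits fewer than two such sizes, a dyadic
    ladder with corner-padded partial boxes is used instead.
    """
    m = np.asarray(structure, dtype=bool)
    if not m.any():
        raise ValueError("empty structure: fractal dimension undefined")
    n = max(m.shape)
    if n < min_extent:
        raise ValueError(f"structure extent {n} below the smallest box ladder")
    sizes = [s for s in range(2, n // 4 + 1)
             if all(d % s == 0 for d in m.shape)]
    if len(sizes) < 2:
        sizes = []
        s = 2
        while s <= n // 4:
            sizes.append(s)
            s *= 2
    if len(sizes) < 2:
        raise ValueError("fewer than two box sizes available")
    counts = [_box_count(m, s) for s in sizes]
    slope, _ = np.polyfit(np.log(1.0 / np.asarray(sizes, float)),
                          np.log(np.asarray(counts, float)), 1)
    return float(slope)


def _box_count(m: np.ndarray, s: int) -> int:
    """Number of corner-anchored boxes of edge s containing any foreground."""
    padded_shape = tuple(-(-d // s) * s for d in m.shape)
    if padded_shape != m.shape:
        pad = [(0, p - d) for d, p in zip(m.shape, padded_shape)]
        m = np.pad(m, pad)
    view = m
    for ax, d in enumerate(m.shape):
        view = view.reshape(view.shape[:2 * ax] + (d // s, s) + view.shape[2 * ax + 1:])
    # axes now alternate (block, within); reduce all 'within' axes
    reduce_axes = tuple(range(1, 2 * m.ndim, 2))
    return int(view.any(axis=reduce_axes).sum())


# ---------------------------------------------------------------------------
# trabecular bone pattern factor


def _exposed_faces(m: np.ndarray) -> int:
    """Count voxel faces adjacent to background or to the grid border."""
    total = 0
    for ax in range(m.ndim):
        p = np.pad(m, [(1, 1) if a == ax else (0, 0) for a in range(m.ndim)])
        lo = np.take(p, range(0, m.shape[ax] + 1), axis=ax)
        hi = np.take(p, range(1, m.shape[ax] + 2), axis=ax)
        total += int((lo ^ hi).sum())
    return total


def tb_pf(roi: BinaryROI) -> float:
    """Trabecular bone pattern factor by the dilation method, 1/mm.

    A one-voxel dilation (face-connected structuring element) is applied
    *within* the ROI region — material never grows past the ROI wall, which
    mirrors how a clipped analysis volume behaves.  Surfaces are exposed-face
    counts (faces against background or the grid border), volumes are voxel
    counts; Tb.Pf = (S1 - S2) / (V1 - V2) in 1/mm after unit conversion.
    """
    m = roi.mask
    if not m.any():
        raise ValueError("empty mask")
    struct = ndi.generate_binary_structure(m.ndim, 1)
    dil = ndi.binary_dilation(m, structure=struct) & roi.region
    if (dil == m).all():
        raise ValueError("dilation changes no voxels: Tb.Pf undefined")
    a = roi.voxel_size
    face_area = a ** (m.ndim - 1)
    vox_vol = a ** m.ndim
    s1, s2 = _exposed_faces(m) * face_area, _exposed_faces(dil) * face_area
    v1, v2 = m.sum() * vox_vol, dil.sum() * vox_vol
    return float((s1 - s2) / (v1 - v2))


# ---------------------------------------------------------------------------
# degree of anisotropy (mean intercept length)


def _sphere_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform directions on the hemisphere (Fibonacci spiral with a
    random seeded longitude offset)."""
    i = np.arange(n)
    phi = (1 + 5**0.5) / 2
    z = (i + 0.5) / n                       # hemisphere: z in (0, 1)
    theta = 2 * np.pi * ((i / phi) % 1.0) + rng.uniform(0, 2 * np.pi)
    r = np.sqrt(1 - z**2)
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _mil_one_direction(mask: np.ndarray, region: np.ndarray, direction: np.ndarray,
                       n_lines: int, rng: np.random.Generator,
                       step: float = 0.5) -> tuple[float, int]:
    """Total bone intercept length (voxel units) and interface count along a
    bundle of parallel test lines in the given direction."""
    shape = np.asarray(mask.shape, dtype=float)
    center = (shape - 1) / 2.0
    radius = float(np.linalg.norm(shape)) / 2.0
    d = direction / np.linalg.norm(direction)
    # orthonormal in-plane basis
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, a); u /= np.linalg.norm(u)
    v = np.cross(d, u)
    offsets = rng.uniform(-radius, radius, size=(n_lines, 2))
    ts = np.arange(-radius, radius, step)
    bone_len = 0.0
    interfaces = 0
    for ou, ov in offsets:
        pts = center + ou * u + ov * v + ts[:, None] * d
        idx = np.round(pts).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(mask.shape)), axis=1)
        if not ok.any():
            continue
        iz, iy, ix = idx[ok, 0], idx[ok, 1], idx[ok, 2]
        valid = region[iz, iy, ix]
        vals = mask[iz, iy, ix] & valid
        bone_len += float(vals.sum()) * step
        # count bone<->marrow transitions where both samples are in the region
        both = valid[1:] & valid[:-1]
        interfaces += int((vals[1:] != vals[:-1])[both].sum())
    return bone_len, interfaces


def degree_of_anisotropy(roi: BinaryROI, n_directions: int = 49,
                         n_lines: int = 64, seed: int = 0) -> float:
    """Degree of anisotropy from the MIL ellipsoid, DA = 1 - MIL_min/MIL_max.

    Mean intercept lengths are measured along quasi-uniform directions
    (Fibonacci hemisphere, seeded rotation); the classical ellipsoid fit
    n^T A n = 1/MIL(n)^2 gives the MIL tensor, whose extreme principal
    lengths define DA in [0, 1): 0 for isotropy, approaching 1 for fully
    oriented structure.
    """
    mask, region = roi.mask, roi.region
    if not mask.any():
        raise ValueError("empty mask: no intercepts")
    if not (region & ~mask).any():
        raise ValueError("fully solid mask: no bone/void interceptions")
    rng = np.random.default_rng(seed)
    dirs = _sphere_directions(n_directions, rng)
    mils, used_dirs = [], []
    cap = float(np.linalg.norm(mask.shape))  # MIL cap for interface-free directions
    for d in dirs:
        # direction vector in (z, y, x) index space
        bone_len, ifaces = _mil_one_direction(mask, region, d[::-1], n_lines, rng)
        if bone_len == 0.0:
            continue
        mil = bone_len / ifaces * 2.0 if ifaces > 0 else cap
        mils.append(min(mil, cap))
        used_dirs.append(d)
    if not mils:
        raise ValueError("no intercepts found along any sampled direction")
    dirs = np.asarray(used_dirs)
    y = 1.0 / np.square(mils)
    # design matrix for the symmetric tensor A (6 unknowns)
    x, yy, z = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    X = np.stack([x * x, yy * yy, z * z, 2 * x * yy, 2 * yy * z, 2 * x * z], axis=1)
    c, *_ = np.linalg.lstsq(X, y, rcond=None)
    A = np.array([[c[0], c[3], c[5]], [c[3], c[1], c[4]], [c[5], c[4], c[2]]])
    w = np.linalg.eigvalsh(A)
    w = np.clip(w, 1e-12, None)
    # small eigenvalue of A <-> long MIL axis
    return float(1.0 - np.sqrt(w[0] / w[-1]))


def _mil_2d(mask: np.ndarray, region: np.ndarray, n_directions: int = 18,
            n_lines: int = 32, seed: int = 0) -> float:
    """In-plane DA of a single slice from 2D MIL (ellipse fit)."""
    if not mask.any() or not (region & ~mask).any():
        return float("nan")
    rng = np.random.default_rng(seed)
    thetas = np.pi * (np.arange(n_directions) + rng.uniform()) / n_directions
    shape = np.asarray(mask.shape, dtype=float)
    center = (shape - 1) / 2.0
    radius = float(np.linalg.norm(shape)) / 2.0
    step = 0.5
    ts = np.arange(-radius, radius, step)
    mils, used = [], []
    cap = 2.0 * radius
    for th in thetas:
        d = np.array([np.sin(th), np.cos(th)])   # (row, col)
        n = np.array([-d[1], d[0]])
        bone_len, ifaces = 0.0, 0
        for o in rng.uniform(-radius, radius, n_lines):
            pts = center + o * n + ts[:, None] * d
            idx = np.round(pts).astype(int)
            ok = np.all((idx >= 0) & (idx < np.asarray(mask.shape)), axis=1)
            if not ok.any():
                continue
            iy, ix = idx[ok, 0], idx[ok, 1]
            valid = region[iy, ix]
            vals = mask[iy, ix] & valid
            bone_len += float(vals.sum()) * step
            both = valid[1:] & valid[:-1]
            ifaces += int((vals[1:] != vals[:-1])[both].sum())
        if bone_len == 0.0:
            continue
        mils.append(min(bone_len / ifaces * 2.0 if ifaces else cap, cap))
        used.append(th)
    if len(mils) < 3:
        return float("nan")
    y = 1.0 / np.square(mils)
    c, s = np.cos(used), np.sin(used)
    X = np.stack([c * c, s * s, 2 * c * s], axis=1)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    A = np.array([[coef[0], coef[2]], [coef[2], coef[1]]])
    w = np.clip(np.linalg.eigvalsh(A), 1e-12, None)
    return float(1.0 - np.sqrt(w[0] / w[-1]))


# ---------------------------------------------------------------------------
# connectivity (Euler characteristic of the cubical complex)


def euler_characteristic(mask: np.ndarray) -> int:
    """Euler characteristic of the foreground cubical complex.

    Each foreground voxel contributes a closed unit cube; chi is
    vertices - edges + faces - cells of the union complex.  This closed-cover
    convention corresponds to 26-connectivity of the foreground.
    """
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 3:
        raise ValueError("3D mask required")
    cells = int(m.sum())

    def _union(axes: tuple[int, ...]) -> int:
        # lattice elements spanned along `axes`: present iff any incident voxel
        out = np.pad(m, [(1, 1) if ax not in axes else (0, 0) for ax in range(3)])
        for ax in range(3):
            if ax not in axes:
                lo = np.take(out, range(0, out.shape[ax] - 1), axis=ax)
                hi = np.take(out, range(1, out.shape[ax]), axis=ax)
                out = lo | hi
        return int(out.sum())

    vertices = _union(())
    edges = _union((0,)) + _union((1,)) + _union((2,))
    faces = _union((0, 1)) + _union((0, 2)) + _union((1, 2))
    return vertices - edges + faces - cells


def connectivity_density(roi: BinaryROI) -> float:
    """Connectivity density Conn.Dn = (1 - chi) / TV, in 1/mm^3.

    The connectivity estimate Conn = 1 - chi equals the first Betti number
    for a single connected component with no enclosed cavities; it is
    reported as-is (with a warning) when the mask has several components.
    """
    if not roi.mask.any():
        raise ValueError("empty mask")
    chi = euler_characteristic(roi.mask)
    n_comp, _ = _label_26(roi.mask)
    if n_comp > 1:
        warnings.warn(
            f"mask has {n_comp} 26-connected components; Conn = 1 - chi reported as-is",
            stacklevel=2,
        )
    return (1 - chi) / roi.tv_mm3


def _label_26(mask: np.ndarray) -> tuple[int, np.ndarray]:
    labels, n = ndi.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    return n, labels


# ---------------------------------------------------------------------------
# composite reports


def analyze_3d(roi: BinaryROI, density: DensityStack | None = None,
               da_seed: int = 0) -> Morphometry3D:
    """Full 3D parameter panel for one ROI.

    BMD is NaN when no density stack is given.  Degenerate geometry is
    reported rather than raised: a fully solid ROI has Tb.Sp = 0 (no marrow
    phase) and undefined (NaN) anisotropy and pattern factor.
    """
    solid = not (roi.region & ~roi.mask).any()
    try:
        pf = tb_pf(roi)
    except ValueError:
        pf = float("nan")
    return Morphometry3D(
        bv_tv=bv_tv(roi),
        bmd=mean_bmd(density, roi) if density is not None else float("nan"),
        tb_th=local_thickness(roi, "foreground"),
        tb_sp=0.0 if solid else local_thickness(roi, "background"),
        fd=fractal_dimension(roi.mask),
        tb_pf=pf,
        da=float("nan") if solid else degree_of_anisotropy(roi, seed=da_seed),
        conn_dn=connectivity_density(roi),
        tv=roi.tv_mm3,
    )


def analyze_slices(roi: BinaryROI, density: DensityStack | None = None,
                   da_seed: int = 0) -> list[SliceMorphometry]:
    """Slice-wise 2D parameter panel along the caudal -> cranial axis.

    2D analogs: area fraction, mean density over the slice disc, disc-based
    local thickness/separation, 2D box counting, exposed-edge perimeter
    pattern factor, and in-plane MIL anisotropy.  Connectivity has no 2D
    analog and is omitted by construction.
    """
    nz = roi.n_slices
    if nz < 2:
        raise ValueError("at least two slices required for a height curve")
    out: list[SliceMorphometry] = []
    for k in range(nz):
        m2, r2 = roi.mask[k], roi.region[k]
        tv2 = int(r2.sum())
        frac = 100.0 * m2.sum() / tv2 if tv2 else float("nan")
        bmd2 = float(density.voxels[k][r2].mean()) if density is not None and tv2 else float("nan")
        if m2.any():
            th = float(local_thickness_map(m2)[m2].mean()) * roi.voxel_size
            fd2 = _fd_or_nan(m2)
            pf2 = _tb_pf_2d(m2, r2, roi.voxel_size)
            da2 = _mil_2d(m2, r2, seed=da_seed)
        else:
            th, fd2, pf2, da2 = 0.0, float("nan"), float("nan"), float("nan")
        marrow = r2 & ~m2
        sp = float(local_thickness_map(marrow)[marrow].mean()) * roi.voxel_size if marrow.any() else 0.0
        out.append(SliceMorphometry(
            slice_index=k,
            normalized_height=k / (nz - 1),
            bv_tv=frac, bmd=bmd2, tb_th=th, tb_sp=sp, fd=fd2, tb_pf=pf2, da=da2,
        ))
    return out


def _fd_or_nan(m2: np.ndarray) -> float:
    try:
        return fractal_dimension(m2)
    except ValueError:
        return float("nan")


def _tb_pf_2d(m2: np.ndarray, r2: np.ndarray, voxel_size: float) -> float:
    struct = ndi.generate_binary_structure(2, 1)
    dil = ndi.binary_dilation(m2, structure=struct) & r2
    if (dil == m2).all():
        return float("nan")
    p1, p2 = _exposed_faces(m2) * voxel_size, _exposed_faces(dil) * voxel_size
    a1, a2 = m2.sum() * voxel_size**2, dil.sum() * voxel_size**2
    return float((p1 - p2) / (a1 - a2))


def slices_to_frame(slices: list[SliceMorphometry]) -> pd.DataFrame:
    """Slice records as a tidy DataFrame (one row per slice)."""
    return pd.DataFrame([asdict(s) for s in slices])
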