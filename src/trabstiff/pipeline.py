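"""End-to-end workflow: stacks -> morphometry -> region selection -> micro-FE.

Per specimen: calibrate gray values to density, segment bone, restrict to the
cylindrical ROI, compute the 3D parameter panel and the slice-wise 2D curves.
Per group: average the curves, difference the group means, and choose the
axial sub-region for FEA (default: the fixed caudal 40% of the cylinder).
Per specimen again: mesh the selected sub-region, solve uniaxial compression,
and report k, k', k/k' together with the 3D morphometry of the same
sub-region.  Finally the study battery: group-by-level summary tables,
between-group tests, and within-group Pearson correlations of each regional
parameter against the stiffness index.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import microfe, morphometry, stats
from .curves_select import (ParameterCurve, RegionSelection, average_group,
                            difference_curve, fixed_caudal_selection,
                            select_region)
from .image_io import (BinaryROI, DensityStack, SegmentationParams,
                       apply_calibration, extract_cylinder,
                       fit_density_calibration, restrict_density, segment)
from .phantoms import SpecimenRecord, StudySpec, generate_study, gray_from_roi

log = logging.getLogger("trabstiff.pipeline")

CURVE_PARAMS = ("bv_tv", "bmd", "tb_th", "tb_sp", "fd", "tb_pf")


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline settings; defaults are the reference study settings
    (threshold 70-255, caudal fraction 0.4, E = 24.5 GPa, nu = 0.3,
    strain = 0.05)."""

    study: StudySpec = field(default_factory=StudySpec)
    anchors: tuple[tuple[float, float], tuple[float, float]] = ((60.0, 0.25),
                                                               (220.0, 0.75))
    threshold: tuple[int, int] = (70, 255)
    selection_fraction: float = 0.4
    selection_mode: str = "fixed-caudal"   # 'fixed-caudal' | 'scored'
    material: microfe.Material = field(default_factory=microfe.Material)
    strain: float = 0.05
    fe_mode: str = "bonded"
    solver_tol: float = 1.0e-8
    n_curve_points: int = 100
    gray_noise_sd: float = 4.0
    compute_curves: bool = True   # slice curves are only required for scored selection
    write_inp: bool = False
    out_dir: str | None = None
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """Everything the pipeline computes, as tidy frames."""

    morpho_full: pd.DataFrame        # 3D panel of the whole cylinder
    morpho_region: pd.DataFrame      # 3D panel + k/k' of the selected region
    curves: pd.DataFrame             # per-specimen slice curves
    selection: RegionSelection
    summary_full: pd.DataFrame
    summary_region: pd.DataFrame
    correlations: pd.DataFrame       # parameter vs k/k', per group + pooled
    stiffness_tests: dict            # between-group tests on k/k'
    manifest: dict


def _specimen_rois(rec: SpecimenRecord, cfg: PipelineConfig):
    """Render, calibrate, segment and crop one specimen volume."""
    roi0 = rec.phantom.roi
    gray = gray_from_roi(roi0, noise_sd=cfg.gray_noise_sd, seed=rec.seed)
    calib = fit_density_calibration(cfg.anchors)
    density = apply_calibration(gray, calib)
    seg = segment(gray, SegmentationParams(*cfg.threshold))
    cyl = roi0.cylinder
    roi = extract_cylinder(seg, roi0.voxel_size, cyl.center_xy, cyl.diameter_mm,
                           0, seg.shape[0])
    return roi, restrict_density(density, roi)


def _crop_axial(roi: BinaryROI, z0: int, z1: int) -> BinaryROI:
    return BinaryROI(roi.mask[z0:z1], roi.voxel_size, roi.cylinder,
                     roi.region[z0:z1])


def run_pipeline(cfg: PipelineConfig) -> StudyReport:
    t0 = time.perf_counter()
    records = generate_study(cfg.study)
    records = sorted(records, key=lambda r: (r.group, r.specimen, r.level))

    morpho_rows, curve_rows = [], []
    rois, densities = {}, {}
    for rec in records:
        key = (rec.specimen, rec.level)
        roi, dens = _specimen_rois(rec, cfg)
        rois[key], densities[key] = roi, dens
        m3 = morphometry.analyze_3d(roi, dens, da_seed=cfg.seed)
        morpho_rows.append({"specimen": rec.specimen, "group": rec.group,
                            "level": rec.level, **m3.as_dict()})
        if cfg.compute_curves or cfg.selection_mode == "scored":
            for s in morphometry.analyze_slices(roi, dens, da_seed=cfg.seed):
                curve_rows.append({"specimen": rec.specimen, "group": rec.group,
                                   "level": rec.level, **dataclasses.asdict(s)})
        log.info("morphometry done for %s/%s", rec.specimen, rec.level)
    morpho_full = pd.DataFrame(morpho_rows)
    curves = pd.DataFrame(curve_rows)

    n_slices = cfg.study.dims[0]
    if cfg.selection_mode == "fixed-caudal":
        selection = fixed_caudal_selection(cfg.selection_fraction, n_slices)
    else:
        diffs = []
        for p in CURVE_PARAMS:
            grp_curves = {}
            for grp in ("sham", "ovx"):
                cs = []
                for (spec_id, level), _ in rois.items():
                    sub = curves[(curves.specimen == spec_id) & (curves.level == level)]
                    if sub.empty or sub.iloc[0]["group"] != grp:
                        continue
                    vals = sub.sort_values("normalized_height")
                    v = np.nan_to_num(vals[p].to_numpy(), nan=0.0)
                    cs.append(ParameterCurve(p, vals["normalized_height"].to_numpy(), v))
                grp_curves[grp] = average_group(cs, cfg.n_curve_points)
            diffs.append(difference_curve(grp_curves["sham"], grp_curves["ovx"],
                                          cfg.n_curve_points))
        selection = select_region(diffs, cfg.selection_fraction, n_slices)
    z0, z1 = selection.z_window
    log.info("selected axial window [%d, %d) (%s)", z0, z1, selection.anchor)

    region_rows = []
    inp_texts = {}
    for rec in records:
        key = (rec.specimen, rec.level)
        sub = _crop_axial(rois[key], z0, z1)
        subdens = DensityStack(densities[key].voxels[z0:z1], sub.voxel_size)
        m3 = morphometry.analyze_3d(sub, subdens, da_seed=cfg.seed)
        try:
            mesh = microfe.build_mesh(sub)
        except microfe.NoLoadPathError:
            # a structure with no spanning bone carries no load: k = 0
            log.warning("%s/%s: no load path in the selected region; k = 0",
                        rec.specimen, rec.level)
            area = np.pi * sub.diameter_mm**2 / 4.0
            k_prime = cfg.material.e_mpa * area / sub.height_mm
            region_rows.append({
                "specimen": rec.specimen, "group": rec.group,
                "level": rec.level, **m3.as_dict(), "k": 0.0,
                "k_prime": k_prime, "k_over_kprime": 0.0,
                "removed_fraction": 1.0, "n_elements": 0,
                "residual": 0.0,
            })
            continue
        if mesh.removed_fraction > 0.05:
            log.warning("%s/%s: %.1f%% of bone removed as non-load-bearing",
                        rec.specimen, rec.level, 100 * mesh.removed_fraction)
        bcs = microfe.make_boundary_conditions(mesh, strain=cfg.strain,
                                               mode=cfg.fe_mode)
        sol = microfe.solve(mesh, cfg.material, bcs, tol=cfg.solver_tol)
        res = microfe.stiffness_index(sol, sub.diameter_mm, cfg.material)
        region_rows.append({
            "specimen": rec.specimen, "group": rec.group, "level": rec.level,
            **m3.as_dict(), "k": res.k, "k_prime": res.k_prime,
            "k_over_kprime": res.index,
            "removed_fraction": mesh.removed_fraction,
            "n_elements": mesh.n_elements, "residual": sol.residual,
        })
        if cfg.write_inp:
            inp_texts[key] = microfe.export_inp(mesh, cfg.material, bcs)
        log.info("FE done for %s/%s (%d elements)", rec.specimen, rec.level,
                 mesh.n_elements)

    morpho_region = pd.DataFrame(region_rows)

    params = ["bv_tv", "bmd", "tb_th", "tb_sp", "fd", "tb_pf", "da", "conn_dn"]
    summary_full = _tidy_summary(morpho_full, params)
    summary_region = _tidy_summary(morpho_region, params + ["k_over_kprime"])

    corr_rows = []
    for p in params:
        for grp, dgrp in list(morpho_region.groupby("group")) + [("pooled", morpho_region)]:
            if dgrp[p].nunique() < 2 or len(dgrp) < 3:
                continue
            r = stats.pearson(dgrp[p], dgrp["k_over_kprime"])
            corr_rows.append({"parameter": p, "group": grp, "r": r.statistic,
                              "p": r.p, "n": len(dgrp),
                              "per_reference_design": grp != "pooled"})
    correlations = pd.DataFrame(corr_rows)

    stiff_tests = {}
    for level in morpho_region["level"].unique():
        d = morpho_region[morpho_region.level == level]
        sham = d[d.group == "sham"]["k_over_kprime"].to_numpy()
        ovx = d[d.group == "ovx"]["k_over_kprime"].to_numpy()
        if sham.size >= 2 and ovx.size >= 2:
            t = stats.mann_whitney_u(sham, ovx, mode="asymptotic")
            stiff_tests[level] = {"U": t.statistic, "p": t.p,
                                  "sham_mean": float(sham.mean()),
                                  "ovx_mean": float(ovx.mean())}

    manifest = {
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.study.master_seed,
        "selection": {"anchor": selection.anchor, "fraction": selection.fraction,
                      "z_window": list(selection.z_window)},
        "n_specimens": len(records),
        "versions": _versions(),
        "elapsed_s": round(time.perf_counter() - t0, 1),
    }
    report = StudyReport(morpho_full, morpho_region, curves, selection,
                         summary_full, summary_region, correlations,
                         stiff_tests, manifest)
    if cfg.out_dir:
        _write_outputs(report, inp_texts, cfg)
    return report


def _tidy_summary(frame: pd.DataFrame, params: list[str]) -> pd.DataFrame:
    melted = frame.melt(id_vars=["specimen", "group", "level"],
                        value_vars=params, var_name="parameter")
    levels = sorted(melted["level"].unique())
    if len(levels) >= 2:
        return stats.summarize_study(melted)
    rows = []
    for (param, grp), d in melted.groupby(["parameter", "group"]):
        rows.append({"parameter": param, "group": grp,
                     "mean": d["value"].mean(), "sd": d["value"].std(ddof=1),
                     "n": len(d)})
    return pd.DataFrame(rows)


def _versions() -> dict:
    import numpy, pandas, scipy

    from . import __version__
    return {"trabstiff": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__}


def _write_outputs(report: StudyReport, inp_texts: dict,
                   cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.morpho_full.to_csv(out / "morphometry_3d_full.csv", index=False)
    report.morpho_region.to_csv(out / "morphometry_3d_region.csv", index=False)
    report.curves.to_csv(out / "curves_2d.csv", index=False)
    report.summary_full.to_csv(out / "summary_full.csv", index=False)
    report.summary_region.to_csv(out / "summary_region.csv", index=False)
    report.correlations.to_csv(out / "correlations.csv", index=False)
    (out / "stiffness_tests.json").write_text(
        json.dumps(report.stiffness_tests, indent=2))
    (out / "manifest.json").write_text(json.dumps(report.manifest, indent=2))
    for (spec_id, level), text in inp_texts.items():
        (out / f"{spec_id}_{level}.inp").write_text(text)
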