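"""Serialization of pipeline artifacts.

Every stage consumes only serialized artifacts of previous stages, so a
run is restartable at any stage.  Formats are deliberately plain: OCT
stacks as multi-page TIFF with a JSON calibration sidecar, silhouettes
and maps as CSV, everything else as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .coregister import Landmark, Registration
from .errors import FormatError
from .geometry import SideBranch, VesselGeometry
from .grids import BinGrid, CapMap2D, ScalarMap2D, WssMap2D
from .oct_cap import OctPullback, Roi, ThicknessProfile
from .phantom import CapField, PhantomConfig, PhantomTruth
from .vessel_recon import ProjectionContours

__all__ = [
    "write_pullback", "read_pullback", "write_projections", "read_projections",
    "write_geometry", "read_geometry", "write_map", "read_map",
    "write_landmarks", "read_landmarks", "write_roi", "read_roi",
    "write_registration", "read_registration", "write_truth_bundle",
    "read_truth_bundle", "write_cap_measurements", "read_cap_measurements",
    "phantom_config_to_dict", "phantom_config_from_dict",
]


# ---------------------------------------------------------------- pullback

def write_pullback(pullback: OctPullback, path) -> None:
    path = Path(path)
    data = np.clip(pullback.frames * 10000.0, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = {
        "inter_frame_um": pullback.inter_frame_um,
        "radial_pixel_um": pullback.radial_pixel_um,
        "n_alines": int(pullback.n_alines),
        "intensity_scale": 10000.0,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_pullback(path) -> OctPullback:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing calibration sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    frames = tifffile.imread(path).astype(np.float32) / meta.get("intensity_scale", 1.0)
    if frames.ndim == 2:
        frames = frames[None]
    return OctPullback(frames=frames, radial_pixel_um=meta["radial_pixel_um"],
                       inter_frame_um=meta["inter_frame_um"])


# -------------------------------------------------------------- projections

def write_projections(views: list[ProjectionContours], path) -> None:
    rows = []
    for v in views:
        for side, y in (("left", v.y_left_mm), ("right", v.y_right_mm)):
            rows.append(pd.DataFrame({
                "x_mm": v.s_mm, "y_mm": y, "side": side,
                "view": v.view_angle_deg}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_projections(path) -> list[ProjectionContours]:
    df = pd.read_csv(path)
    required = {"x_mm", "y_mm", "side", "view"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: projection CSV needs columns {sorted(required)}")
    out = []
    for angle, g in df.groupby("view", sort=True):
        left = g[g["side"] == "left"].sort_values("x_mm")
        right = g[g["side"] == "right"].sort_values("x_mm")
        if len(left) != len(right):
            raise FormatError(f"{path}: unpaired silhouette points in view {angle}")
        out.append(ProjectionContours(
            view_angle_deg=float(angle), s_mm=left["x_mm"].to_numpy(),
            y_left_mm=left["y_mm"].to_numpy(), y_right_mm=right["y_mm"].to_numpy()))
    return out


# ----------------------------------------------------------------- geometry

def write_geometry(geom: VesselGeometry, path) -> None:
    payload = {
        "s_mm": geom.s_mm.tolist(),
        "centerline_mm": geom.centerline_mm.tolist(),
        "a_mm": geom.a_mm.tolist(),
        "b_mm": geom.b_mm.tolist(),
        "psi_deg": geom.psi_deg.tolist(),
        "is_extension": geom.is_extension.astype(int).tolist(),
        "branches": [dataclasses.asdict(b) for b in geom.branches],
    }
    Path(path).write_text(json.dumps(payload))


def read_geometry(path) -> VesselGeometry:
    d = json.loads(Path(path).read_text())
    return VesselGeometry(
        s_mm=np.asarray(d["s_mm"]), centerline_mm=np.asarray(d["centerline_mm"]),
        a_mm=np.asarray(d["a_mm"]), b_mm=np.asarray(d["b_mm"]),
        psi_deg=np.asarray(d["psi_deg"]),
        branches=[SideBranch(**b) for b in d["branches"]],
        is_extension=np.asarray(d["is_extension"], dtype=bool))


# --------------------------------------------------------------------- maps

def write_map(m: ScalarMap2D, base_path) -> None:
    """Write a binned map as a CSV matrix (rows: s bins, columns: theta
    bins, edges in the headers) plus counts and a metadata sidecar."""
    base = Path(base_path)
    cols = [f"theta_{lo:g}_{hi:g}" for lo, hi in
            zip(m.grid.theta_edges()[:-1], m.grid.theta_edges()[1:])]
    idx = [f"s_{lo:g}_{hi:g}" for lo, hi in
           zip(m.grid.s_edges()[:-1], m.grid.s_edges()[1:])]
    pd.DataFrame(m.values, index=idx, columns=cols).to_csv(base.with_suffix(".csv"))
    pd.DataFrame(m.counts, index=idx, columns=cols).to_csv(
        base.with_suffix(".counts.csv"))
    meta = {
        "ds_mm": m.grid.ds_mm, "dtheta_deg": m.grid.dtheta_deg,
        "length_mm": m.grid.length_mm,
        "kind": type(m).__name__,
        "normalized": bool(getattr(m, "normalized", False)),
    }
    base.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def read_map(base_path) -> ScalarMap2D:
    base = Path(base_path)
    meta = json.loads(base.with_suffix(".meta.json").read_text())
    values = pd.read_csv(base.with_suffix(".csv"), index_col=0).to_numpy()
    counts = pd.read_csv(base.with_suffix(".counts.csv"), index_col=0).to_numpy()
    grid = BinGrid(length_mm=meta["length_mm"], ds_mm=meta["ds_mm"],
                   dtheta_deg=meta["dtheta_deg"])
    if meta["kind"] == "CapMap2D":
        return CapMap2D(grid=grid, values=values, counts=counts)
    return WssMap2D(grid=grid, values=values, counts=counts,
                    normalized=meta.get("normalized", False))


# ---------------------------------------------------------------- landmarks

def write_landmarks(landmarks: list[Landmark], path) -> None:
    Path(path).write_text(json.dumps(
        [dataclasses.asdict(lm) for lm in landmarks], indent=2))


def read_landmarks(path) -> list[Landmark]:
    return [Landmark(**d) for d in json.loads(Path(path).read_text())]


def write_roi(roi: Roi, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(roi), indent=2))


def read_roi(path) -> Roi:
    return Roi(**json.loads(Path(path).read_text()))


# ------------------------------------------------------------- registration

def write_registration(reg: Registration, path) -> None:
    payload = {
        "anchor_frames": reg.anchor_frames.tolist(),
        "anchor_s_mm": reg.anchor_s_mm.tolist(),
        "rot_anchor_frames": list(reg.rot_anchor_frames)
        if reg.rot_anchor_frames else None,
        "rot_anchor_offsets_deg": list(reg.rot_anchor_offsets_deg)
        if reg.rot_anchor_offsets_deg else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_registration(path) -> Registration:
    d = json.loads(Path(path).read_text())
    return Registration(
        anchor_frames=np.asarray(d["anchor_frames"]),
        anchor_s_mm=np.asarray(d["anchor_s_mm"]),
        rot_anchor_frames=tuple(d["rot_anchor_frames"])
        if d["rot_anchor_frames"] else None,
        rot_anchor_offsets_deg=tuple(d["rot_anchor_offsets_deg"])
        if d["rot_anchor_offsets_deg"] else None)


# ------------------------------------------------------------ phantom truth

def phantom_config_to_dict(cfg: PhantomConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["cap_thickness_field"] = {"kind": cfg.cap_thickness_field.kind,
                                "params": dict(cfg.cap_thickness_field.params)}
    return d


def phantom_config_from_dict(d: dict) -> PhantomConfig:
    d = dict(d)
    if "cap_thickness_field" in d and isinstance(d["cap_thickness_field"], dict):
        d["cap_thickness_field"] = CapField(**d["cap_thickness_field"])
    for key in ("branch_positions_mm", "branch_angles_deg", "branch_diameters_mm",
                "cap_s_range_mm", "cap_theta_range_deg"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return PhantomConfig(**d)


def write_truth_bundle(truth: PhantomTruth, outdir) -> None:
    """Ground truth stored alongside rendered data: JSON for the scalar
    records, CSV tables for the per-frame contours."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": phantom_config_to_dict(truth.config),
        "frame_z_mm": truth.frame_z_mm.tolist(),
        "rotation_offset_deg": truth.rotation_offset_deg.tolist(),
    }
    (outdir / "truth.json").write_text(json.dumps(meta))
    write_geometry(truth.geometry, outdir / "truth_geometry.json")
    np.savetxt(outdir / "truth_lumen_um.csv", truth.lumen_radius_um,
               delimiter=",", fmt="%.3f")
    np.savetxt(outdir / "truth_abluminal_um.csv", truth.abluminal_radius_um,
               delimiter=",", fmt="%.3f")


def read_truth_bundle(outdir) -> PhantomTruth:
    outdir = Path(outdir)
    meta = json.loads((outdir / "truth.json").read_text())
    return PhantomTruth(
        config=phantom_config_from_dict(meta["config"]),
        geometry=read_geometry(outdir / "truth_geometry.json"),
        frame_z_mm=np.asarray(meta["frame_z_mm"]),
        rotation_offset_deg=np.asarray(meta["rotation_offset_deg"]),
        lumen_radius_um=np.loadtxt(outdir / "truth_lumen_um.csv", delimiter=","),
        abluminal_radius_um=np.loadtxt(outdir / "truth_abluminal_um.csv",
                                       delimiter=","))


# --------------------------------------------------------- cap measurements

def write_cap_measurements(profiles: list[ThicknessProfile],
                           lumens: dict, path) -> None:
    """Per-(frame, A-line) contour radii and thickness as one CSV."""
    rows = []
    for p in profiles:
        lum = lumens.get(p.frame_index)
        r_lum = (lum.radius_um[p.alines] if lum is not None
                 else np.full(p.alines.size, np.nan))
        rows.append(pd.DataFrame({
            "frame": p.frame_index, "a_line": p.alines, "z_mm": p.z_mm,
            "r_lumen_um": r_lum,
            "thickness_um": p.thickness_um}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_cap_measurements(path) -> list[ThicknessProfile]:
    df = pd.read_csv(path)
    out = []
    for frame, g in df.groupby("frame", sort=True):
        out.append(ThicknessProfile(
            alines=g["a_line"].to_numpy(), thickness_um=g["thickness_um"].to_numpy(),
            frame_index=int(frame), z_mm=float(g["z_mm"].iloc[0])))
    return out
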