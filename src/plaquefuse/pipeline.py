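"""End-to-end orchestration: phantom -> segmentation -> reconstruction ->
WSS -> registration -> fusion, from a single configuration.

Manual steps of the clinical workflow (ROI selection, landmark
identification, 2D angiographic contour segmentation) are replaced by
annotation files that the phantom stage writes, so a run is fully
headless.  Every stage consumes only serialized artifacts of previous
stages and writes its own, making runs restartable stage by stage; the
run summary is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .coregister import (area_agreement, axial_map, resample_cap_to_grid,
                         rotational_map)
from .errors import PlaquefuseError
from .grids import BinGrid
from .hemodynamics import (HemoConfig, assign_flows, bin_wss,
                           export_wss_samples, import_external_wss,
                           normalize_map, surrogate_wss)
from .oct_cap import (RepresentativeSamplingConfig, SegmentationParams,
                      lumen_area, representative_thickness,
                      segment_cap_abluminal, segment_lumen, thickness_profile)
from .phantom import (default_config, make_phantom_vessel, render_biplane,
                      render_oct_pullback)
from .risk_fusion import (RiskLevel, RiskThresholds, build_risk_map,
                          threshold_sensitivity)
from .vessel_recon import extend_inlets_outlets, reconstruct_lumen, section_area

__all__ = ["RunConfig", "run_pipeline", "write_report", "StageError"]

log = logging.getLogger("plaquefuse")

STAGES = ("simulate", "segment", "reconstruct", "wss", "register", "fuse")


class StageError(PlaquefuseError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (loadable from YAML)."""

    outdir: str = "plaquefuse_run"
    seed: int = 0
    phantom: dict = field(default_factory=dict)
    view_angles: tuple[float, float] = (0.0, 90.0)
    grid: dict = field(default_factory=dict)            # ds_mm, dtheta_deg
    segmentation: dict = field(default_factory=dict)    # SegmentationParams fields
    hemodynamics: dict = field(default_factory=dict)    # HemoConfig fields
    thresholds: dict = field(default_factory=dict)      # t_cap_um, t_wss_pa
    stages: dict = field(default_factory=dict)          # stage name -> bool
    area_frame_stride: int = 4
    sensitivity: bool = True
    external_wss: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if cfg.external_wss and not Path(cfg.external_wss).exists():
            raise StageError(f"config: external_wss file {cfg.external_wss} not found")
        return cfg

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


def _stage(name: str):
    def deco(fn):
        def wrapped(cfg: RunConfig, out: Path, summary: dict):
            log.info("stage %s: start", name)
            try:
                fn(cfg, out, summary)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
        wrapped.__name__ = name
        return wrapped
    return deco


@_stage("simulate")
def _simulate(cfg: RunConfig, out: Path, summary: dict) -> None:
    base = pio.phantom_config_to_dict(default_config(seed=cfg.seed))
    phantom_cfg = pio.phantom_config_from_dict({**base, **cfg.phantom})
    truth = make_phantom_vessel(phantom_cfg)
    pio.write_truth_bundle(truth, out / "truth")
    pullback = render_oct_pullback(truth)
    pio.write_pullback(pullback, out / "pullback.tif")
    views = render_biplane(truth, tuple(cfg.view_angles))
    pio.write_projections(list(views), out / "projections.csv")
    pio.write_landmarks(truth.landmarks(), out / "landmarks.json")
    pio.write_roi(truth.cap_roi(), out / "roi.json")
    summary["simulate"] = {
        "n_frames": int(pullback.n_frames),
        "n_alines": int(pullback.n_alines),
        "outputs": ["truth/", "pullback.tif", "projections.csv",
                    "landmarks.json", "roi.json"],
    }


@_stage("segment")
def _segment(cfg: RunConfig, out: Path, summary: dict) -> None:
    pullback = pio.read_pullback(out / "pullback.tif")
    roi = pio.read_roi(out / "roi.json")
    params = SegmentationParams(**cfg.segmentation)

    roi_frames = list(roi.frames())
    area_frames = sorted(set(range(0, pullback.n_frames, max(cfg.area_frame_stride, 1)))
                         | set(roi_frames))
    lumens, areas, profiles = {}, {}, []
    for i in area_frames:
        frame = pullback.frame(i)
        lum = segment_lumen(frame, params)
        lumens[i] = lum
        areas[i] = lumen_area(lum)
        if i in set(roi_frames):
            abl = segment_cap_abluminal(frame, roi, lum, params)
            prof = thickness_profile(lum, abl)
            prof.frame_index = i
            prof.z_mm = frame.z_position_mm
            profiles.append(prof)

    pio.write_cap_measurements(profiles, lumens, out / "cap_measurements.csv")
    with open(out / "lumen_areas.csv", "w") as fh:
        fh.write("frame,z_mm,area_mm2\n")
        for i in area_frames:
            fh.write(f"{i},{i * pullback.inter_frame_um / 1000.0:.4f},{areas[i]:.6f}\n")

    rep = representative_thickness(
        profiles, RepresentativeSamplingConfig(seed=cfg.seed))
    valid = np.concatenate([p.thickness_um[p.valid] for p in profiles])
    summary["segment"] = {
        "n_frames_segmented": len(area_frames),
        "n_cap_frames": len(profiles),
        "cap_mean_um": float(np.mean(valid)),
        "cap_min_um": float(np.min(valid)),
        "cap_representative_um": float(rep),
        "outputs": ["cap_measurements.csv", "lumen_areas.csv"],
    }


@_stage("reconstruct")
def _reconstruct(cfg: RunConfig, out: Path, summary: dict) -> None:
    views = pio.read_projections(out / "projections.csv")
    if len(views) != 2:
        raise ValueError(f"expected 2 views, found {len(views)}")
    truth_geom = pio.read_geometry(out / "truth" / "truth_geometry.json")
    geom = reconstruct_lumen(views[0], views[1], branches=truth_geom.branches)
    geom = extend_inlets_outlets(geom, factor=5.0)
    pio.write_geometry(geom, out / "geometry.json")
    core = ~geom.is_extension
    summary["reconstruct"] = {
        "length_mm": float(geom.length_mm),
        "mean_area_mm2": float(np.mean(section_area(geom.a_mm[core],
                                                    geom.b_mm[core]))),
        "outputs": ["geometry.json"],
    }


@_stage("wss")
def _wss(cfg: RunConfig, out: Path, summary: dict) -> None:
    geom = pio.read_geometry(out / "geometry.json")
    grid = BinGrid(length_mm=geom.length_mm, **cfg.grid)
    if cfg.external_wss:
        samples = import_external_wss(cfg.external_wss)
        flows = None
    else:
        hemo = HemoConfig(**cfg.hemodynamics)
        flows = assign_flows(geom, hemo)
        samples = surrogate_wss(geom, flows, hemo)
        export_wss_samples(samples, out / "wss_samples.csv")
    wss_map = bin_wss(samples, grid)
    wss_norm = normalize_map(wss_map)
    pio.write_map(wss_map, out / "wss_map")
    pio.write_map(wss_norm, out / "wss_map_normalized")
    summary["wss"] = {
        "inlet_q_ml_s": float(flows.inlet_q * 1e6) if flows else None,
        "median_wss_pa": float(np.median(wss_map.counted_values())),
        "outputs": ["wss_samples.csv", "wss_map.csv", "wss_map_normalized.csv"],
    }


@_stage("register")
def _register(cfg: RunConfig, out: Path, summary: dict) -> None:
    landmarks = pio.read_landmarks(out / "landmarks.json")
    branches = [lm for lm in landmarks if lm.kind == "side_branch"]
    if len(branches) < 2:
        raise ValueError("need two side-branch landmarks")
    reg = rotational_map(branches[0], branches[1], axial_map(branches))
    pio.write_registration(reg, out / "registration.json")

    geom = pio.read_geometry(out / "geometry.json")
    grid = BinGrid(length_mm=geom.length_mm, **cfg.grid)
    profiles = pio.read_cap_measurements(out / "cap_measurements.csv")
    pullback = json.loads((out / "pullback.tif.json").read_text())
    capmap = resample_cap_to_grid(profiles, reg, grid, pullback["n_alines"])
    pio.write_map(capmap, out / "cap_map")

    # lumen-area agreement between OCT frames and the reconstruction
    areas = np.loadtxt(out / "lumen_areas.csv", delimiter=",", skiprows=1, ndmin=2)
    s_of_frame = reg.frame_to_s(areas[:, 0])
    inside = (s_of_frame >= geom.s_mm[~geom.is_extension][0]) & \
             (s_of_frame <= geom.s_mm[~geom.is_extension][-1])
    a_i, b_i = geom.interp_axes(s_of_frame[inside])
    r = area_agreement(areas[inside, 2], section_area(a_i, b_i))
    summary["register"] = {
        "rotation_anchor_offsets_deg": [float(x) for x in reg.rot_anchor_offsets_deg],
        "lumen_area_pearson_r": float(r),
        "outputs": ["registration.json", "cap_map.csv"],
    }


@_stage("fuse")
def _fuse(cfg: RunConfig, out: Path, summary: dict) -> None:
    capmap = pio.read_map(out / "cap_map")
    wssmap = pio.read_map(out / "wss_map")
    thresholds = RiskThresholds(**cfg.thresholds)
    risk = build_risk_map(capmap, wssmap, thresholds)
    np.savetxt(out / "risk_map.csv", risk.levels, fmt="%d", delimiter=",")
    _render_risk_png(risk, out / "risk_map.png")

    cap_bins = capmap.covered & wssmap.covered
    mean_wss_cap = float(np.mean(wssmap.values[cap_bins]))
    norm = pio.read_map(out / "wss_map_normalized")
    mean_norm_cap = float(np.mean(norm.values[cap_bins]))
    summary["fuse"] = {
        "thresholds": {"t_cap_um": thresholds.t_cap_um,
                       "t_wss_pa": thresholds.t_wss_pa},
        "risk_fractions": risk.fractions,
        "risk_fractions_cap_covered": risk.fractions_cap_covered,
        "mean_wss_at_cap_pa": mean_wss_cap,
        "mean_normalized_wss_at_cap": mean_norm_cap,
        "outputs": ["risk_map.csv", "risk_map.png"],
    }
    if cfg.sensitivity:
        sens = threshold_sensitivity(capmap, wssmap, central=thresholds)
        payload = {
            "cap_list_um": list(sens.cap_list_um),
            "wss_list_pa": list(sens.wss_list_pa),
            "n_maps": sens.n_maps,
            "variability_pct": {k: list(v) for k, v in sens.variability_pct.items()},
            "fractions": {f"{tc:g}um_{tw:g}Pa": m.fractions
                          for (tc, tw), m in sens.maps.items()},
        }
        (out / "sensitivity.json").write_text(json.dumps(payload, indent=2,
                                                         sort_keys=True))
        summary["fuse"]["sensitivity"] = {
            "n_maps": sens.n_maps,
            "variability_pct": {k: list(v) for k, v in sens.variability_pct.items()},
        }
        summary["fuse"]["outputs"].append("sensitivity.json")


def _render_risk_png(risk, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    from .risk_fusion import RISK_PALETTE
    cmap = ListedColormap([RISK_PALETTE[RiskLevel(i)] for i in (-1, 0, 1, 2, 3)])
    norm = BoundaryNorm([-1.5, -0.5, 0.5, 1.5, 2.5, 3.5], cmap.N)
    fig, ax = plt.subplots(figsize=(8, 3))
    extent = [0, risk.grid.length_mm, 0, 360]
    ax.imshow(risk.levels.T, origin="lower", aspect="auto", cmap=cmap, norm=norm,
              extent=extent)
    ax.set_xlabel("arc-length s (mm)")
    ax.set_ylabel("angle (deg)")
    ax.set_title("risk map (gray low / blue high WSS / yellow thin cap / red both)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run summary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("run config: %s", config)
    summary: dict = {"seed": config.seed, "stages_run": []}
    try:
        for name, fn in zip(STAGES, (_simulate, _segment, _reconstruct,
                                     _wss, _register, _fuse)):
            if not config.enabled(name):
                log.info("stage %s: disabled", name)
                continue
            fn(config, out, summary)
            summary["stages_run"].append(name)
            # partial outputs are retained on failure of a later stage
            (out / "summary.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True))
    finally:
        log.removeHandler(handler)
        handler.close()
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def write_report(summary: dict, outdir) -> Path:
    """Human-readable report, regenerable from the stored artifacts."""
    out = Path(outdir)
    lines = ["plaquefuse run report", "=====================", ""]
    lines.append(f"seed: {summary.get('seed')}")
    lines.append(f"stages: {', '.join(summary.get('stages_run', []))}")
    seg = summary.get("segment")
    if seg:
        lines += ["", "fibrous cap",
                  f"  mean thickness: {seg['cap_mean_um']:.1f} um",
                  f"  minimum thickness: {seg['cap_min_um']:.1f} um",
                  f"  representative thickness: {seg['cap_representative_um']:.1f} um"]
    else:
        lines += ["", "no cap analyzed (segmentation stage disabled or empty ROI)"]
    fuse = summary.get("fuse")
    if fuse:
        lines += ["", "risk map region fractions (over classified bins)"]
        for k, v in fuse["risk_fractions"].items():
            lines.append(f"  {k}: {100 * v:.1f} %")
        lines.append(f"  mean WSS at cap: {fuse['mean_wss_at_cap_pa']:.3f} Pa")
        lines.append("  mean normalized WSS at cap: "
                     f"{fuse['mean_normalized_wss_at_cap']:.3f}")
    report = out / "report.txt"
    report.write_text("\n".join(lines) + "\n")

    # triptych: WSS map, cap map, risk map for the analyzed segment
    try:
        _render_triptych(out)
    except FileNotFoundError:
        pass
    return report


def _render_triptych(out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wss = pio.read_map(out / "wss_map")
    cap = pio.read_map(out / "cap_map")
    import numpy as _np
    levels = _np.loadtxt(out / "risk_map.csv", delimiter=",")
    fig, axes = plt.subplots(3, 1, figsize=(8, 8), sharex=True)
    extent = [0, wss.grid.length_mm, 0, 360]
    im0 = axes[0].imshow(wss.values.T, origin="lower", aspect="auto", extent=extent)
    axes[0].set_title("WSS (Pa)")
    fig.colorbar(im0, ax=axes[0])
    im1 = axes[1].imshow(cap.values.T, origin="lower", aspect="auto", extent=extent)
    axes[1].set_title("cap thickness (um)")
    fig.colorbar(im1, ax=axes[1])
    im2 = axes[2].imshow(levels.T, origin="lower", aspect="auto", extent=extent,
                         vmin=-1, vmax=3)
    axes[2].set_title("risk level")
    fig.colorbar(im2, ax=axes[2])
    axes[2].set_xlabel("arc-length s (mm)")
    for ax in axes:
        ax.set_ylabel("angle (deg)")
    fig.tight_layout()
    fig.savefig(out / "report_triptych.png", dpi=120)
    plt.close(fig)
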