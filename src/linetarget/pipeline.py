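"""Staged offline pipeline: simulate -> select-target -> plan-line ->
preprocess -> fit-prf -> validate.

Each stage reads its inputs from the run directory, writes its outputs
plus a JSON provenance sidecar (inputs, parameters, seed, version), and
never mutates another stage's outputs. The between-session registration
step is represented by a transform file input applied during planning.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

import linetarget
from linetarget import io as lio
from linetarget import metrics, planning, preproc, prf, surface, synthetic

__all__ = ["RunConfig", "run_pipeline", "STAGES", "StageError"]

STAGES = ("simulate", "select-target", "plan-line", "preprocess", "fit-prf", "validate")


class StageError(RuntimeError):
    """A stage cannot run because an upstream artifact is missing."""


_THRESHOLD_KEYS = {"ecc_max": 3.0, "r2_min": 0.35, "gap_mm": 4.0,
                   "line_res_mm": 0.25, "slice_thickness_mm": 2.5}
_PREPROC_KEYS = {"dct_cutoff_hz": 0.01, "acompcor_cutoff_hz": 0.18,
                 "n_components": 5, "savgol_window": 11, "savgol_polyorder": 3}
_PATH_KEYS = ("mesh", "prf_map", "registration", "line_data", "design")
_SIM_KEYS = {"thermal_snr": 5.0, "n_iterations": 2, "bar_step_deg": 0.0625,
             "grid_extent_deg": 10.0}


@dataclass
class RunConfig:
    """Validated run configuration (YAML-loadable); unknown keys rejected."""

    paths: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    preproc: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for key in self.paths:
            if key not in _PATH_KEYS:
                raise ValueError(f"unknown path key {key!r}; allowed: {_PATH_KEYS}")
        for key in self.thresholds:
            if key not in _THRESHOLD_KEYS:
                raise ValueError(f"unknown threshold key {key!r}")
        for key in self.preproc:
            if key not in _PREPROC_KEYS:
                raise ValueError(f"unknown preproc key {key!r}")
        for key in self.simulate:
            if key not in _SIM_KEYS:
                raise ValueError(f"unknown simulate key {key!r}")
        self.thresholds = {**_THRESHOLD_KEYS, **self.thresholds}
        self.preproc = {**_PREPROC_KEYS, **self.preproc}
        self.simulate = {**_SIM_KEYS, **self.simulate}
        for k, v in self.thresholds.items():
            if k != "r2_min" and v <= 0:
                raise ValueError(f"threshold {k} must be positive, got {v}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {"paths", "thresholds", "preproc", "simulate", "seed"}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        return cls(**raw)


def _write_prov(out_dir: str, stage: str, inputs: dict, params: dict, seed: int) -> None:
    prov = {"stage": stage, "inputs": inputs, "parameters": params,
            "seed": seed, "version": linetarget.__version__}
    with open(os.path.join(out_dir, f"{stage}.prov.json"), "w") as fh:
        json.dump(prov, fh, indent=2, default=str)


def _require(out_dir: str, fname: str, producer: str):
    path = os.path.join(out_dir, fname)
    if not os.path.exists(path):
        raise StageError(f"missing artifact {fname!r}: run stage {producer!r} first")
    return path


def _stage_simulate(cfg: RunConfig, out_dir: str) -> None:
    sim = cfg.simulate
    sheet = synthetic.make_folded_sheet(nx=48, ny=24, fold_amplitude=1.5,
                                        fold_wavelength=24.0, spacing=0.5)
    mesh = sheet.mesh
    surface.compute_vertex_normals(mesh)
    surface.compute_mean_curvature(mesh)
    prf_map = synthetic.make_retinotopy(mesh, seed=cfg.seed)
    design = prf.build_bar_design(
        [0.0, 90.0], directions=(1, -1), bar_widths=(0.625, 1.25),
        grid_extent=sim["grid_extent_deg"], step=sim["bar_step_deg"],
        tr=0.105, blank_s=15.0)

    lio.write_surface(mesh, os.path.join(out_dir, "mesh.surf"))
    np.savetxt(os.path.join(out_dir, "mesh_labels_V1.txt"), mesh.labels["V1"], fmt="%d")
    lio.write_curv(mesh.curvature, os.path.join(out_dir, "curvature.curv"))
    lio.write_prf_map(prf_map, os.path.join(out_dir, "prf_map.tsv"))
    np.savez_compressed(os.path.join(out_dir, "design.npz"),
                        apertures=design.apertures,
                        blank_frames=design.blank_frames)
    with open(os.path.join(out_dir, "design.json"), "w") as fh:
        json.dump({"grid_extent": design.grid_extent, "tr": design.tr,
                   "n_configurations": design.n_configurations}, fh)

    # target selection needed up-front to know the true pRF for the simulator
    eligible = planning.eligible_vertices(prf_map, mesh, "V1",
                                          cfg.thresholds["ecc_max"],
                                          cfg.thresholds["r2_min"])
    target = planning.select_target_vertex(mesh, eligible, prf_map=prf_map)
    gt = synthetic.default_ground_truth(
        prf.PRFParams(target.prf.x0, target.prf.y0, target.prf.sigma),
        seed=cfg.seed, thermal_snr=sim["thermal_snr"], target_index=target.index)
    session = synthetic.simulate_line_session(gt, design, dt=design.tr,
                                              n_iterations=sim["n_iterations"])
    np.savez_compressed(os.path.join(out_dir, "line_data.npz"),
                        data=session.series.data,
                        echo_times=np.array(session.series.echo_times),
                        dt=session.series.dt,
                        seg=session.seg.astype("U3"),
                        line_mask=session.line_mask,
                        sensitivities=session.sensitivities)
    _write_prov(out_dir, "simulate", {}, {**sim, "n_vertices": mesh.n_vertices},
                cfg.seed)


def _load_mesh(out_dir: str):
    mesh = lio.read_surface(_require(out_dir, "mesh.surf", "simulate"))
    labels = np.loadtxt(os.path.join(out_dir, "mesh_labels_V1.txt"), dtype=int)
    mesh.labels["V1"] = np.atleast_1d(labels)
    mesh.curvature = lio.read_curv(_require(out_dir, "curvature.curv", "simulate"))
    surface.compute_vertex_normals(mesh)
    return mesh


def _load_design(out_dir: str):
    arr = np.load(_require(out_dir, "design.npz", "simulate"))
    with open(_require(out_dir, "design.json", "simulate")) as fh:
        meta = json.load(fh)
    return prf.StimulusDesign(apertures=arr["apertures"],
                              grid_extent=meta["grid_extent"], tr=meta["tr"],
                              blank_frames=arr["blank_frames"],
                              n_configurations=meta.get("n_configurations"))


def _stage_select_target(cfg: RunConfig, out_dir: str) -> None:
    mesh = _load_mesh(out_dir)
    prf_map = lio.read_prf_map(_require(out_dir, "prf_map.tsv", "simulate"))
    eligible = planning.eligible_vertices(prf_map, mesh, "V1",
                                          cfg.thresholds["ecc_max"],
                                          cfg.thresholds["r2_min"])
    target = planning.select_target_vertex(mesh, eligible, prf_map=prf_map)
    out = {"index": int(target.index),
           "coord_tkr": list(target.coord_tkr),
           "coord_scanner": list(target.coord_scanner),
           "normal": list(target.normal),
           "curvature": float(target.curvature),
           "prf": {"x0": target.prf.x0, "y0": target.prf.y0,
                   "sigma": target.prf.sigma, "r2": target.prf.r2}}
    with open(os.path.join(out_dir, "target.json"), "w") as fh:
        json.dump(out, fh, indent=2)
    _write_prov(out_dir, "select-target", {"prf_map": "prf_map.tsv"},
                cfg.thresholds, cfg.seed)


def load_target(out_dir: str) -> planning.TargetVertex:
    with open(_require(out_dir, "target.json", "select-target")) as fh:
        d = json.load(fh)
    p = d.get("prf")
    return planning.TargetVertex(
        index=d["index"], coord_tkr=np.array(d["coord_tkr"]),
        coord_scanner=np.array(d["coord_scanner"]), normal=np.array(d["normal"]),
        curvature=d["curvature"],
        prf=prf.PRFParams(p["x0"], p["y0"], p["sigma"], r2=p["r2"]) if p else None)


def _stage_plan_line(cfg: RunConfig, out_dir: str) -> None:
    target = load_target(out_dir)
    reg_path = cfg.paths.get("registration")
    if reg_path:
        reg = lio.read_affine(reg_path, convention="lps")
        target = planning.map_target_between_sessions(target, reg)
    plan = planning.plan_line(target, gap_mm=cfg.thresholds["gap_mm"],
                              slice_thickness_mm=cfg.thresholds["slice_thickness_mm"],
                              line_res_mm=cfg.thresholds["line_res_mm"])
    plan.to_json(os.path.join(out_dir, "plan.json"))
    _write_prov(out_dir, "plan-line", {"target": "target.json",
                                       "registration": reg_path or "none"},
                {"gap_mm": plan.gap_mm}, cfg.seed)


def _stage_preprocess(cfg: RunConfig, out_dir: str) -> None:
    arr = np.load(_require(out_dir, "line_data.npz", "simulate"))
    design = _load_design(out_dir)
    series = preproc.MultiCoilLineSeries(data=arr["data"], dt=float(arr["dt"]),
                                         echo_times=tuple(arr["echo_times"]))
    n_iter = series.n_frames // design.n_frames
    bounds = [i * design.n_frames for i in range(n_iter)]
    blanks = design.blank_frames
    chain = preproc.PreprocChain(
        dct_cutoff_hz=cfg.preproc["dct_cutoff_hz"],
        acompcor_cutoff_hz=cfg.preproc["acompcor_cutoff_hz"],
        n_acompcor=cfg.preproc["n_components"],
        savgol_window=cfg.preproc["savgol_window"],
        savgol_polyorder=cfg.preproc["savgol_polyorder"])
    all_blanks = np.concatenate([blanks + b for b in bounds]) if n_iter else blanks
    clean = chain.run(series, arr["sensitivities"], arr["seg"], arr["line_mask"],
                      baseline_frames=all_blanks, iteration_boundaries=bounds)
    frame = pd.DataFrame(clean.data.T)
    frame.columns = [f"pos{p:02d}_{t}" for p, t in enumerate(arr["seg"])]
    frame.to_csv(os.path.join(out_dir, "clean_line.tsv"), sep="\t", index=False)
    _write_prov(out_dir, "preprocess", {"line_data": "line_data.npz"},
                {**cfg.preproc, "chain_log": chain.log}, cfg.seed)


def _stage_fit_prf(cfg: RunConfig, out_dir: str) -> None:
    frame = pd.read_csv(_require(out_dir, "clean_line.tsv", "preprocess"), sep="\t")
    design = _load_design(out_dir)
    gm_cols = [c for c in frame.columns if c.endswith("_GM")]
    ts = frame[gm_cols].to_numpy().mean(axis=1)
    model = prf.GaussianPRFModel(ts, design)
    res = model.fit()
    fit = res.params
    with open(os.path.join(out_dir, "line_fit.json"), "w") as fh:
        json.dump({"x0": fit.x0, "y0": fit.y0, "sigma": fit.sigma,
                   "beta": fit.beta, "baseline": fit.baseline, "r2": fit.r2}, fh,
                  indent=2)
    with open(os.path.join(out_dir, "line_fit_summary.txt"), "w") as fh:
        fh.write(res.summary() + "\n")
    _write_prov(out_dir, "fit-prf", {"clean_line": "clean_line.tsv"}, {}, cfg.seed)


def _stage_validate(cfg: RunConfig, out_dir: str) -> None:
    mesh = _load_mesh(out_dir)
    prf_map = lio.read_prf_map(_require(out_dir, "prf_map.tsv", "simulate"))
    target = load_target(out_dir)
    plan = planning.LinePlan.from_json(_require(out_dir, "plan.json", "plan-line"))
    with open(_require(out_dir, "line_fit.json", "fit-prf")) as fh:
        f = json.load(fh)
    line_prf = prf.PRFParams(f["x0"], f["y0"], f["sigma"], beta=f["beta"],
                             baseline=f["baseline"], r2=f["r2"])

    slice_grid = planning.make_slice_grid(plan)
    mask = planning.build_nominal_line_mask(slice_grid, plan.gap_mm)
    tkr2scan = lio.AffineTransform.identity("surface_tkr").with_frames(
        "surface_tkr", "scanner_ras")
    line_vertices = surface.vertices_in_volume_mask(mesh, mask, tkr2scan)
    curv_mean, curv_sd, _ = metrics.curvature_in_line(mesh, line_vertices)

    jitter = synthetic.make_transform_jitter(100, sigma_trans=0.15,
                                             sigma_rot_deg=0.05, seed=cfg.seed)
    disp = metrics.point_dispersion(jitter, target.coord_scanner)
    match = metrics.best_match_distance(prf_map, line_prf, mesh, target)

    report = {
        "n_line_vertices": int(line_vertices.size),
        "target_in_line": bool(target.index in set(line_vertices.tolist())),
        "curvature_in_line": {"mean": curv_mean, "sd": curv_sd},
        "registration_dispersion": disp.as_dict(),
        "best_match": match.as_dict(),
        "line_fit": f,
    }
    with open(os.path.join(out_dir, "validation_report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    _write_prov(out_dir, "validate", {"plan": "plan.json", "fit": "line_fit.json"},
                {}, cfg.seed)


def default_line_design(step: float = 0.0625, grid_extent: float = 10.0,
                        tr: float = 0.105) -> prf.StimulusDesign:
    """The line-session bar design: 2 orientations x 2 directions x 2 widths."""
    return prf.build_bar_design([0.0, 90.0], directions=(1, -1),
                                bar_widths=(0.625, 1.25), grid_extent=grid_extent,
                                step=step, tr=tr, blank_s=15.0)


def synthetic_end_to_end(seed: int, thermal_snr: float | None = 5.0,
                         n_iterations: int = 2, design=None, grid=None,
                         refine: bool = True) -> dict:
    """In-memory end-to-end run: generate -> select -> plan -> simulate ->
    preprocess -> fit -> match.

    Returns the true and fitted pRF centers, the planning/back-projection
    outcome and the best-match report for one seed. ``grid`` may carry a
    prebuilt :class:`~linetarget.prf.CandidateGrid` to amortise the coarse
    search across seeds.
    """
    sheet = synthetic.make_folded_sheet(nx=48, ny=24, fold_amplitude=1.5,
                                        fold_wavelength=24.0, spacing=0.5)
    mesh = sheet.mesh
    surface.compute_vertex_normals(mesh)
    surface.compute_mean_curvature(mesh)
    prf_map = synthetic.make_retinotopy(mesh, seed=seed)
    if design is None:
        design = default_line_design()

    eligible = planning.eligible_vertices(prf_map, mesh, "V1", 3.0, 0.35)
    target = planning.select_target_vertex(mesh, eligible, prf_map=prf_map)
    plan = planning.plan_line(target)
    slice_grid = planning.make_slice_grid(plan)
    mask = planning.build_nominal_line_mask(slice_grid, plan.gap_mm)
    tkr2scan = lio.AffineTransform.identity("surface_tkr").with_frames(
        "surface_tkr", "scanner_ras")
    line_vertices = surface.vertices_in_volume_mask(mesh, mask, tkr2scan)

    true_prf = prf.PRFParams(target.prf.x0, target.prf.y0, target.prf.sigma)
    if thermal_snr is None:  # fully noiseless condition
        noise = synthetic.NoiseSpec(drift_pct_per_min=0.0, cardiac_pct=0.0,
                                    resp_pct=0.0, thermal_sigma=0.0)
    else:
        noise = None
    gt = synthetic.default_ground_truth(true_prf, seed=seed,
                                       thermal_snr=thermal_snr,
                                       noise_spec=noise,
                                       target_index=target.index)
    session = synthetic.simulate_line_session(gt, design, dt=design.tr,
                                              n_iterations=n_iterations)
    chain = preproc.PreprocChain()
    bounds = [i * design.n_frames for i in range(n_iterations)]
    blanks = np.concatenate([design.blank_frames + b for b in bounds])
    clean = chain.run(session.series, session.sensitivities, session.seg,
                      session.line_mask, baseline_frames=blanks,
                      iteration_boundaries=bounds)
    ts = clean.data[session.seg == "GM"].mean(axis=0)
    fit = prf.fit_prf(ts, design, grid=grid, refine=refine)
    match = metrics.best_match_distance(prf_map, fit, mesh, target)
    center_error = float(np.hypot(fit.x0 - true_prf.x0, fit.y0 - true_prf.y0))
    return {
        "target": target,
        "plan": plan,
        "line_vertices": line_vertices,
        "target_in_line": bool(target.index in set(line_vertices.tolist())),
        "true_prf": true_prf,
        "fit": fit,
        "gm_timeseries": ts,
        "clean": clean,
        "session": session,
        "design": design,
        "match": match,
        "center_error_deg": center_error,
    }


_STAGE_FN = {
    "simulate": _stage_simulate,
    "select-target": _stage_select_target,
    "plan-line": _stage_plan_line,
    "preprocess": _stage_preprocess,
    "fit-prf": _stage_fit_prf,
    "validate": _stage_validate,
}


def run_pipeline(config: RunConfig, out_dir: str, stages=None) -> dict:
    """Execute the requested stages in the fixed order; returns the paths
    of the artifacts written."""
    os.makedirs(out_dir, exist_ok=True)
    wanted = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = (set(stages) - set(STAGES)) if stages else set()
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}; valid: {STAGES}")
    for stage in wanted:
        _STAGE_FN[stage](config, out_dir)
    return {"out_dir": out_dir, "stages": wanted}
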