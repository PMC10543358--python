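"""Seeded synthetic fixtures with analytic ground truth.

Every input the targeting pipeline consumes can be generated here: a
folded cortical sheet with closed-form normals and curvature, a smooth
retinotopic pRF map, rigid registration jitter, and a simulated
multi-coil multi-echo line-scanning session carrying a known pRF signal,
linear drift, cardiac/respiratory sinusoids and thermal noise. All
generators are pure functions of their seed and parameters.

What these fixtures emulate — and what they do not — is documented in the
methods note; briefly, the sheet is a single sinusoidal fold (not a whole
hemisphere), physiology is strictly sinusoidal, and coil noise is i.i.d.
Gaussian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from linetarget.io import AffineTransform, PRFMap
from linetarget.prf import PRFParams, StimulusDesign, HRFModel, prf_prediction
from linetarget.preproc import MultiCoilLineSeries
from linetarget.surface import SurfaceMesh

__all__ = [
    "SheetFixture",
    "NoiseSpec",
    "GroundTruth",
    "SimulatedSession",
    "make_folded_sheet",
    "make_retinotopy",
    "default_ground_truth",
    "simulate_line_session",
    "make_transform_jitter",
    "degenerate_preset",
]

#: Baseline raw signal level used by the line simulator (arbitrary units).
BASELINE = 100.0


@dataclass
class SheetFixture:
    """A folded-sheet mesh plus its analytic normals and mean curvature."""

    mesh: SurfaceMesh
    analytic_normals: np.ndarray
    analytic_curvature: np.ndarray


def make_folded_sheet(nx: int = 40, ny: int = 30, fold_amplitude: float = 2.0,
                      fold_wavelength: float = 20.0, spacing: float = 0.5
                      ) -> SheetFixture:
    """Triangulated sheet z = a*sin(2*pi*x/lambda) standing in for cortex.

    The analytic unit normal is (-z'(x), 0, 1)/norm and the analytic mean
    curvature of the graph surface is H = -z''/(2*(1 + z'^2)^(3/2)), both
    attached for oracle comparison. A synthetic "V1" label covers the
    central interior band of the sheet.
    """
    if nx < 3 or ny < 3:
        raise ValueError("sheet needs nx, ny >= 3")
    x = np.arange(nx) * spacing
    y = np.arange(ny) * spacing
    X, Y = np.meshgrid(x, y, indexing="ij")
    k = 2.0 * np.pi / fold_wavelength
    Z = fold_amplitude * np.sin(k * X)
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    idx = np.arange(nx * ny).reshape(nx, ny)
    v00 = idx[:-1, :-1].ravel()
    v10 = idx[1:, :-1].ravel()
    v01 = idx[:-1, 1:].ravel()
    v11 = idx[1:, 1:].ravel()
    faces = np.vstack([np.column_stack([v00, v10, v11]),
                       np.column_stack([v00, v11, v01])])

    zp = fold_amplitude * k * np.cos(k * X).ravel()
    zpp = -fold_amplitude * k**2 * np.sin(k * X).ravel()
    normals = np.column_stack([-zp, np.zeros_like(zp), np.ones_like(zp)])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    curvature = -zpp / (2.0 * (1.0 + zp**2) ** 1.5)

    interior = (idx[1:-1, 1:-1]).ravel()
    yc = vertices[interior, 1]
    band = np.abs(yc - y.mean()) <= (y.max() - y.min()) / 4.0
    labels = {"V1": interior[band]}

    mesh = SurfaceMesh(vertices=vertices, faces=faces, labels=labels)
    return SheetFixture(mesh=mesh, analytic_normals=normals, analytic_curvature=curvature)


def make_retinotopy(mesh: SurfaceMesh, ecc_axis=(1.0, 0.0, 0.0),
                    polar_axis=(0.0, 1.0, 0.0), ecc_range=(0.5, 3.5),
                    polar_range=(-np.pi / 5, np.pi / 5),
                    sigma_fn=None, r2_fn=None, seed: int = 0) -> PRFMap:
    """Smooth synthetic retinotopy over a mesh.

    Eccentricity grows linearly along ``ecc_axis`` and polar angle along
    ``polar_axis`` (V1-like organisation); sigma grows with eccentricity
    (default 0.25 + 0.2*ecc) and r2 carries seeded noise about 0.6.
    Setting ``polar_range`` to a constant pair yields a pure linear
    visual-field gradient of (ecc_range span)/(mesh extent) deg/mm.
    """
    rng = np.random.default_rng(seed)
    v = mesh.vertices
    e_ax = np.asarray(ecc_axis, float) / np.linalg.norm(ecc_axis)
    p_ax = np.asarray(polar_axis, float) / np.linalg.norm(polar_axis)
    se = v @ e_ax
    sp = v @ p_ax

    def _norm(s):
        span = s.max() - s.min()
        return (s - s.min()) / span if span > 0 else np.zeros_like(s)

    ecc = ecc_range[0] + _norm(se) * (ecc_range[1] - ecc_range[0])
    polar = polar_range[0] + _norm(sp) * (polar_range[1] - polar_range[0])
    sigma = sigma_fn(ecc) if sigma_fn is not None else 0.25 + 0.2 * ecc
    r2 = (r2_fn(ecc) if r2_fn is not None
          else np.clip(0.6 + 0.1 * rng.standard_normal(len(v)), 0.0, 0.95))
    table = pd.DataFrame({
        "x0": ecc * np.cos(polar),
        "y0": ecc * np.sin(polar),
        "sigma": sigma,
        "r2": r2,
    })
    prf_map = PRFMap(table)
    span = se.max() - se.min()
    prf_map.deg_per_mm = (ecc_range[1] - ecc_range[0]) / span if span > 0 else np.nan
    return prf_map


# ---------------------------------------------------------------------------
# line-session simulation


@dataclass(frozen=True)
class NoiseSpec:
    """Structured-noise amplitudes for the line simulator.

    drift_pct_per_min : linear drift slope, percent of baseline per minute;
    cardiac_hz / resp_hz : physiological frequencies; cardiac_pct /
    resp_pct : sinusoid amplitudes in percent of baseline; thermal_sigma :
    Gaussian noise SD in raw units (baseline = 100).
    """

    drift_pct_per_min: float = 1.0
    cardiac_hz: float = 1.0
    resp_hz: float = 0.3
    cardiac_pct: float = 0.5
    resp_pct: float = 0.5
    thermal_sigma: float = 0.6


@dataclass
class GroundTruth:
    """Everything that determines one simulated line session.

    true_prf holds one :class:`~linetarget.prf.PRFParams` (or None) per
    line position; tissue labels the positions 'CSF'/'GM'/'WM'; depths is
    the cortical depth fraction per position (0 superficial, 1 deep, NaN
    outside gray matter). Same seed, same parameters => bit-identical
    simulations.
    """

    target_index: int
    true_prf: list
    tissue: np.ndarray
    line_mask: np.ndarray
    depths: np.ndarray
    noise_spec: NoiseSpec
    seed: int
    bold_amp_percent: float = 3.0
    true_transforms: list = field(default_factory=list)

    @property
    def n_positions(self) -> int:
        return len(self.true_prf)


def default_ground_truth(target_prf: PRFParams, seed: int = 0,
                         n_csf: int = 8, n_gm: int = 16, n_wm: int = 16,
                         thermal_snr: float | None = 5.0,
                         bold_amp_percent: float = 3.0,
                         noise_spec: NoiseSpec | None = None,
                         target_index: int = 0) -> GroundTruth:
    """Canonical ground truth: a CSF | GM | WM line profile.

    The line runs from superficial (CSF side) to deep (WM side); all gray
    matter positions share the target pRF. ``thermal_snr`` is the ratio of
    the peak BOLD amplitude (raw units, superficial) to the thermal noise
    SD; None keeps the sigma given in ``noise_spec``.
    """
    tissue = np.array(["CSF"] * n_csf + ["GM"] * n_gm + ["WM"] * n_wm)
    P = tissue.size
    depths = np.full(P, np.nan)
    depths[n_csf:n_csf + n_gm] = np.linspace(0.0, 1.0, n_gm)
    true_prf = [target_prf if t == "GM" else None for t in tissue]
    line_mask = np.ones(P, dtype=bool)
    if noise_spec is None:
        noise_spec = NoiseSpec()
    if thermal_snr is not None:
        peak_raw = BASELINE * bold_amp_percent / 100.0 * 2.0  # superficial factor 2
        sigma = peak_raw / thermal_snr if thermal_snr > 0 else 0.0
        noise_spec = NoiseSpec(
            drift_pct_per_min=noise_spec.drift_pct_per_min,
            cardiac_hz=noise_spec.cardiac_hz, resp_hz=noise_spec.resp_hz,
            cardiac_pct=noise_spec.cardiac_pct, resp_pct=noise_spec.resp_pct,
            thermal_sigma=sigma,
        )
    return GroundTruth(target_index=target_index, true_prf=true_prf, tissue=tissue,
                       line_mask=line_mask, depths=depths, noise_spec=noise_spec,
                       seed=seed, bold_amp_percent=bold_amp_percent)


@dataclass
class SimulatedSession:
    """Output bundle of :func:`simulate_line_session`."""

    series: MultiCoilLineSeries
    seg: np.ndarray
    line_mask: np.ndarray
    sensitivities: np.ndarray  # (C, P)
    clean_percent: np.ndarray  # noise-free task signal, %BOLD, (P, T)
    ground_truth: GroundTruth


def _coil_sensitivities(n_coils: int, n_positions: int) -> np.ndarray:
    """Smooth Gaussian-bump sensitivity profile per coil."""
    p = np.arange(n_positions)
    centers = (np.arange(n_coils) + 0.5) * n_positions / n_coils
    width = n_positions / (1.5 * n_coils)
    return 0.3 + np.exp(-((p[None, :] - centers[:, None]) ** 2) / (2 * width**2))


def simulate_line_session(gt: GroundTruth, design: StimulusDesign,
                          n_coils: int = 2,
                          echo_times=(0.006, 0.014, 0.022),
                          dt: float = 0.105,
                          t2star: float = 0.028,
                          n_iterations: int = 1) -> SimulatedSession:
    """Simulate a multi-coil multi-echo line-scanning run.

    Gray-matter positions carry the depth-scaled pRF response to the
    design (depth amplitude factor interpolating 2 -> 1 from superficial
    to deep, matching the roughly doubled superficial BOLD magnitude);
    every tissue shares a linear drift and cardiac/respiratory sinusoids;
    each coil sees the signal through a smooth sensitivity profile, each
    echo decays as exp(-TE/T2*), and i.i.d. Gaussian thermal noise is
    added per coil/echo sample. ``n_iterations`` repeats the design
    (identical task signal, fresh noise) back to back.
    """
    if abs(design.tr - dt) > 1e-9:
        raise ValueError("design.tr must equal the line sampling interval dt")
    ns = gt.noise_spec
    if 1.0 / (2.0 * dt) < ns.cardiac_hz:
        warnings.warn("sampling too coarse to resolve the cardiac frequency; "
                      "expect aliasing")
    rng = np.random.default_rng(gt.seed)
    P = gt.n_positions
    T1 = design.n_frames
    T = T1 * n_iterations
    t = np.arange(T) * dt
    hrf = HRFModel.double_gamma(dt)

    # task signal in percent, per position
    clean_pct = np.zeros((P, T))
    gm = gt.tissue == "GM"
    cache: dict = {}
    peak = None
    for p in np.flatnonzero(gm):
        prf = gt.true_prf[p]
        key = (prf.x0, prf.y0, prf.sigma)
        if key not in cache:
            pred = prf_prediction(
                PRFParams(prf.x0, prf.y0, prf.sigma, beta=1.0, baseline=0.0),
                design, hrf)
            cache[key] = pred
        pred = cache[key]
        if peak is None:
            peak = max(np.abs(pred).max(), 1e-12)
        depth_factor = 2.0 - gt.depths[p]  # 2 superficial -> 1 deep
        one = gt.bold_amp_percent * depth_factor * pred / peak
        clean_pct[p] = np.tile(one, n_iterations)

    drift = ns.drift_pct_per_min * (t / 60.0)
    cardiac = ns.cardiac_pct * np.sin(2 * np.pi * ns.cardiac_hz * t
                                      + rng.uniform(0, 2 * np.pi))
    resp = ns.resp_pct * np.sin(2 * np.pi * ns.resp_hz * t
                                + rng.uniform(0, 2 * np.pi))
    shared_pct = drift + cardiac + resp

    raw = BASELINE * (1.0 + (clean_pct + shared_pct[None, :]) / 100.0)  # (P, T)

    sens = _coil_sensitivities(n_coils, P)
    te = np.asarray(echo_times, dtype=float)
    echo_scale = np.exp(-te / t2star)
    data = (sens[:, None, :, None] * echo_scale[None, :, None, None]
            * raw[None, None, :, :])
    if ns.thermal_sigma > 0:
        data = data + rng.normal(0.0, ns.thermal_sigma, size=data.shape)

    series = MultiCoilLineSeries(data=data, dt=dt, echo_times=tuple(te),
                                 position_res=0.25)
    return SimulatedSession(series=series, seg=gt.tissue.copy(),
                            line_mask=gt.line_mask.copy(), sensitivities=sens,
                            clean_percent=clean_pct, ground_truth=gt)


def make_transform_jitter(n: int, sigma_trans: float = 0.2,
                          sigma_rot_deg: float = 0.1, seed: int = 0,
                          frame: str = "scanner_ras") -> list:
    """Seeded small rigid perturbations (registration/motion variability).

    Rotations are drawn as rotation vectors with per-axis SD
    ``sigma_rot_deg`` (degrees), translations with per-axis SD
    ``sigma_trans`` (mm). Zero sigmas give exact identities.
    """
    if sigma_trans < 0 or sigma_rot_deg < 0:
        raise ValueError("sigmas must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        mat = np.eye(4)
        if sigma_rot_deg > 0:
            rv = rng.normal(0.0, np.deg2rad(sigma_rot_deg), 3)
            mat[:3, :3] = Rotation.from_rotvec(rv).as_matrix()
        if sigma_trans > 0:
            mat[:3, 3] = rng.normal(0.0, sigma_trans, 3)
        out.append(AffineTransform(mat, source_frame=frame, dest_frame=frame))
    return out


def degenerate_preset(name: str, seed: int = 0):
    """Small fixtures that exercise the error paths of consuming modules.

    Available presets:

    - ``"no_noise_pool"``: a session whose line contains only gray matter
      (aCompCor must fail with the available labels).
    - ``"empty_line_mask"``: all positions masked out.
    - ``"constant_series"``: a zero-variance time course (pRF fit must
      flag its spatial parameters).
    """
    from linetarget.prf import build_bar_design

    design = build_bar_design([0.0], directions=(1,), bar_widths=(2.0,),
                              grid_extent=8.0, step=1.0, tr=0.105, blank_s=1.0,
                              n_pix=16)
    prf = PRFParams(1.0, -1.0, 0.7)
    if name == "no_noise_pool":
        gt = default_ground_truth(prf, seed=seed, n_csf=0, n_gm=8, n_wm=0,
                                  thermal_snr=None)
        return simulate_line_session(gt, design, dt=design.tr)
    if name == "empty_line_mask":
        gt = default_ground_truth(prf, seed=seed, n_csf=2, n_gm=4, n_wm=2,
                                  thermal_snr=None)
        gt.line_mask[:] = False
        return simulate_line_session(gt, design, dt=design.tr)
    if name == "constant_series":
        return np.full(design.n_frames, 7.0), design
    raise KeyError(f"unknown degenerate preset {name!r}")
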