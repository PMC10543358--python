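"""Target-vertex selection and scanner-frame line placement.

A line-scanning acquisition samples a single line; to probe a chosen
neural population the line must (1) pass through the target vertex and
(2) run along the cortical surface normal, i.e. perpendicular to the
cortex. This module selects that vertex from pRF and curvature criteria,
maps it into the scanner frame, and converts the normal vector into the
console-facing placement: a base slice orientation (coronal or sagittal),
two angulation angles, and cardinal-axis angles from the rule of cosines.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from linetarget.io import AffineTransform, VolumeGrid
from linetarget.prf import PRFParams
from linetarget.surface import SurfaceMesh

__all__ = [
    "TargetVertex",
    "LinePlan",
    "NoEligibleVerticesError",
    "eligible_vertices",
    "select_target_vertex",
    "tkr_to_scanner",
    "map_target_between_sessions",
    "normal_to_cardinal_angles",
    "choose_slice_orientation",
    "base_slice_axes",
    "direction_from_plan",
    "plan_line",
    "make_slice_grid",
    "build_nominal_line_mask",
]

# scanner RAS cardinal axes: left-right (LR), anterior-posterior (AP),
# foot-head (FH)
_CARDINAL = {"LR": np.array([1.0, 0.0, 0.0]),
             "AP": np.array([0.0, 1.0, 0.0]),
             "FH": np.array([0.0, 0.0, 1.0])}


class NoEligibleVerticesError(ValueError):
    """No vertex satisfied all selection criteria; carries per-criterion counts."""

    def __init__(self, counts: dict):
        self.counts = counts
        super().__init__(
            "no eligible vertices; vertices passing each criterion: "
            + ", ".join(f"{k}={v}" for k, v in counts.items())
        )


@dataclass
class TargetVertex:
    """The selected cortical target with geometry in both frames."""

    index: int
    coord_tkr: np.ndarray
    coord_scanner: np.ndarray
    normal: np.ndarray  # unit vector, scanner_ras
    curvature: float  # 1/mm
    prf: PRFParams | None = None

    def __post_init__(self) -> None:
        self.coord_tkr = np.asarray(self.coord_tkr, dtype=float)
        self.coord_scanner = np.asarray(self.coord_scanner, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-6:
            raise ValueError(f"target normal must be unit length, |n| = {n}")


@dataclass
class LinePlan:
    """Console-facing placement of a measurement line.

    center : mm, scanner RAS; direction : unit vector along the line;
    base_orientation : 'coronal' or 'sagittal'; angles_cardinal : degrees
    between the line and the (LR, AP, FH) axes, folded to [0, 90];
    angulation : the two rotations (degrees) taking the base slice's
    frequency-encoding axis onto the line direction; gap_mm : width of the
    unsuppressed band between outer-volume-suppression pulses;
    slice_thickness_mm and line_res_mm : acquisition geometry.
    """

    center: np.ndarray
    direction: np.ndarray
    base_orientation: str
    angles_cardinal: tuple
    angulation: tuple
    gap_mm: float = 4.0
    slice_thickness_mm: float = 2.5
    line_res_mm: float = 0.25

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-6:
            raise ValueError("line direction must be a unit vector")
        if self.base_orientation not in ("coronal", "sagittal"):
            raise ValueError(f"unknown base orientation {self.base_orientation!r}")
        if any(not (0.0 - 1e-9 <= a <= 180.0 + 1e-9) for a in self.angles_cardinal):
            raise ValueError("cardinal angles must lie in [0, 180] degrees")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["center"] = list(self.center)
        d["direction"] = list(self.direction)
        d["angles_cardinal"] = list(self.angles_cardinal)
        d["angulation"] = list(self.angulation)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LinePlan":
        with open(path) as fh:
            d = json.load(fh)
        d["angles_cardinal"] = tuple(d["angles_cardinal"])
        d["angulation"] = tuple(d["angulation"])
        return cls(**d)


# ---------------------------------------------------------------------------
# vertex selection


def eligible_vertices(prf_map, mesh: SurfaceMesh, label: str = "V1",
                      ecc_max: float = 3.0, r2_min: float = 0.35) -> np.ndarray:
    """Vertices in ``label`` with eccentricity < ecc_max, r2 >= r2_min and
    finite pRF parameters.

    Raises :class:`NoEligibleVerticesError` (with per-criterion counts)
    when the intersection is empty.
    """
    if label not in mesh.labels:
        raise KeyError(f"mesh has no label {label!r}; available: {sorted(mesh.labels)}")
    prf_map.check_paired(mesh)
    in_label = np.zeros(mesh.n_vertices, dtype=bool)
    in_label[mesh.labels[label]] = True
    x0, y0 = prf_map["x0"], prf_map["y0"]
    sigma, r2 = prf_map["sigma"], prf_map["r2"]
    finite = np.isfinite(x0) & np.isfinite(y0) & np.isfinite(sigma) & np.isfinite(r2)
    ecc = np.hypot(np.where(finite, x0, np.inf), np.where(finite, y0, np.inf))
    ok_ecc = ecc < ecc_max
    ok_r2 = np.where(finite, r2, -np.inf) >= r2_min
    eligible = in_label & finite & ok_ecc & ok_r2
    if not eligible.any():
        raise NoEligibleVerticesError(
            {
                "in_label": int(in_label.sum()),
                "finite_params": int((in_label & finite).sum()),
                "ecc_lt_max": int((in_label & finite & ok_ecc).sum()),
                "r2_ge_min": int((in_label & finite & ok_r2).sum()),
            }
        )
    return np.flatnonzero(eligible)


def select_target_vertex(mesh: SurfaceMesh, eligible: np.ndarray,
                         prf_map=None,
                         scanner_from_tkr: AffineTransform | None = None) -> TargetVertex:
    """Pick the flattest eligible vertex: argmin of |mean curvature|.

    Minimal *absolute* curvature is used (flattest cortex); ties break to
    the lowest vertex index. Requires curvature and normals on the mesh.
    When ``scanner_from_tkr`` is given the coordinate and normal are mapped
    into the scanner frame; otherwise the tkr frame is reused.
    """
    eligible = np.asarray(eligible, dtype=int)
    if eligible.size == 0:
        raise ValueError("eligible set is empty")
    if mesh.curvature is None:
        raise ValueError("mesh curvature not computed; run compute_mean_curvature first")
    curv = mesh.curvature[eligible]
    if not np.any(np.isfinite(curv)):
        raise ValueError("curvature is NaN on every eligible vertex")
    absc = np.where(np.isfinite(curv), np.abs(curv), np.inf)
    best = int(eligible[np.argmin(absc)])  # np.argmin returns first minimum -> lowest index

    if mesh.normals is None:
        from linetarget.surface import compute_vertex_normals

        compute_vertex_normals(mesh)
    coord_tkr = mesh.vertices[best]
    normal = mesh.normals[best] / np.linalg.norm(mesh.normals[best])
    if scanner_from_tkr is not None:
        coord_scanner = scanner_from_tkr.apply(coord_tkr)
        normal = scanner_from_tkr.rotation() @ normal
        normal = normal / np.linalg.norm(normal)
    else:
        coord_scanner = coord_tkr.copy()
    prf = None
    if prf_map is not None:
        row = prf_map.table.iloc[best]
        prf = PRFParams(float(row.x0), float(row.y0), float(row.sigma), r2=float(row.r2))
    return TargetVertex(index=best, coord_tkr=coord_tkr, coord_scanner=coord_scanner,
                        normal=normal, curvature=float(mesh.curvature[best]), prf=prf)


def tkr_to_scanner(coord, vox2ras: AffineTransform, vox2ras_tkr: AffineTransform) -> np.ndarray:
    """Map a surface-tkr coordinate to scanner RAS.

    Uses the volume's two voxel-to-world matrices:
    ``scanner = vox2ras @ inv(vox2ras_tkr) @ coord``.
    """
    if vox2ras_tkr.dest_frame != "surface_tkr":
        raise ValueError(
            f"vox2ras_tkr must map voxel -> surface_tkr, maps to {vox2ras_tkr.dest_frame!r}"
        )
    if vox2ras.dest_frame != "scanner_ras":
        raise ValueError(
            f"vox2ras must map voxel -> scanner_ras, maps to {vox2ras.dest_frame!r}"
        )
    if vox2ras.source_frame != vox2ras_tkr.source_frame:
        raise ValueError("the two voxel-to-world matrices must share their voxel frame")
    return vox2ras.compose(vox2ras_tkr.inverse()).apply(np.asarray(coord, dtype=float))


def scanner_from_tkr_transform(vox2ras: AffineTransform,
                               vox2ras_tkr: AffineTransform) -> AffineTransform:
    """The full surface_tkr -> scanner_ras transform as an AffineTransform."""
    return vox2ras.compose(vox2ras_tkr.inverse())


def map_target_between_sessions(target: TargetVertex, reg: AffineTransform,
                                invert: bool = False) -> TargetVertex:
    """Map a target into another session's frame through a registration.

    The coordinate goes through the full affine (or its inverse when
    ``invert`` — the forward/inverse direction of a registration file is
    always declared by the caller, never guessed). The normal goes through
    the rotation block only (no translation) and is renormalised; for a
    non-rigid transform a warning is raised and the unit-determinant polar
    factor is used.
    """
    t = reg.inverse() if invert else reg
    if not t.is_rigid():
        warnings.warn("registration is not rigid; normal mapped through its polar factor")
    coord = t.apply(target.coord_scanner)
    normal = t.rotation() @ target.normal
    normal = normal / np.linalg.norm(normal)
    return TargetVertex(index=target.index, coord_tkr=target.coord_tkr,
                        coord_scanner=coord, normal=normal,
                        curvature=target.curvature, prf=target.prf)


# ---------------------------------------------------------------------------
# angulation


def normal_to_cardinal_angles(normal) -> tuple:
    """Angles (degrees) between a line direction and the LR, AP, FH axes.

    Rule of cosines: theta_i = arccos(|n . e_i| / ||n||). Angles are folded
    to [0, 90] because a line has no polarity.
    """
    n = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("zero vector has no direction")
    return tuple(
        float(np.degrees(np.arccos(np.clip(abs(n @ _CARDINAL[ax]) / norm, 0.0, 1.0))))
        for ax in ("LR", "AP", "FH")
    )


def choose_slice_orientation(angles_cardinal) -> str:
    """Coronal by default; sagittal iff the angle to the LR axis exceeds 45 deg.

    Exactly 45 deg keeps the coronal base (fixed tie-break).
    """
    return "sagittal" if angles_cardinal[0] > 45.0 else "coronal"


def base_slice_axes(base_orientation: str):
    """Orthonormal (frequency, phase, slice-normal) triad of a base slice.

    Coronal: in-plane LR (frequency) and FH (phase), through-plane AP.
    Sagittal: in-plane AP (frequency) and FH (phase), through-plane LR.
    """
    if base_orientation == "coronal":
        return _CARDINAL["LR"], _CARDINAL["FH"], _CARDINAL["AP"]
    if base_orientation == "sagittal":
        return _CARDINAL["AP"], _CARDINAL["FH"], _CARDINAL["LR"]
    raise ValueError(f"unknown base orientation {base_orientation!r}")


def _angulation_from_direction(direction: np.ndarray, base_orientation: str) -> tuple:
    """Two rotation angles (deg) taking the base frequency axis onto ``direction``.

    With the direction expressed in the (f, p, s) triad as (df, dp, ds)
    and folded so df >= 0, the decomposition is: rotate about the in-plane
    phase axis by a = arccos(df), then about the frequency axis by
    b = atan2(dp, ds). Any consistent parameterization satisfies the
    placement; this one is validated by the direction round trip.
    """
    f, p, s = base_slice_axes(base_orientation)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if d @ f < 0:  # lines are unoriented; fold into the +f hemisphere
        d = -d
    df, dp, ds = d @ f, d @ p, d @ s
    a = np.degrees(np.arccos(np.clip(df, -1.0, 1.0)))
    b = np.degrees(np.arctan2(dp, ds)) if a > 1e-12 else 0.0
    return (float(a), float(b))


def direction_from_plan(base_orientation: str, angulation) -> np.ndarray:
    """Reconstruct the unit line direction from (orientation, angulation)."""
    f, p, s = base_slice_axes(base_orientation)
    a, b = np.deg2rad(angulation)
    return np.cos(a) * f + np.sin(a) * (np.sin(b) * p + np.cos(b) * s)


def plan_line(target: TargetVertex, gap_mm: float = 4.0,
              slice_thickness_mm: float = 2.5, line_res_mm: float = 0.25) -> LinePlan:
    """Convert a scanner-frame target into a console-facing line placement.

    The line is centered on the target coordinate and directed along its
    surface normal; the base slice orientation follows the >45 deg LR-angle
    rule and the angulation is the two-rotation decomposition reaching the
    normal from the base slice's frequency axis.
    """
    n = np.asarray(target.normal, dtype=float)
    norm = np.linalg.norm(n)
    if not np.isfinite(norm) or norm < 1e-12:
        raise ValueError("target normal is degenerate; cannot plan a line")
    direction = n / norm
    angles = normal_to_cardinal_angles(direction)
    base = choose_slice_orientation(angles)
    angulation = _angulation_from_direction(direction, base)
    direction = direction_from_plan(base, angulation)  # folded, unit-normalized
    return LinePlan(center=np.asarray(target.coord_scanner, float), direction=direction,
                    base_orientation=base, angles_cardinal=angles, angulation=angulation,
                    gap_mm=gap_mm, slice_thickness_mm=slice_thickness_mm,
                    line_res_mm=line_res_mm)


# ---------------------------------------------------------------------------
# nominal line mask


def make_slice_grid(plan: LinePlan, fov_mm: float = 16.0,
                    in_plane_res_mm: float | None = None) -> VolumeGrid:
    """Empty slice grid aligned to a plan: axes (frequency, phase, slice).

    The frequency axis runs along the line direction; the grid is centered
    on the plan center. In-plane resolution defaults to the line
    resolution; the single slice voxel spans ``slice_thickness_mm``.
    """
    res = plan.line_res_mm if in_plane_res_mm is None else in_plane_res_mm
    n = int(round(fov_mm / res))
    fdir = plan.direction
    f0, p0, s0 = base_slice_axes(plan.base_orientation)
    # in-plane phase axis: orthogonal to the line, inside the angulated slice
    sdir = np.cross(fdir, p0)
    if np.linalg.norm(sdir) < 1e-9:  # line along the base phase axis
        sdir = np.cross(fdir, f0)
    sdir = sdir / np.linalg.norm(sdir)
    pdir = np.cross(sdir, fdir)
    mat = np.eye(4)
    mat[:3, 0] = fdir * res
    mat[:3, 1] = pdir * res
    mat[:3, 2] = sdir * plan.slice_thickness_mm
    # voxel (i, j, k) centers; grid centered on the plan center
    center_vox = np.array([(n - 1) / 2.0, (n - 1) / 2.0, 0.0])
    mat[:3, 3] = plan.center - mat[:3, :3] @ center_vox
    vox2world = AffineTransform(mat, source_frame="voxel", dest_frame="scanner_ras")
    return VolumeGrid(shape=(n, n, 1), vox2world=vox2world,
                      data=np.zeros((n, n, 1), dtype=np.int16))


def build_nominal_line_mask(slice_grid: VolumeGrid, gap_mm: float = 4.0,
                            line_res_mm: float | None = None) -> VolumeGrid:
    """Binary mask of the nominal line inside a slice grid.

    The unsuppressed band between the two outer-volume-suppression pulses
    is ``gap_mm`` wide along the phase-encoding axis (grid axis 1); the
    mask keeps the central ``round(gap_mm / phase_res)`` voxels along that
    axis at full frequency-axis extent. With an odd leftover the extra
    masked voxel sits on the lower-index side.
    """
    n_freq, n_phase, n_slice = slice_grid.shape
    phase_res = slice_grid.voxel_sizes[1]
    if gap_mm > n_phase * phase_res + 1e-9:
        raise ValueError(
            f"gap {gap_mm} mm exceeds the phase-axis field of view "
            f"({n_phase * phase_res:.3f} mm)"
        )
    width = int(round(gap_mm / phase_res))
    width = max(min(width, n_phase), 1)
    start = (n_phase - width) // 2
    data = np.zeros(slice_grid.shape, dtype=np.int16)
    data[:, start:start + width, :] = 1
    return VolumeGrid(shape=slice_grid.shape, vox2world=slice_grid.vox2world, data=data)
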