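"""Targeting-accuracy metrics.

Anatomical validation: dispersion of the target coordinate under repeated
registrations and run-to-run motion, curvature statistics inside the line,
and tissue fractions of the nominal line mask. Functional validation:
cross-session pRF comparison via the best-matching-vertex distance in
visual and cortical space, and paired statistics (t, Cohen's D) for
model-comparison scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from linetarget.surface import SurfaceMesh, geodesic_distance

__all__ = [
    "DispersionReport",
    "MatchReport",
    "point_dispersion",
    "motion_displacement",
    "curvature_in_line",
    "tissue_fractions",
    "best_match_distance",
    "paired_comparison",
]


@dataclass
class DispersionReport:
    """Euclidean displacement (mm) of a point under a set of transforms."""

    distances: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.distances.mean())

    @property
    def sd(self) -> float:
        return float(self.distances.std(ddof=1)) if self.distances.size > 1 else 0.0

    @property
    def max(self) -> float:
        return float(self.distances.max())

    def as_dict(self) -> dict:
        return {"mean_mm": self.mean, "sd_mm": self.sd, "max_mm": self.max,
                "n": int(self.distances.size)}


@dataclass
class MatchReport:
    """Best-matching-vertex comparison between line and whole-brain pRFs."""

    target_index: int
    match_index: int
    visual_distance: float  # degrees
    euclid_mm: float
    geodesic_mm: float
    per_vertex_visual_distance: np.ndarray = None

    def as_dict(self) -> dict:
        return {
            "target_index": int(self.target_index),
            "match_index": int(self.match_index),
            "visual_distance_deg": float(self.visual_distance),
            "euclid_mm": float(self.euclid_mm),
            "geodesic_mm": float(self.geodesic_mm),
        }


def point_dispersion(transforms, point, reference=None, labels=None) -> DispersionReport:
    """Distances between a point mapped through each transform and a reference.

    Emulates repeating a between-session registration many times, applying
    every resulting matrix to the target coordinate and taking the
    Euclidean distance to the originally targeted coordinate. ``reference``
    defaults to the unmapped point.
    """
    transforms = list(transforms)
    if not transforms:
        raise ValueError("need at least one transform")
    point = np.asarray(point, dtype=float)
    reference = point if reference is None else np.asarray(reference, dtype=float)
    mapped = np.array([t.apply(point) for t in transforms])
    d = np.linalg.norm(mapped - reference, axis=1)
    return DispersionReport(distances=d, labels=list(labels) if labels else [])


def motion_displacement(run_transforms, target, labels=None) -> DispersionReport:
    """Per-run displacement of the target coordinate (run-to-run motion).

    Same computation as :func:`point_dispersion`, with per-run labels.
    """
    transforms = list(run_transforms)
    if labels is None:
        labels = [f"run-{i + 1}" for i in range(len(transforms))]
    return point_dispersion(transforms, target, labels=labels)


def curvature_in_line(mesh: SurfaceMesh, line_vertices) -> tuple[float, float, np.ndarray]:
    """(mean, sd, values) of |mean curvature| over the line's surface vertices.

    Absolute curvature is summarised, consistent with reading low values
    as flat cortex.
    """
    idx = np.asarray(line_vertices, dtype=int)
    if idx.size == 0:
        raise ValueError("line vertex set is empty")
    if mesh.curvature is None:
        raise ValueError("mesh curvature not computed")
    vals = np.abs(mesh.curvature[idx])
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("curvature is NaN on every line vertex")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd, vals


def tissue_fractions(seg, line_mask, gm_label=1, wm_label=2, csf_label=3) -> dict:
    """Percentages of GM/WM/CSF voxels inside a line mask (sum to 100).

    ``seg`` and ``line_mask`` are aligned label/binary grids
    (:class:`~linetarget.io.VolumeGrid` or arrays). Background voxels are
    excluded from the normalisation.
    """
    from linetarget.io import VolumeGrid

    seg_data = seg.data if isinstance(seg, VolumeGrid) else np.asarray(seg)
    mask_data = (line_mask.data if isinstance(line_mask, VolumeGrid)
                 else np.asarray(line_mask))
    if seg_data.shape != mask_data.shape:
        raise ValueError(f"segmentation {seg_data.shape} and mask {mask_data.shape} differ")
    inside = seg_data[mask_data.astype(bool)]
    counts = {
        "GM": int(np.sum(inside == gm_label)),
        "WM": int(np.sum(inside == wm_label)),
        "CSF": int(np.sum(inside == csf_label)),
    }
    total = sum(counts.values())
    if total == 0:
        raise ValueError("line mask contains no labelled tissue voxels")
    return {k: 100.0 * v / total for k, v in counts.items()}


def best_match_distance(prf_map, line_prf, mesh: SurfaceMesh, target,
                        label: str = "V1") -> MatchReport:
    """Find the cortical vertex whose pRF best matches the line-scanning pRF.

    For every vertex in the label the visual-field distance between its
    pRF center and the line pRF center is computed; the argmin is the
    *match*. The report carries the match-to-target Euclidean (mm, frame
    invariant under rigid motion) and graph-geodesic (mm) distances. Ties
    break to the smaller geodesic distance to the target, then the lower
    index.
    """
    prf_map.check_paired(mesh)
    if label not in mesh.labels:
        raise KeyError(f"mesh has no label {label!r}")
    candidates = np.asarray(mesh.labels[label], dtype=int)
    x0, y0 = prf_map["x0"][candidates], prf_map["y0"][candidates]
    finite = np.isfinite(x0) & np.isfinite(y0)
    if not finite.any():
        raise ValueError("no vertices with finite pRF centers in the label")
    candidates = candidates[finite]
    dvis = np.hypot(x0[finite] - line_prf.x0, y0[finite] - line_prf.y0)

    per_vertex = np.full(mesh.n_vertices, np.nan)
    per_vertex[candidates] = dvis
    tol = 1e-12 * max(float(dvis.max()), 1.0)
    tied = candidates[dvis <= dvis.min() + tol]
    if tied.size > 1:
        geo = geodesic_distance(mesh, int(target.index), tied)
        order = np.lexsort((tied, geo))
        match = int(tied[order[0]])
    else:
        match = int(tied[0])

    euclid = float(np.linalg.norm(mesh.vertices[match] - mesh.vertices[target.index]))
    geodesic = float(geodesic_distance(mesh, int(target.index), [match])[0])
    return MatchReport(
        target_index=int(target.index),
        match_index=match,
        visual_distance=float(per_vertex[match]),
        euclid_mm=euclid,
        geodesic_mm=geodesic,
        per_vertex_visual_distance=per_vertex,
    )


def paired_comparison(a, b) -> tuple[float, float, float]:
    """Paired t test and Cohen's D on difference scores.

    t = mean(d) / (sd(d)/sqrt(n)) with d = a - b and df = n - 1;
    D = mean(d) / sd(d); two-sided p from the Student t distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired comparison needs at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):  # identical samples: no effect at all
            return 0.0, 1.0, 0.0
        raise ValueError("zero-variance differences: t statistic undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    cohen_d = d.mean() / sd
    return float(t), float(p), float(cohen_d)
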