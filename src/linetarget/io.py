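"""Readers and writers for every artifact the targeting pipeline touches.

All geometry carries an explicit coordinate frame. The internal world frame
is scanner RAS; ITK/ANTs-style files are declared LPS by the caller and
converted on read (sign flip of the first two axes). Surface vertex
coordinates live in FreeSurfer's internal surface RAS ("tkr") frame until
explicitly mapped to the scanner.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FRAMES",
    "AffineTransform",
    "VolumeGrid",
    "PRFMap",
    "FormatError",
    "FrameError",
    "read_surface",
    "write_surface",
    "read_curv",
    "write_curv",
    "read_affine",
    "write_affine",
    "read_volume",
    "write_volume",
    "read_prf_map",
    "write_prf_map",
]

#: Recognised coordinate frames for points and transforms.
FRAMES = ("surface_tkr", "scanner_ras", "scanner_lps", "voxel")

# Point-mapping conversion between RAS and LPS: flip left-right and
# posterior-anterior axes.
_LPS_TO_RAS = np.diag([-1.0, -1.0, 1.0, 1.0])


class FormatError(ValueError):
    """An on-disk artifact could not be parsed as its expected format."""


class FrameError(ValueError):
    """Coordinate frames of two composed/applied objects do not match."""


def _check_frame(frame: str) -> str:
    if frame not in FRAMES:
        raise FrameError(f"unknown coordinate frame {frame!r}; expected one of {FRAMES}")
    return frame


@dataclass(frozen=True)
class AffineTransform:
    """A 4x4 homogeneous transform (mm) between two tagged coordinate frames.

    Parameters
    ----------
    matrix
        4x4 homogeneous matrix; bottom row must be (0, 0, 0, 1).
    source_frame, dest_frame
        One of :data:`FRAMES`. ``apply`` maps points from ``source_frame``
        into ``dest_frame``.
    """

    matrix: np.ndarray
    source_frame: str = "scanner_ras"
    dest_frame: str = "scanner_ras"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise ValueError(f"bottom row of an affine must be (0,0,0,1), got {m[3]}")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("affine is non-invertible (singular 3x3 block)")
        object.__setattr__(self, "matrix", m)
        _check_frame(self.source_frame)
        _check_frame(self.dest_frame)

    # -- algebra ---------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (..., 3) points from the source frame into the dest frame."""
        pts = np.asarray(points, dtype=float)
        squeeze = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if squeeze else out

    def inverse(self) -> "AffineTransform":
        return AffineTransform(
            np.linalg.inv(self.matrix), source_frame=self.dest_frame, dest_frame=self.source_frame
        )

    def compose(self, first: "AffineTransform") -> "AffineTransform":
        """Return self ∘ first, i.e. the transform applying ``first`` then self."""
        if first.dest_frame != self.source_frame:
            raise FrameError(
                f"cannot compose: inner transform ends in {first.dest_frame!r} "
                f"but outer starts in {self.source_frame!r}"
            )
        return AffineTransform(
            self.matrix @ first.matrix,
            source_frame=first.source_frame,
            dest_frame=self.dest_frame,
        )

    # -- predicates ------------------------------------------------------
    def is_rigid(self, atol: float = 1e-6) -> bool:
        """True when the 3x3 block is orthonormal with determinant +1."""
        r = self.matrix[:3, :3]
        return bool(
            np.allclose(r @ r.T, np.eye(3), atol=atol) and abs(np.linalg.det(r) - 1.0) < atol
        )

    def rotation(self) -> np.ndarray:
        """Unit-determinant polar factor of the 3x3 block (exact for rigid)."""
        u, _, vt = np.linalg.svd(self.matrix[:3, :3])
        r = u @ vt
        if np.linalg.det(r) < 0:
            u[:, -1] *= -1
            r = u @ vt
        return r

    def with_frames(self, source_frame: str, dest_frame: str) -> "AffineTransform":
        return replace(self, source_frame=source_frame, dest_frame=dest_frame)

    @classmethod
    def identity(cls, frame: str = "scanner_ras") -> "AffineTransform":
        return cls(np.eye(4), source_frame=frame, dest_frame=frame)


@dataclass
class VolumeGrid:
    """A voxel grid with a voxel-to-world affine.

    ``data`` is a scalar, label or binary array; ``vox2world`` maps voxel
    indices (i, j, k) to world mm coordinates.
    """

    shape: tuple
    vox2world: AffineTransform
    data: np.ndarray

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if any(s <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be strictly positive, got {self.shape}")
        self.data = np.asarray(self.data)
        if self.data.shape[: len(self.shape)] != self.shape:
            raise ValueError(f"data shape {self.data.shape} inconsistent with {self.shape}")

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge length (mm) along each of the three grid axes."""
        return np.linalg.norm(self.vox2world.matrix[:3, :3], axis=0)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        return self.vox2world.inverse().apply(points)


class PRFMap:
    """Per-vertex Gaussian pRF parameters (x0, y0, sigma, r2), NaN where unfitted."""

    REQUIRED = ("x0", "y0", "sigma", "r2")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise FormatError(f"pRF table missing required column(s): {missing}")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def __getitem__(self, col: str) -> np.ndarray:
        return self.table[col].to_numpy()

    def check_paired(self, mesh) -> None:
        """Raise when the table row count does not match the mesh vertex count."""
        n = mesh.n_vertices
        if len(self) != n:
            raise ValueError(
                f"pRF map has {len(self)} rows but mesh has {n} vertices; cannot pair"
            )

    def eccentricity(self) -> np.ndarray:
        return np.hypot(self["x0"], self["y0"])

    def polar_angle(self) -> np.ndarray:
        return np.arctan2(self["y0"], self["x0"])


# ---------------------------------------------------------------------------
# surfaces


def read_surface(path):
    """Read a FreeSurfer binary or GIFTI surface into a :class:`SurfaceMesh`.

    Coordinates are taken to be in the surface-RAS ("tkr") frame, in mm.
    """
    from linetarget.surface import SurfaceMesh

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"surface file does not exist: {path}")
    try:
        if path.endswith(".gii"):
            img = nib.load(path)
            coords = img.agg_data("NIFTI_INTENT_POINTSET")
            faces = img.agg_data("NIFTI_INTENT_TRIANGLE")
        else:
            coords, faces = nib.freesurfer.read_geometry(path)
    except Exception as exc:  # nibabel raises various errors on truncation
        raise FormatError(f"could not read surface file {path}: {exc}") from exc
    return SurfaceMesh(np.asarray(coords, float), np.asarray(faces, int))


def write_surface(mesh, path) -> None:
    """Write a mesh as FreeSurfer binary (default) or GIFTI (``.gii``)."""
    path = os.fspath(path)
    if path.endswith(".gii"):
        pts = nib.gifti.GiftiDataArray(
            mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
        )
        tri = nib.gifti.GiftiDataArray(
            mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
        )
        nib.save(nib.gifti.GiftiImage(darrays=[pts, tri]), path)
    else:
        nib.freesurfer.write_geometry(path, mesh.vertices, mesh.faces)


def read_curv(path) -> np.ndarray:
    """Read a FreeSurfer 'curv' overlay or a GIFTI functional overlay."""
    path = os.fspath(path)
    try:
        if path.endswith(".gii"):
            return np.asarray(nib.load(path).agg_data(), float)
        return np.asarray(nib.freesurfer.read_morph_data(path), float)
    except Exception as exc:
        raise FormatError(f"could not read overlay {path}: {exc}") from exc


def write_curv(values: np.ndarray, path, fnum: int = 0) -> None:
    path = os.fspath(path)
    values = np.asarray(values, dtype=np.float32)
    if path.endswith(".gii"):
        da = nib.gifti.GiftiDataArray(values, intent="NIFTI_INTENT_NONE")
        nib.save(nib.gifti.GiftiImage(darrays=[da]), path)
    else:
        nib.freesurfer.write_morph_data(path, values, fnum=fnum)


# ---------------------------------------------------------------------------
# affines


def _parse_itk_transform(lines):
    """Parse an ITK transform parameter file (AffineTransform / Euler3D / MatrixOffset)."""
    params = fixed = None
    for line in lines:
        if line.startswith("Parameters:"):
            params = np.array([float(x) for x in line.split(":", 1)[1].split()])
        elif line.startswith("FixedParameters:"):
            fixed = np.array([float(x) for x in line.split(":", 1)[1].split()])
    if params is None or params.size != 12:
        raise FormatError("ITK transform file must carry 12 'Parameters' values")
    mat = np.eye(4)
    mat[:3, :3] = params[:9].reshape(3, 3)
    trans = params[9:12]
    if fixed is not None and fixed.size >= 3:
        # ITK stores the offset about a fixed center c: x' = R(x - c) + c + t
        c = fixed[:3]
        trans = trans + c - mat[:3, :3] @ c
    mat[:3, 3] = trans
    return mat


def read_affine(path, convention: str = "ras", source_frame: str = "scanner_ras",
                dest_frame: str = "scanner_ras") -> AffineTransform:
    """Read a 4x4 transform from plain text or an ITK-style parameter file.

    Parameters
    ----------
    convention
        ``"ras"`` for files already in scanner RAS, ``"lps"`` for ITK/ANTs
        files whose point mapping is expressed in LPS. LPS matrices are
        converted so that :meth:`AffineTransform.apply` acts on RAS points.
    source_frame, dest_frame
        Frames the (converted) transform maps between. The forward/inverse
        direction of a registration file is *declared* by the caller via
        these tags and, if needed, :meth:`AffineTransform.inverse` — never
        guessed from the file.
    """
    path = os.fspath(path)
    with open(path) as fh:
        text = fh.read()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"empty transform file: {path}")
    if any(ln.startswith("#Insight Transform File") or ln.startswith("Transform:") for ln in lines):
        mat = _parse_itk_transform(lines)
    else:
        try:
            mat = np.array([[float(x) for x in ln.split()] for ln in lines], dtype=float)
        except ValueError as exc:
            raise FormatError(f"could not parse {path} as a numeric matrix: {exc}") from exc
        if mat.shape == (3, 4):
            mat = np.vstack([mat, [0.0, 0.0, 0.0, 1.0]])
        if mat.shape != (4, 4):
            raise FormatError(f"transform in {path} has shape {mat.shape}, expected 4x4")
    convention = convention.lower()
    if convention == "lps":
        mat = _LPS_TO_RAS @ mat @ _LPS_TO_RAS
    elif convention != "ras":
        raise ValueError(f"convention must be 'ras' or 'lps', got {convention!r}")
    return AffineTransform(mat, source_frame=source_frame, dest_frame=dest_frame)


def write_affine(transform: AffineTransform, path) -> None:
    """Write the 4x4 matrix as plain text with 17 significant digits."""
    np.savetxt(os.fspath(path), transform.matrix, fmt="%.17g")


# ---------------------------------------------------------------------------
# volumes


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI-1 volume. The sform affine wins when both sform and qform exist."""
    path = os.fspath(path)
    try:
        img = nib.load(path)
    except Exception as exc:
        raise FormatError(f"could not read NIfTI volume {path}: {exc}") from exc
    affine = img.get_sform() if img.header.get("sform_code", 0) else img.affine
    if affine is None:
        raise FormatError(f"volume {path} has no usable affine")
    data = np.asanyarray(img.dataobj)
    vox2world = AffineTransform(affine, source_frame="voxel", dest_frame="scanner_ras")
    return VolumeGrid(shape=data.shape[:3], vox2world=vox2world, data=data)


def write_volume(grid: VolumeGrid, path) -> None:
    data = grid.data
    if np.issubdtype(data.dtype, np.integer) or data.dtype == bool:
        data = data.astype(np.int16)
    img = nib.Nifti1Image(data, grid.vox2world.matrix)
    img.set_sform(grid.vox2world.matrix, code=1)
    img.set_qform(grid.vox2world.matrix, code=1)
    nib.save(img, os.fspath(path))


# ---------------------------------------------------------------------------
# pRF tables


def read_prf_map(path) -> PRFMap:
    """Read a per-vertex pRF parameter table (TSV with x0, y0, sigma, r2)."""
    table = pd.read_csv(os.fspath(path), sep="\t")
    return PRFMap(table)


def write_prf_map(prf_map: PRFMap, path) -> None:
    prf_map.table.to_csv(os.fspath(path), sep="\t", index=False, na_rep="NaN",
                         float_format="%.17g")
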