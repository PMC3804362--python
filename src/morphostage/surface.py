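"""Triangulated organ surfaces: extraction, standardization, metrics, I/O.

Surfaces live in physical millimetre coordinates.  A valid organ surface is
a closed, orientable, genus-0 triangle mesh (Euler characteristic 2); after
standardization it carries a fixed vertex count (1000 by default) so that
corresponded surfaces can be stacked into shape vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .decimate import decimate_qem
from .volume import EmptySegmentationError, LabelVolume

log = logging.getLogger(__name__)

DEFAULT_VERTEX_COUNT = 1000


@dataclass
class Surface:
    """A triangulated closed mesh for one organ of one subject.

    vertices : (V, 3) float array, physical mm
    faces : (F, 3) int array of vertex indices
    organ : "liver" or "spleen" (free-form tags are tolerated)
    """

    vertices: np.ndarray
    faces: np.ndarray
    organ: str = "liver"
    subject_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face index out of range")

    # -- conversions ----------------------------------------------------
    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh, organ: str = "liver", subject_id: str = "") -> "Surface":
        return cls(np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=np.int64),
                   organ=organ, subject_id=subject_id)

    # -- basic metrics --------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def euler_characteristic(self) -> int:
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        n_edges = len(np.unique(edges, axis=0))
        return self.n_vertices - n_edges + len(self.faces)

    def is_closed(self) -> bool:
        return self.to_trimesh().is_watertight

    def area(self) -> float:
        return float(self.to_trimesh().area)

    def volume(self) -> float:
        """Enclosed volume in mm^3 (positive for outward orientation)."""
        v = self.vertices[self.faces]
        return float(np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6.0)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def bbox_diagonal(self) -> float:
        return float(np.linalg.norm(self.vertices.max(axis=0) - self.vertices.min(axis=0)))


def extract_surface(volume: LabelVolume, iso_level: float = 0.5,
                    smoothing_sigma: float = 1.0) -> Surface:
    """Extract a closed triangulated surface from a binary label volume.

    Runs marching cubes at ``iso_level`` on the zero-padded occupancy grid
    (padding guarantees closure at the grid boundary) and maps vertices to
    physical coordinates ``index * spacing + origin``.  The binary grid is
    first smoothed with a Gaussian of ``smoothing_sigma`` voxels: the raw
    staircase isosurface of a binary grid overestimates surface area by
    ~10%, and a one-voxel smooth recovers the underlying smooth boundary
    without measurably biasing organ-scale shapes (set 0 to disable).  If
    the foreground is disconnected, only the largest connected surface
    component is kept and a warning is logged.  Normals are oriented
    outward (positive enclosed volume).
    """
    if volume.is_empty:
        raise EmptySegmentationError("empty segmentation: label volume has no foreground voxels")
    if not 0.0 < iso_level < 1.0:
        raise ValueError("iso_level must be in (0, 1)")
    from skimage import measure

    pad = 1 + int(np.ceil(3 * smoothing_sigma))
    padded = np.pad(volume.grid, pad).astype(np.float32)
    if smoothing_sigma > 0:
        from scipy.ndimage import gaussian_filter

        padded = gaussian_filter(padded, smoothing_sigma)
    verts, faces, _, _ = measure.marching_cubes(padded, level=iso_level, spacing=volume.spacing)
    verts = verts - (pad - 1) * np.asarray(volume.spacing)
    # undo the one-voxel pad, then shift to the physical origin
    verts = verts - np.asarray(volume.spacing) + np.asarray(volume.origin)
    mesh = trimesh.Trimesh(verts, faces, process=False)
    parts = mesh.split(only_watertight=False)
    if len(parts) > 1:
        log.warning("disconnected foreground: keeping largest of %d surface components", len(parts))
        mesh = max(parts, key=lambda p: p.area)
        mesh = trimesh.Trimesh(np.asarray(mesh.vertices), np.asarray(mesh.faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return Surface.from_trimesh(mesh, organ=volume.organ or "liver")


def standardize_vertex_count(surface: Surface, target_count: int = DEFAULT_VERTEX_COUNT,
                             hausdorff_tolerance: float = 0.02) -> Surface:
    """Decimate a closed surface to exactly ``target_count`` vertices.

    Quadric-error-metric edge collapse; deterministic for a fixed input.
    The result must stay within ``hausdorff_tolerance`` (fraction of the
    input bounding-box diagonal) of the input surface, otherwise a
    ``RuntimeError`` is raised.  Upsampling is not supported.
    """
    if target_count < 4:
        raise ValueError("target_count must be at least 4")
    if target_count > surface.n_vertices:
        raise ValueError(
            f"target_count {target_count} exceeds input vertex count "
            f"{surface.n_vertices}; upsampling is not supported")
    if target_count == surface.n_vertices:
        return surface
    verts, faces = decimate_qem(surface.vertices, surface.faces, target_count)
    out = Surface(verts, faces, organ=surface.organ, subject_id=surface.subject_id)
    tol = hausdorff_tolerance * surface.bbox_diagonal()
    d = hausdorff_distance(surface, out)
    if d > tol:
        raise RuntimeError(
            f"decimation exceeded Hausdorff tolerance: {d:.3g} > {tol:.3g} mm")
    return out


def _points_to_mesh_distance(points: np.ndarray, mesh: Surface,
                             chunk: int = 256) -> np.ndarray:
    """Exact unsigned distance from each point to the closest triangle."""
    tri = mesh.vertices[mesh.faces]  # (F, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    out = np.empty(len(points))
    for start in range(0, len(points), chunk):
        p = points[start:start + chunk][:, None, :]  # (n, 1, 3)
        ap = p - a  # (n, F, 3)
        d1 = np.einsum("fk,nfk->nf", ab, ap)
        d2 = np.einsum("fk,nfk->nf", ac, ap)
        bp = p - b
        d3 = np.einsum("fk,nfk->nf", ab, bp)
        d4 = np.einsum("fk,nfk->nf", ac, bp)
        cp = p - c
        d5 = np.einsum("fk,nfk->nf", ab, cp)
        d6 = np.einsum("fk,nfk->nf", ac, cp)
        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2

        def _safe_div(num, den):
            return num / np.where(den != 0, den, 1.0)

        # Voronoi-region walk (Ericson, Real-Time Collision Detection 5.1.5),
        # vectorized with a done-mask standing in for the early returns.
        v = np.zeros_like(d1)
        w = np.zeros_like(d1)
        done = (d1 <= 0) & (d2 <= 0)  # vertex A: v = w = 0
        cond = ~done & (d3 >= 0) & (d4 <= d3)  # vertex B
        v = np.where(cond, 1.0, v)
        done |= cond
        cond = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge AB
        v = np.where(cond, _safe_div(d1, d1 - d3), v)
        done |= cond
        cond = ~done & (d6 >= 0) & (d5 <= d6)  # vertex C
        w = np.where(cond, 1.0, w)
        done |= cond
        cond = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge AC
        w = np.where(cond, _safe_div(d2, d2 - d6), w)
        done |= cond
        cond = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge BC
        t_bc = _safe_div(d4 - d3, (d4 - d3) + (d5 - d6))
        v = np.where(cond, 1.0 - t_bc, v)
        w = np.where(cond, t_bc, w)
        done |= cond
        denom = va + vb + vc  # interior
        v = np.where(done, v, _safe_div(vb, denom))
        w = np.where(done, w, _safe_div(vc, denom))
        closest = a + v[..., None] * ab + w[..., None] * ac
        d = np.linalg.norm(p - closest, axis=-1)
        out[start:start + chunk] = d.min(axis=1)
    return out


def hausdorff_distance(a: Surface, b: Surface) -> float:
    """Symmetric vertex-to-surface Hausdorff distance (mm).

    Exact point-to-triangle distances from each mesh's vertices to the
    other mesh's surface; a tight proxy for the continuous Hausdorff
    distance at organ-scale vertex densities.
    """
    d_ab = _points_to_mesh_distance(a.vertices, b)
    d_ba = _points_to_mesh_distance(b.vertices, a)
    return float(max(d_ab.max(), d_ba.max()))


# -- I/O ------------------------------------------------------------------

def load_surface(path: str | Path, organ: str = "liver", subject_id: str = "") -> Surface:
    """Read a PLY/OBJ/STL mesh as a Surface (physical mm assumed)."""
    mesh = trimesh.load_mesh(str(path), process=False)
    if isinstance(mesh, trimesh.Scene):  # pragma: no cover - multi-part files
        mesh = mesh.to_mesh()
    return Surface.from_trimesh(mesh, organ=organ, subject_id=subject_id)


def save_surface(surface: Surface, path: str | Path) -> None:
    """Write a Surface as PLY/OBJ/STL, chosen by file extension."""
    surface.to_trimesh().export(str(path))
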