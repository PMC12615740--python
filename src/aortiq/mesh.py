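"""Vessel-wall / ILT meshing from contour segmentations.

A closed luminal contour (and either an outer contour or a uniform wall
thickness) is resampled to C equally spaced circumferential points by arc
length and R radial rings interpolated between the borders along local
outward normals.  Each mesh point carries an orthonormal local frame
(outward normal = radial direction, tangent = circumferential direction)
which the displacement projection and the strain rotation rely on.
Default mesh sizes are 5x101 (wall only) and 17x151 (wall + ILT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Contour",
    "VesselMesh",
    "circle_contour",
    "mesh_from_contours",
    "local_directions",
    "adaptive_strain_kernel",
]


@dataclass
class Contour:
    """Closed 2-D contour, stored counterclockwise, points in mm (x, z)."""

    points: np.ndarray
    role: str = "lumen-wall"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("contour needs at least 3 2-D points")
        # drop a duplicated closing point
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if self.signed_area(pts) < 0:
            pts = pts[::-1]
        self.points = pts

    @staticmethod
    def signed_area(pts: np.ndarray) -> float:
        x, y = pts[:, 0], pts[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def resample(self, n: int) -> np.ndarray:
        """n points equally spaced in arc length (closed; point n would
        coincide with point 0)."""
        pts = np.vstack([self.points, self.points[:1]])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        tgt = np.linspace(0.0, total, n, endpoint=False)
        x = np.interp(tgt, s, pts[:, 0])
        z = np.interp(tgt, s, pts[:, 1])
        return np.column_stack([x, z])


def circle_contour(
    center, radius: float, n: int = 256, jitter: float = 0.0, seed: int = 0, start_angle: float = 0.0
) -> Contour:
    """Analytic circular segmentation, optional radial jitter to mimic
    manual delineation (synthetic stand-in for a human segmentation)."""
    rng = np.random.default_rng(seed)
    th = start_angle + np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = radius + (jitter * rng.standard_normal(n) if jitter > 0 else 0.0)
    pts = np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])
    return Contour(pts)


@dataclass
class VesselMesh:
    """R x C lattice of material points with local frames.

    ``points[i, j]`` is ring i (0 = inner border, R-1 = outer border),
    circumferential index j.  The lattice is periodic in j.
    """

    points: np.ndarray  # (R, C, 2) mm
    region: str = "wall"  # "wall" | "wall+ilt"
    normals: np.ndarray | None = None  # (R, C, 2) outward unit
    circ_dirs: np.ndarray | None = None  # (R, C, 2) unit tangent
    kernel_extents: np.ndarray | None = None  # (R, C, 2) ints (radial, circ)

    @property
    def shape(self):
        return self.points.shape[:2]

    @property
    def centroid(self) -> np.ndarray:
        return self.points.reshape(-1, 2).mean(axis=0)

    def ring_spacing(self, i: int) -> float:
        """Mean circumferential spacing of ring i, mm."""
        p = self.points[i]
        d = np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)
        return float(d.mean())

    def middle_ring_index(self) -> int:
        return self.shape[0] // 2


def mesh_from_contours(inner: Contour, outer, size=(5, 101)) -> VesselMesh:
    """Mesh between the luminal border and the outer border.

    ``outer`` is either a Contour or a uniform wall thickness in mm, in
    which case the outer border is the luminal contour offset along its
    local outward normals (the 2 mm extruded-wall convention).
    """
    R, C = size
    if R < 2 or C < 4:
        raise ValueError("mesh size too small")
    inner_pts = inner.resample(C)
    centroid = inner_pts.mean(axis=0)
    nrm = _outward_normals(inner_pts, centroid)
    if isinstance(outer, Contour):
        outer_pts = _match_outer(outer, inner_pts, nrm)
        region = "wall+ilt"
    else:
        thickness = float(outer)
        if thickness <= 0:
            raise ValueError("wall thickness must be positive")
        outer_pts = inner_pts + thickness * nrm
        region = "wall"
    if np.any(np.einsum("ij,ij->i", outer_pts - inner_pts, nrm) <= 0):
        raise ValueError("outer border crosses the inner border")
    frac = np.linspace(0.0, 1.0, R)[:, None, None]
    points = inner_pts[None] * (1 - frac) + outer_pts[None] * frac
    mesh = VesselMesh(points=points, region=region)
    return local_directions(mesh)


def _match_outer(outer: Contour, inner_pts: np.ndarray, nrm: np.ndarray) -> np.ndarray:
    """Intersect each inner-point normal ray with the outer contour
    (nearest-point fallback keeps eccentric shapes robust)."""
    opts = outer.resample(max(len(inner_pts) * 4, 256))
    out = np.empty_like(inner_pts)
    for k, (p, n) in enumerate(zip(inner_pts, nrm)):
        rel = opts - p
        along = rel @ n
        perp = np.abs(rel @ np.array([-n[1], n[0]]))
        cand = along > 0
        if not np.any(cand):
            raise ValueError("outer contour does not enclose the inner contour")
        score = perp + np.where(cand, 0.0, 1e9)
        out[k] = opts[np.argmin(score)]
    return out


def _outward_normals(pts: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    ln = np.linalg.norm(tang, axis=1, keepdims=True)
    if np.any(ln < 1e-12):
        raise ValueError("duplicate adjacent contour points")
    tang = tang / ln
    nrm = np.column_stack([tang[:, 1], -tang[:, 0]])
    # orient outward with respect to the centroid
    flip = np.einsum("ij,ij->i", nrm, pts - centroid) < 0
    nrm[flip] *= -1
    return nrm


def local_directions(mesh: VesselMesh) -> VesselMesh:
    """Circumferential tangents by central differences along j; outward
    normals as the perpendicular, oriented away from the mesh centroid."""
    pts = mesh.points
    consec = np.linalg.norm(np.roll(pts, -1, axis=1) - pts, axis=-1)
    if np.any(consec < 1e-12):
        raise ValueError("duplicate adjacent mesh points")
    tang = np.roll(pts, -1, axis=1) - np.roll(pts, 1, axis=1)
    ln = np.linalg.norm(tang, axis=-1, keepdims=True)
    if np.any(ln < 1e-12):
        raise ValueError("duplicate adjacent mesh points")
    tang = tang / ln
    nrm = np.stack([tang[..., 1], -tang[..., 0]], axis=-1)
    c = mesh.centroid
    flip = np.einsum("...i,...i->...", nrm, pts - c) < 0
    nrm[flip] *= -1
    # keep the frame right-handed after any flips
    tang = np.stack([-nrm[..., 1], nrm[..., 0]], axis=-1)
    mesh.normals = nrm
    mesh.circ_dirs = tang
    return mesh


def _odd_clip(n: float, lo: int, hi: int) -> int:
    """Nearest odd integer to n, clipped to [lo, hi]."""
    k = int(np.floor(n))
    c1, c2 = (k, k + 2) if k % 2 else (k - 1, k + 1)
    k = c1 if abs(n - c1) <= abs(n - c2) else c2
    return int(np.clip(k, lo, hi))


def adaptive_strain_kernel(mesh: VesselMesh, outer_kernel=(9, 15)) -> np.ndarray:
    """Per-point strain-kernel extents (radial, circumferential) in mesh
    points.

    Wall-only meshes use a constant (5, 9) kernel.  For wall+ILT meshes
    the circumferential extent grows toward the inner border so that the
    kernel's physical width stays approximately equal to its width at the
    outer border, where the nominal kernel is ``outer_kernel``.
    """
    R, C = mesh.shape
    if mesh.region != "wall+ilt":
        ext = np.empty((R, C, 2), dtype=int)
        ext[..., 0] = min(5, R if R % 2 else R - 1)
        ext[..., 1] = 9
        mesh.kernel_extents = ext
        return ext
    kr, kc = outer_kernel
    outer_sp = mesh.ring_spacing(R - 1)
    ext = np.empty((R, C, 2), dtype=int)
    ext[..., 0] = min(kr, R if R % 2 else R - 1)
    for i in range(R):
        sp = mesh.ring_spacing(i)
        ext[i, :, 1] = _odd_clip(kc * outer_sp / max(sp, 1e-12), kc, C - 1 if (C - 1) % 2 else C - 2)
    mesh.kernel_extents = ext
    return ext
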