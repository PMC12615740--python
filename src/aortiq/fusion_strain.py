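"""Multi-aperture displacement fusion and regularized strain estimation.

The bistatic arm only uses the (phase-accurate) axial displacement of
each pathway.  At every mesh point the axial estimate of pathway k is
projected onto the local radial direction, u_rad = u_ax / cos(theta_k),
with theta_k the angle between that pathway's axial direction and the
outward normal, and the four projections are fused with angular weight
masks,

    u_rad = M11 u11 + M22 u22 + (M12 u12 + M21 u21) / 2,

the trans-probe pair again sharing half weights.  Raw weights are
cos^2(theta) with a hard cutoff at theta_max (the 1/cos projection
diverges at grazing incidence) and are normalized so the combination
above sums to one wherever any pathway has support.

Rigid anterior motion of the aorta (the spine blocks posterior
expansion) shifts the midpoint every frame and leaks into the radial
projection; the tracked midpoints are smoothed over time and the
per-pair shift is removed in each pathway's own axial frame before
projection, which reduces to the orthogonal-projection correction
c = -(s.n)n at theta = 0 and exactly cancels a pure translation.

Frame-to-frame fused displacements can be regularized by constraining
the thin-plate bending roughness, E*_bend <= xi* . gamma . RMS(u_r),
with gamma a constant of the initial mesh geometry and xi* = 0.9 the
default (only xi* < 1 constrains at all).  Strain is a 2-D least-squares
fit of the displacement field (relative to the first end-diastole)
within adaptive kernels, rotated into the local radial/circumferential
frame; the principal strain is the larger eigenvalue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .mesh import VesselMesh

__all__ = [
    "WeightMask",
    "RegularizerConfig",
    "MidpointTrack",
    "StrainField",
    "radial_project",
    "angular_weights",
    "compound_displacements",
    "smooth_midpoints",
    "midpoint_correct",
    "bending_roughness",
    "geometry_factor",
    "regularize_displacements",
    "lsq_strain",
    "bistatic_track",
    "single_aperture_track",
]

THETA_MAX_DEFAULT = np.deg2rad(75.0)


@dataclass
class WeightMask:
    """Normalized angular weights and projection cosines per pathway.

    ``weights[k]`` (R, C) with pathway order (T1R1, T2R2, T1R2, T2R1);
    ``cos_theta[k]`` signed cosines between pathway axial direction and
    the outward normal.  ``covered`` marks points with any support.
    """

    weights: np.ndarray  # (4, R, C)
    cos_theta: np.ndarray  # (4, R, C) signed
    covered: np.ndarray  # (R, C) bool

    def combination_sum(self) -> np.ndarray:
        w = self.weights
        return w[0] + w[1] + 0.5 * w[2] + 0.5 * w[3]


@dataclass
class RegularizerConfig:
    xi_star: float = 0.9
    gamma: float = 0.0  # computed once from the initial mesh
    e_bend: float = 0.0  # diagnostic: last measured roughness
    rms_ur: float = 0.0

    def __post_init__(self) -> None:
        if self.xi_star <= 0:
            raise ValueError("xi_star must be positive")


@dataclass
class MidpointTrack:
    raw: np.ndarray  # (F, 2) mm
    smoothed: np.ndarray  # (F, 2) mm
    shifts: np.ndarray  # (F-1, 2) mm, per frame pair


@dataclass
class StrainField:
    radial: np.ndarray  # (F, R, C)
    circumferential: np.ndarray
    principal: np.ndarray
    valid: np.ndarray  # (R, C) bool
    reference_frame: int = 0


def radial_project(u_ax, cos_theta, theta_max: float = THETA_MAX_DEFAULT):
    """u_rad = u_ax / cos(theta); points beyond the cutoff are flagged
    unsupported rather than projected."""
    u_ax = np.asarray(u_ax, dtype=float)
    ct = np.asarray(cos_theta, dtype=float)
    supported = np.abs(ct) >= np.cos(theta_max)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(supported, u_ax / np.where(supported, ct, 1.0), 0.0)
    return u, supported


def angular_weights(
    mesh: VesselMesh, axial_dirs: np.ndarray, theta_max: float = THETA_MAX_DEFAULT
) -> WeightMask:
    """cos^2 angular weights, zero beyond theta_max, normalized so that
    M11 + M22 + (M12 + M21)/2 = 1 wherever any pathway has support.

    ``axial_dirs``: (4, R, C, 2) unit axial directions of the pathways
    (trans-probe pathways use the virtual-probe geometry).
    """
    n = mesh.normals
    ct = np.einsum("kijd,ijd->kij", axial_dirs, n)
    supported = np.abs(ct) >= np.cos(theta_max)
    raw = np.where(supported, ct**2, 0.0)
    denom = raw[0] + raw[1] + 0.5 * raw[2] + 0.5 * raw[3]
    covered = denom > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(covered[None], raw / np.where(covered, denom, 1.0)[None], 0.0)
    return WeightMask(weights=w, cos_theta=ct, covered=covered)


def compound_displacements(u_rad: np.ndarray, mask: WeightMask) -> np.ndarray:
    """Pointwise fusion rule; uncovered points fall back to the pathway
    with the smallest |theta| (with a warning)."""
    w = mask.weights
    fused = w[0] * u_rad[0] + w[1] * u_rad[1] + 0.5 * (w[2] * u_rad[2] + w[3] * u_rad[3])
    if not mask.covered.all():
        warnings.warn("uncovered mesh points; falling back to best single pathway")
        best = np.argmax(np.abs(mask.cos_theta), axis=0)
        fb = np.take_along_axis(u_rad, best[None], axis=0)[0]
        fused = np.where(mask.covered, fused, fb)
    return fused


def smooth_midpoints(midpoints: np.ndarray, times: np.ndarray, smoothing: float = 0.01) -> MidpointTrack:
    """Smoothing spline through the per-frame centroids; ``smoothing`` is
    the tolerated RMS residual in mm."""
    mp = np.asarray(midpoints, dtype=float)
    if len(mp) < 4:
        sm = mp.copy()
    else:
        s = len(mp) * smoothing**2
        sm = np.column_stack(
            [UnivariateSpline(times, mp[:, d], s=s, k=3)(times) for d in range(2)]
        )
    return MidpointTrack(raw=mp, smoothed=sm, shifts=np.diff(sm, axis=0))


def midpoint_correct(coords: np.ndarray, normals: np.ndarray, smoothing: float = 0.01) -> np.ndarray:
    """Rigid-shift correction of tracked coordinates, c = -(s.n)n.

    ``coords``: (F, ..., 2) tracked positions; ``normals``: (..., 2)
    end-diastolic outward normals.  The per-pair midpoint shift s of the
    smoothed centroid track is projected onto the local normals and
    removed cumulatively.
    """
    coords = np.asarray(coords, dtype=float)
    F = coords.shape[0]
    mid = coords.reshape(F, -1, 2).mean(axis=1)
    track = smooth_midpoints(mid, np.arange(F, dtype=float), smoothing)
    out = coords.copy()
    cum = np.zeros(coords.shape[1:], dtype=float)
    for f in range(1, F):
        s = track.shifts[f - 1]
        sn = normals @ s  # (...,)
        cum = cum + (-sn[..., None]) * normals
        out[f] = out[f] + cum
    return out


# -- Eq. 4 regularization -------------------------------------------------


def _second_diffs(field: np.ndarray, hr: float, hc: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Second derivatives on the mesh lattice (radial edge replicated,
    circumferential periodic), scaled by the physical spacings."""
    frr = (np.roll(field, -1, axis=0) - 2 * field + np.roll(field, 1, axis=0)) / hr**2
    frr[0] = frr[1]
    frr[-1] = frr[-2]
    fcc = (np.roll(field, -1, axis=1) - 2 * field + np.roll(field, 1, axis=1)) / hc**2
    fr = (np.roll(field, -1, axis=0) - np.roll(field, 1, axis=0)) / (2 * hr)
    fr[0] = (field[1] - field[0]) / hr
    fr[-1] = (field[-1] - field[-2]) / hr
    frc = (np.roll(fr, -1, axis=1) - np.roll(fr, 1, axis=1)) / (2 * hc)
    return frr, frc, fcc


def bending_roughness(fields: np.ndarray, mesh: VesselMesh) -> float:
    """RMS thin-plate roughness of one or more scalar fields on the mesh
    lattice: sqrt(mean(u_rr^2 + 2 u_rc^2 + u_cc^2)); linear in u so the
    Eq. 4 bound is scale invariant."""
    fields = np.atleast_3d(np.asarray(fields, dtype=float))
    if fields.shape[-2:] == mesh.shape:
        stack = fields.reshape(-1, *mesh.shape)
    else:
        stack = fields[None] if fields.shape == mesh.shape else fields
    R, C = mesh.shape
    hr = float(np.mean(np.linalg.norm(np.diff(mesh.points, axis=0), axis=-1))) if R > 1 else 1.0
    hc = float(np.mean([mesh.ring_spacing(i) for i in range(R)]))
    acc = 0.0
    for f in stack:
        frr, frc, fcc = _second_diffs(f, hr, hc)
        acc += float(np.mean(frr**2 + 2 * frc**2 + fcc**2))
    return float(np.sqrt(acc / len(stack)))


def geometry_factor(mesh: VesselMesh) -> float:
    """gamma of the Eq. 4 bound: the bending roughness per unit RMS of a
    unit-magnitude outward-normal displacement of the initial mesh."""
    u = mesh.normals  # |u| = 1 everywhere -> RMS = 1
    return bending_roughness(np.stack([u[..., 0], u[..., 1]]), mesh)


def _smooth_lattice(field: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing on the lattice: periodic circumferentially,
    replicated radially."""
    out = gaussian_filter1d(field, sigma, axis=1, mode="wrap")
    if field.shape[0] > 2:
        out = gaussian_filter1d(out, sigma, axis=0, mode="nearest")
    return out


def regularize_displacements(
    u_r: np.ndarray,
    mesh: VesselMesh,
    cfg: RegularizerConfig,
    companions: list[np.ndarray] | None = None,
):
    """Constrain the bending roughness of a frame-to-frame radial
    displacement field to xi* . gamma . RMS(u_r).

    Fields already satisfying the bound are returned unchanged; rough
    fields are smoothed on the mesh lattice with the smoothing width
    found by bisection so the constraint holds with ~1% equality.
    ``companions`` (e.g. a circumferential component) are smoothed with
    the same width.
    """
    u_r = np.asarray(u_r, dtype=float)
    gamma = cfg.gamma if cfg.gamma > 0 else geometry_factor(mesh)
    rms = float(np.sqrt(np.mean(u_r**2)))
    bound = cfg.xi_star * gamma * rms
    e0 = bending_roughness(u_r, mesh)
    cfg.gamma, cfg.rms_ur, cfg.e_bend = gamma, rms, e0
    comp = companions or []
    if not np.isfinite(bound) or e0 <= bound:
        return (u_r, *comp) if comp else u_r
    if rms == 0:
        warnings.warn("zero RMS radial displacement with nonzero roughness; fully smoothing")
        sig = max(u_r.shape) / 2
        out = _smooth_lattice(u_r, sig)
        cfg.e_bend = bending_roughness(out, mesh)
        return (out, *[_smooth_lattice(c, sig) for c in comp]) if comp else out
    lo, hi = 1e-3, 0.5
    while bending_roughness(_smooth_lattice(u_r, hi), mesh) > bound and hi < max(u_r.shape):
        lo, hi = hi, hi * 2
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if bending_roughness(_smooth_lattice(u_r, mid), mesh) > bound:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4 * hi:
            break
    out = _smooth_lattice(u_r, hi)
    cfg.e_bend = bending_roughness(out, mesh)
    return (out, *[_smooth_lattice(c, hi) for c in comp]) if comp else out


# -- least-squares strain -------------------------------------------------


def lsq_strain(
    coords: np.ndarray,
    mesh: VesselMesh,
    kernel_extents: np.ndarray | None = None,
    reference_frame: int = 0,
) -> StrainField:
    """2-D least-squares strain of tracked coordinates.

    Within each point's kernel window (periodic circumferentially) the
    displacement relative to the reference frame is fit as a linear
    function of the reference position; the symmetric part of the fitted
    gradient is the infinitesimal strain tensor, rotated into the local
    radial/circumferential frame.  Principal strain = larger eigenvalue.
    """
    coords = np.asarray(coords, dtype=float)
    F, R, C = coords.shape[:3]
    if kernel_extents is None:
        if mesh.kernel_extents is None:
            from .mesh import adaptive_strain_kernel

            adaptive_strain_kernel(mesh)
        kernel_extents = mesh.kernel_extents
    ref = coords[reference_frame]
    n = mesh.normals
    t = mesh.circ_dirs
    e_rr = np.zeros((F, R, C))
    e_cc = np.zeros((F, R, C))
    e_p = np.zeros((F, R, C))
    valid = np.ones((R, C), dtype=bool)
    disp = coords - ref[None]

    # cache window index arrays per distinct kernel extent
    win_cache: dict[tuple[int, int, int], tuple[np.ndarray, np.ndarray]] = {}

    def window(i, j):
        kr, kc = int(kernel_extents[i, j, 0]), int(kernel_extents[i, j, 1])
        hr, hc = kr // 2, kc // 2
        i0, i1 = max(0, i - hr), min(R, i + hr + 1)
        key = (i0, i1, kc)
        ii = np.arange(i0, i1)
        jj = (j + np.arange(-hc, hc + 1)) % C
        return ii, jj

    for i in range(R):
        for j in range(C):
            ii, jj = window(i, j)
            P = ref[np.ix_(ii, jj)].reshape(-1, 2)
            X = np.column_stack([np.ones(len(P)), P])
            D = disp[:, ii][:, :, jj].reshape(F, -1, 2)
            sol, _, rank, _ = np.linalg.lstsq(X, D.transpose(1, 0, 2).reshape(len(P), -1), rcond=None)
            if rank < 3:
                valid[i, j] = False
                continue
            G = sol[1:].reshape(2, F, 2).transpose(1, 0, 2)  # (F, d/dx, comp)
            # gradient: G[f, a, b] = d u_b / d x_a ; strain = sym part
            exx = G[:, 0, 0]
            ezz = G[:, 1, 1]
            exz = 0.5 * (G[:, 0, 1] + G[:, 1, 0])
            nn, tt = n[i, j], t[i, j]
            e_rr[:, i, j] = (
                exx * nn[0] ** 2 + 2 * exz * nn[0] * nn[1] + ezz * nn[1] ** 2
            )
            e_cc[:, i, j] = (
                exx * tt[0] ** 2 + 2 * exz * tt[0] * tt[1] + ezz * tt[1] ** 2
            )
            tr = 0.5 * (exx + ezz)
            dd = np.sqrt((0.5 * (exx - ezz)) ** 2 + exz**2)
            e_p[:, i, j] = tr + dd
    e_rr[:, ~valid] = 0.0
    e_cc[:, ~valid] = 0.0
    e_p[:, ~valid] = 0.0
    return StrainField(
        radial=e_rr, circumferential=e_cc, principal=e_p, valid=valid, reference_frame=reference_frame
    )


# -- arm drivers ----------------------------------------------------------


def bistatic_track(
    mesh: VesselMesh,
    pathway_fields,
    pathway_grids,
    regularizer: RegularizerConfig | None = None,
    theta_max: float = THETA_MAX_DEFAULT,
    n_corrections: int = 12,
    midpoint_smoothing: float = 0.01,
):
    """Radial-only tracking of the mesh through fused axial displacements.

    ``pathway_fields``: sequence over frame pairs of 4-tuples of
    DisplacementField (order T1R1, T2R2, T1R2, T2R1); ``pathway_grids``
    the matching grids.  The smoothed midpoint shift is estimated from
    the tracked centroids and removed in each pathway's axial frame
    before projection, iterated to convergence; Eq. 4 regularization is
    applied to the frame-to-frame fused radial field when configured.

    Returns (coords (F, R, C, 2), midpoint track).
    """
    from .tracking import sample_field

    R, C = mesh.shape
    n_pairs = len(pathway_fields)
    points0 = mesh.points
    n = mesh.normals
    ax_dirs_at = [g.axial_dirs() for g in pathway_grids]

    shifts = np.zeros((n_pairs, 2))
    track = None
    for _ in range(max(n_corrections, 1)):
        coords = np.empty((n_pairs + 1, R, C, 2))
        coords[0] = points0
        for p in range(n_pairs):
            fields = pathway_fields[p]
            u_rad = np.empty((4, R, C))
            ax_dirs = np.empty((4, R, C, 2))
            for k in range(4):
                fld = fields[k]
                g = pathway_grids[k]
                u_ax = sample_field(g, fld.u_ax, coords[p], warn=False)
                idx = g.index_coords(coords[p])
                th = g.axis_angle + g.theta0 + np.clip(idx[..., 1], 0, g.ntheta - 1) * g.dtheta
                ad = np.stack([np.sin(th), np.cos(th)], axis=-1)
                ax_dirs[k] = ad
                u_ax = u_ax - ad @ shifts[p]
                ct = np.einsum("ijd,ijd->ij", ad, n)
                u, _ = radial_project(u_ax, ct, theta_max)
                u_rad[k] = u
            mask = angular_weights(mesh, ax_dirs, theta_max)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fused = compound_displacements(u_rad, mask)
            if regularizer is not None:
                fused = regularize_displacements(fused, mesh, regularizer)
            coords[p + 1] = coords[p] + fused[..., None] * n
        mids = coords.reshape(n_pairs + 1, -1, 2).mean(axis=1)
        track = smooth_midpoints(mids, np.arange(n_pairs + 1, dtype=float), midpoint_smoothing)
        residual = track.shifts
        if np.max(np.abs(residual)) < 1e-5:
            break
        shifts = shifts + residual
    return coords, track


def single_aperture_track(
    mesh: VesselMesh,
    fields,
    grid,
    regularizer: RegularizerConfig | None = None,
    midpoint_smoothing: float = 0.01,
):
    """Conventional arm: full axial + lateral displacement vectors from a
    single pathway, accumulated, then the Eq. 3 midpoint correction; the
    same optional Eq. 4 regularization acts on the radial component."""
    from .tracking import sample_field

    R, C = mesh.shape
    n = mesh.normals
    t = mesh.circ_dirs
    coords = np.empty((len(fields) + 1, R, C, 2))
    coords[0] = mesh.points
    ax_dirs = grid.axial_dirs()
    lat_dirs = grid.lateral_dirs()
    for p, fld in enumerate(fields):
        u_ax = sample_field(grid, fld.u_ax, coords[p], warn=False)
        u_lat = sample_field(grid, fld.u_lat, coords[p], warn=False)
        idx = grid.index_coords(coords[p])
        th = grid.axis_angle + grid.theta0 + np.clip(idx[..., 1], 0, grid.ntheta - 1) * grid.dtheta
        ad = np.stack([np.sin(th), np.cos(th)], axis=-1)
        ld = np.stack([ad[..., 1], -ad[..., 0]], axis=-1)
        u = u_ax[..., None] * ad + u_lat[..., None] * ld
        if regularizer is not None:
            u_r = np.einsum("ijd,ijd->ij", u, n)
            u_c = np.einsum("ijd,ijd->ij", u, t)
            u_r, u_c = regularize_displacements(u_r, mesh, regularizer, companions=[u_c])
            u = u_r[..., None] * n + u_c[..., None] * t
        coords[p + 1] = coords[p] + u
    corrected = midpoint_correct(coords, n, smoothing=midpoint_smoothing)
    return corrected
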