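"""Delay-and-sum reconstruction and bistatic coherent compounding.

Per-pathway IQ images are formed by classic DAS: for every pixel the
demodulated channel signals are delayed along the transmit (virtual
source) and receive (element) paths, phase-rotated back to RF, apodized
with a depth-dependent Hann receive aperture (f-number controlled) and
summed coherently over elements and steering angles.

The bistatic image combines the four pathways on a common quarter-wave
Cartesian grid,

    I_bistatic = I_T1R1 + I_T2R2 + (I_T1R2 + I_T2R1) / 2,

the trans-probe pair being averaged because acoustic reciprocity makes
the two signals carry the same information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .acquisition import AcquisitionConfig, ChannelData, RigidTransform, TransducerGeometry

__all__ = [
    "GridSpec",
    "IQImage",
    "ProbePose",
    "cartesian_grid",
    "sector_grid",
    "make_sector_grids",
    "das_reconstruct",
    "compound_bistatic",
    "localize_probe",
    "bmode_render",
    "envelope",
]


@dataclass
class GridSpec:
    """Reconstruction grid; either Cartesian (axial = +z) or a sector of
    rays from a (real or virtual) curved-array apex."""

    kind: str  # "cartesian" | "sector"
    # cartesian
    x0: float = 0.0
    z0: float = 0.0
    dx: float = 0.1
    dz: float = 0.1
    nx: int = 0
    nz: int = 0
    # sector
    apex: tuple[float, float] = (0.0, 0.0)  # curvature centre, world mm
    axis_angle: float = 0.0  # world angle of the central ray
    start_radius: float = 0.0  # radius of the first axial sample
    dr: float = 0.05
    nr: int = 0
    theta0: float = 0.0  # first line angle relative to the axis
    dtheta: float = 0.005
    ntheta: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("cartesian", "sector"):
            raise ValueError("grid kind must be cartesian or sector")
        if self.kind == "cartesian" and (self.dx <= 0 or self.dz <= 0):
            raise ValueError("spacings must be positive")
        if self.kind == "sector" and (self.dr <= 0 or self.dtheta <= 0):
            raise ValueError("spacings must be positive")

    @property
    def shape(self):
        if self.kind == "cartesian":
            return (self.nz, self.nx)
        return (self.nr, self.ntheta)

    def world_points(self) -> np.ndarray:
        """(n_ax, n_lat, 2) world coordinates; axis 0 is axial."""
        if self.kind == "cartesian":
            x = self.x0 + np.arange(self.nx) * self.dx
            z = self.z0 + np.arange(self.nz) * self.dz
            X, Z = np.meshgrid(x, z)
            return np.stack([X, Z], axis=-1)
        r = self.start_radius + np.arange(self.nr) * self.dr
        th = self.axis_angle + self.theta0 + np.arange(self.ntheta) * self.dtheta
        ux = np.sin(th)[None, :]
        uz = np.cos(th)[None, :]
        ax = np.asarray(self.apex)
        return np.stack([ax[0] + r[:, None] * ux, ax[1] + r[:, None] * uz], axis=-1)

    def axial_dirs(self) -> np.ndarray:
        """(n_ax, n_lat, 2) unit axial direction at every pixel."""
        if self.kind == "cartesian":
            d = np.zeros(self.shape + (2,))
            d[..., 1] = 1.0
            return d
        th = self.axis_angle + self.theta0 + np.arange(self.ntheta) * self.dtheta
        d = np.zeros(self.shape + (2,))
        d[..., 0] = np.sin(th)[None, :]
        d[..., 1] = np.cos(th)[None, :]
        return d

    def lateral_dirs(self) -> np.ndarray:
        a = self.axial_dirs()
        return np.stack([a[..., 1], -a[..., 0]], axis=-1)

    def lateral_spacing(self, axial_index=None) -> np.ndarray | float:
        """Lateral pixel spacing in mm (depth dependent for sectors)."""
        if self.kind == "cartesian":
            return self.dx
        r = self.start_radius + np.arange(self.nr) * self.dr
        sp = r * self.dtheta
        if axial_index is None:
            return sp
        return float(sp[axial_index])

    @property
    def axial_spacing(self) -> float:
        return self.dz if self.kind == "cartesian" else self.dr

    def index_coords(self, points: np.ndarray) -> np.ndarray:
        """Map world points (..., 2) to fractional (axial, lateral) index
        coordinates of this grid."""
        p = np.asarray(points, dtype=float)
        if self.kind == "cartesian":
            i = (p[..., 1] - self.z0) / self.dz
            j = (p[..., 0] - self.x0) / self.dx
            return np.stack([i, j], axis=-1)
        ax = np.asarray(self.apex)
        d = p - ax
        rr = np.hypot(d[..., 0], d[..., 1])
        th = np.arctan2(d[..., 0], d[..., 1])  # world angle of the ray
        rel = _wrap_angle(th - self.axis_angle - self.theta0)
        i = (rr - self.start_radius) / self.dr
        j = rel / self.dtheta
        return np.stack([i, j], axis=-1)


def _wrap_angle(a):
    return (np.asarray(a) + np.pi) % (2 * np.pi) - np.pi


@dataclass
class IQImage:
    values: np.ndarray  # complex, grid.shape
    grid: GridSpec
    pathway: str
    frame_index: int = 0
    center_frequency: float = 3.7e6

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("image dimensions do not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite image values")


@dataclass
class ProbePose:
    rotation: float
    translation: tuple[float, float]
    score: float
    success: bool = True


def cartesian_grid(center, width: float, height: float, spacing: float) -> GridSpec:
    nx = int(round(width / spacing)) + 1
    nz = int(round(height / spacing)) + 1
    return GridSpec(
        kind="cartesian",
        x0=center[0] - (nx - 1) * spacing / 2,
        z0=center[1] - (nz - 1) * spacing / 2,
        dx=spacing,
        dz=spacing,
        nx=nx,
        nz=nz,
    )


def sector_grid(
    apex,
    axis_angle: float,
    depth_range,
    angle_range,
    dr: float,
    dtheta: float,
    start_radius: float = 0.0,
) -> GridSpec:
    r0 = start_radius + depth_range[0]
    nr = int(np.ceil((depth_range[1] - depth_range[0]) / dr)) + 1
    ntheta = int(np.ceil((angle_range[1] - angle_range[0]) / dtheta)) + 1
    return GridSpec(
        kind="sector",
        apex=tuple(np.asarray(apex, dtype=float)),
        axis_angle=axis_angle,
        start_radius=r0,
        dr=dr,
        nr=nr,
        theta0=angle_range[0],
        dtheta=dtheta,
        ntheta=ntheta,
    )


def virtual_probe(geom1: TransducerGeometry, geom2: TransducerGeometry) -> TransducerGeometry:
    """Probe standing in for a third transducer midway between the two:
    curvature centre at the midpoint, axis along the bisector."""
    c1, c2 = geom1.curvature_center(), geom2.curvature_center()
    mid = (c1 + c2) / 2
    ang = _wrap_angle(
        np.angle(
            np.exp(1j * geom1.pose.rotation) + np.exp(1j * geom2.pose.rotation)
        )
    )
    rc = (geom1.curvature_radius + geom2.curvature_radius) / 2
    u = np.array([np.sin(ang), np.cos(ang)])
    pose = RigidTransform(rotation=float(ang), translation=tuple(mid + rc * u))
    return TransducerGeometry(
        n_elements=geom1.n_elements,
        pitch=geom1.pitch,
        curvature_radius=rc,
        center_frequency=geom1.center_frequency,
        pose=pose,
    )


def make_sector_grids(
    geom1: TransducerGeometry,
    geom2: TransducerGeometry,
    roi_center,
    roi_radius: float,
    wavelength: float,
):
    """Sector grids for T1R1 (apex probe 1), T2R2 (apex probe 2) and the
    trans-probe pathways (apex at the virtual mid probe); axial spacing
    lambda/8, two lines per element pitch."""
    grids = []
    for g in (geom1, geom2, virtual_probe(geom1, geom2)):
        apex = g.curvature_center()
        d = np.asarray(roi_center) - apex
        dist = float(np.hypot(*d))
        ang_c = float(np.arctan2(d[0], d[1]))
        half = np.arcsin(np.clip((roi_radius * 1.15) / dist, 0, 0.95)) + 0.02
        dtheta = g.pitch / (2 * g.curvature_radius)
        rel = _wrap_angle(ang_c - g.pose.rotation)
        grids.append(
            sector_grid(
                apex,
                g.pose.rotation,
                (dist - g.curvature_radius - roi_radius * 1.15, dist - g.curvature_radius + roi_radius * 1.15),
                (rel - half, rel + half),
                dr=wavelength / 8,
                dtheta=dtheta,
                start_radius=g.curvature_radius,
            )
        )
    return tuple(grids)


@njit(cache=True, fastmath=True)
def _das_kernel(
    acc,  # (P,) complex128
    px,  # (P,)
    pz,  # (P,)
    iq,  # (E, S) complex128 for one angle
    el,  # (E, 2)
    src,  # (2,)
    src_offset,  # mm
    rx_center,  # (2,) curvature centre of the receiving probe
    rx_radius,
    t_start,
    fs,
    c_mm_s,
    f0,
    f_number,
):
    n_p = px.shape[0]
    n_el = el.shape[0]
    n_s = iq.shape[1]
    two_pi_f0 = 2.0 * np.pi * f0
    for ip in range(n_p):
        x = px[ip]
        z = pz[ip]
        dx = x - src[0]
        dz = z - src[1]
        tau_tx = (np.sqrt(dx * dx + dz * dz) - src_offset) / c_mm_s
        # pixel depth and angle about the receive curvature centre
        cx = x - rx_center[0]
        cz = z - rx_center[1]
        rad = np.sqrt(cx * cx + cz * cz)
        depth = rad - rx_radius
        if depth <= 0.0:
            continue
        half_ap = depth / (2.0 * f_number)
        val = 0.0j
        for e in range(n_el):
            ex = x - el[e, 0]
            ez = z - el[e, 1]
            r = np.sqrt(ex * ex + ez * ez)
            # arc distance between element and pixel direction on the array
            ax = el[e, 0] - rx_center[0]
            az = el[e, 1] - rx_center[1]
            cosd = (ax * cx + az * cz) / (rx_radius * rad)
            if cosd > 1.0:
                cosd = 1.0
            elif cosd < -1.0:
                cosd = -1.0
            arc = rx_radius * np.arccos(cosd)
            if arc >= half_ap:
                continue
            w = 0.5 + 0.5 * np.cos(np.pi * arc / half_ap)
            tau = tau_tx + r / c_mm_s
            k = (tau - t_start) * fs
            k0 = int(np.floor(k))
            if k0 < 0 or k0 + 1 >= n_s:
                continue
            frac = k - k0
            s = iq[e, k0] * (1.0 - frac) + iq[e, k0 + 1] * frac
            ph = two_pi_f0 * tau
            val += w * s * complex(np.cos(ph), np.sin(ph))
        acc[ip] += val


def das_reconstruct(
    data: ChannelData,
    grid: GridSpec,
    tx_geom: TransducerGeometry,
    rx_geom: TransducerGeometry,
    cfg: AcquisitionConfig,
    frame: int = 0,
    f_number: float = 1.5,
    angle_indices=None,
    pathway: str = "",
) -> IQImage:
    """Coherent DAS over receive elements and steering angles for one
    frame of one pathway (IQ input, phase-preserving)."""
    if not data.is_iq:
        raise ValueError("das_reconstruct expects IQ channel data")
    pts = grid.world_points()
    px = np.ascontiguousarray(pts[..., 0].ravel())
    pz = np.ascontiguousarray(pts[..., 1].ravel())
    acc = np.zeros(px.shape, dtype=np.complex128)
    el = np.ascontiguousarray(rx_geom.element_positions())
    rx_c = rx_geom.curvature_center()
    c_mm = cfg.speed_of_sound * 1e3
    idxs = range(len(data.angles)) if angle_indices is None else angle_indices
    for a in idxs:
        ang = data.angles[a]
        src = tx_geom.virtual_source(ang)
        off = float(np.min(np.linalg.norm(tx_geom.element_positions() - src, axis=1)))
        _das_kernel(
            acc,
            px,
            pz,
            np.ascontiguousarray(data.samples[frame, a]),
            el,
            src,
            off,
            rx_c,
            rx_geom.curvature_radius,
            data.t_start,
            data.sampling_frequency,
            c_mm,
            data.center_frequency,
            f_number,
        )
    return IQImage(
        values=acc.reshape(grid.shape),
        grid=grid,
        pathway=pathway or f"T{data.tx_aperture + 1}R{data.rx_aperture + 1}",
        frame_index=frame,
        center_frequency=data.center_frequency,
    )


def compound_bistatic(i11: IQImage, i22: IQImage, i12: IQImage, i21: IQImage) -> IQImage:
    """Coherent bistatic compound with the trans-probe pair averaged."""
    for im in (i22, i12, i21):
        if im.grid != i11.grid:
            raise ValueError("all pathways must share an identical grid")
    vals = i11.values + i22.values + 0.5 * (i12.values + i21.values)
    return IQImage(
        values=vals,
        grid=i11.grid,
        pathway="bistatic",
        frame_index=i11.frame_index,
        center_frequency=i11.center_frequency,
    )


def envelope(img: IQImage) -> np.ndarray:
    return np.abs(img.values)


def bmode_render(img: IQImage, dynamic_range_db: float = 55.0, alpha: float = 1.3) -> np.ndarray:
    """8-bit log-compressed, contrast-stretched B-mode."""
    env = envelope(img)
    peak = env.max()
    if peak == 0:
        import warnings

        warnings.warn("all-zero image; rendering uniform black")
        return np.zeros(env.shape, dtype=np.uint8)
    db = 20 * np.log10(np.maximum(env / peak, 1e-12))
    norm = np.clip((db + dynamic_range_db) / dynamic_range_db, 0.0, 1.0)
    return np.round(255 * norm**alpha).astype(np.uint8)


def _coherence(i12: np.ndarray, i21: np.ndarray) -> float:
    num = np.abs(np.vdot(i12, i21))
    den = np.sqrt(np.vdot(i12, i12).real * np.vdot(i21, i21).real)
    if den == 0:
        return 0.0
    return float(num / den)


def localize_probe(
    data12: ChannelData,
    data21: ChannelData,
    geom1: TransducerGeometry,
    geom2_nominal: TransducerGeometry,
    cfg: AcquisitionConfig,
    roi_center,
    roi_size: float = 12.0,
    rot_range: float = np.deg2rad(5.0),
    trans_range: float = 5.0,
    n_steps: int = 5,
    n_levels: int = 3,
    frame: int = 0,
    min_score: float = 0.2,
) -> ProbePose:
    """Grid-search probe-2 pose by maximizing trans-probe coherence.

    The T1R2 and T2R1 images beamformed under a candidate probe-2 pose
    only align (reciprocity) at the true pose; the normalized complex
    correlation of the two images over a central ROI is the objective.
    Coarse-to-fine refinement over (rotation, x, z) perturbations of the
    nominal pose.
    """
    grid = cartesian_grid(roi_center, roi_size, roi_size, spacing=cfg.wavelength / 2)
    mid = len(data12.angles) // 2

    def score(drot, dx, dz):
        pose = RigidTransform(
            rotation=geom2_nominal.pose.rotation + drot,
            translation=(
                geom2_nominal.pose.translation[0] + dx,
                geom2_nominal.pose.translation[1] + dz,
            ),
        )
        g2 = TransducerGeometry(
            n_elements=geom2_nominal.n_elements,
            pitch=geom2_nominal.pitch,
            curvature_radius=geom2_nominal.curvature_radius,
            center_frequency=geom2_nominal.center_frequency,
            pose=pose,
        )
        i12 = das_reconstruct(data12, grid, geom1, g2, cfg, frame=frame, angle_indices=[mid])
        i21 = das_reconstruct(data21, grid, g2, geom1, cfg, frame=frame, angle_indices=[mid])
        return _coherence(i12.values, i21.values)

    best = (0.0, 0.0, 0.0)
    best_score = -1.0
    rr, tr = rot_range, trans_range
    center = best
    for _ in range(n_levels):
        rots = center[0] + np.linspace(-rr, rr, n_steps)
        dxs = center[1] + np.linspace(-tr, tr, n_steps)
        dzs = center[2] + np.linspace(-tr, tr, n_steps)
        for dr_ in rots:
            for dx_ in dxs:
                for dz_ in dzs:
                    s = score(dr_, dx_, dz_)
                    if s > best_score:
                        best_score, best = s, (dr_, dx_, dz_)
        center = best
        rr /= n_steps - 1
        tr /= n_steps - 1
    ok = best_score >= min_score
    if not ok:
        best = (0.0, 0.0, 0.0)  # fall back to the nominal pose
    return ProbePose(
        rotation=geom2_nominal.pose.rotation + best[0],
        translation=(
            geom2_nominal.pose.translation[0] + best[1],
            geom2_nominal.pose.translation[1] + best[2],
        ),
        score=best_score,
        success=ok,
    )
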