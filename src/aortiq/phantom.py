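"""Synthetic pulsating AAA cross-section with analytic ground truth.

The phantom is a 2-D transverse slice of an abdominal aortic aneurysm:
a hypoechoic lumen, optionally an intermediate-echogenicity intraluminal
thrombus (ILT), an echogenic wall of uniform thickness, and speckle
background.  Kinematics are analytic: plane-strain incompressible radial
pulsation of the wall, an optional more-compliant ILT layer blended to
the wall motion at the ILT/wall interface, and a strain-free rigid
anterior shift of the whole cross-section (the aorta is pushed anteriorly
during systole because the spine blocks posterior expansion).  Because
the motion is analytic, displacement and circumferential/radial strain
are known exactly at every material point, which is what the tracking
and strain stages are validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhantomSpec",
    "Phantom",
    "PhantomFrame",
    "make_phantom",
    "kinematics_at",
    "ground_truth_strain",
    "cardiac_waveform",
]

#: region labels
LUMEN, ILT, WALL, BACKGROUND = "lumen", "ilt", "wall", "background"

DEFAULT_ECHOGENICITY = {LUMEN: 0.02, ILT: 0.25, WALL: 1.0, BACKGROUND: 0.5}


@dataclass
class PhantomSpec:
    """Geometry, echogenicity and kinematics of the synthetic vessel.

    Lengths in mm, times in s.  ``lumen_radius`` is the inner radius of
    the wall (equal to the ILT outer radius when an ILT is present);
    ``ilt_inner_radius`` is then the blood/thrombus border.
    """

    lumen_radius: float = 10.0
    wall_thickness: float = 2.0
    ilt_present: bool = False
    ilt_inner_radius: float = 6.0
    center: tuple[float, float] = (0.0, 45.0)
    field_size: tuple[float, float] = (40.0, 40.0)
    scatterer_density: float = 4.0  # per mm^2
    echogenicity: dict = field(default_factory=lambda: dict(DEFAULT_ECHOGENICITY))
    period: float = 1.0
    pulsation: float = 0.19  # systolic radial increment of the wall inner border, mm
    systole_fraction: float = 0.3
    ilt_compliance_ratio: float = 3.0  # lumen-border pulsation relative to the wall border
    midpoint_shift_amplitude: float = 0.3  # peak anterior shift, mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lumen_radius <= 0:
            raise ValueError("lumen_radius must be positive")
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")
        if self.ilt_present and not (0 < self.ilt_inner_radius < self.lumen_radius):
            raise ValueError("ilt_inner_radius must lie strictly inside the wall inner radius")
        e = self.echogenicity
        if not (e[LUMEN] < e[ILT] < e[WALL]):
            raise ValueError("echogenicity must be ordered lumen < ILT < wall")

    @property
    def outer_radius(self) -> float:
        return self.lumen_radius + self.wall_thickness

    @property
    def inner_border_radius(self) -> float:
        """Radius of the blood-facing border (ILT inner border if ILT present)."""
        return self.ilt_inner_radius if self.ilt_present else self.lumen_radius


@dataclass
class PhantomFrame:
    """Scatterer state plus ground truth at one instant."""

    time: float
    scatterer_positions: np.ndarray  # (N, 2) mm, world frame (x, z)
    scatterer_amplitudes: np.ndarray  # (N,)
    true_displacement: np.ndarray  # (N, 2) mm relative to t = 0
    true_strain_circ: np.ndarray  # (N,)


class Phantom:
    """Scatterer cloud with attached analytic kinematics."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        fx, fz = spec.field_size
        area = fx * fz
        n = int(round(spec.scatterer_density * area))
        cx, cz = spec.center
        xs = rng.uniform(cx - fx / 2, cx + fx / 2, n)
        zs = rng.uniform(cz - fz / 2, cz + fz / 2, n)
        self.positions0 = np.column_stack([xs, zs])
        regions = self.region_of(self.positions0)
        echo = np.array([spec.echogenicity[r] for r in regions])
        # Rayleigh-type amplitudes: folded standard normal scaled per region
        self.amplitudes = echo * np.abs(rng.standard_normal(n))
        self.regions = regions

    # -- geometry ---------------------------------------------------------
    def radii(self, points: np.ndarray) -> np.ndarray:
        return np.hypot(points[..., 0] - self.spec.center[0], points[..., 1] - self.spec.center[1])

    def region_of(self, points: np.ndarray) -> np.ndarray:
        s = self.spec
        r = self.radii(np.atleast_2d(points))
        out = np.full(r.shape, BACKGROUND, dtype=object)
        out[r < s.outer_radius] = WALL
        if s.ilt_present:
            out[r < s.lumen_radius] = ILT
            out[r < s.ilt_inner_radius] = LUMEN
        else:
            out[r < s.lumen_radius] = LUMEN
        return out

    # -- kinematics -------------------------------------------------------
    def _mapped_radius(self, r: np.ndarray, t: float) -> np.ndarray:
        """Deformed radius r' for material radius r (no rigid shift)."""
        s = self.spec
        p = cardiac_waveform(t, s.period, s.systole_fraction)
        a = s.lumen_radius
        ap = a + s.pulsation * p
        r = np.asarray(r, dtype=float)
        rp = np.array(r, copy=True)
        if s.ilt_present:
            al = s.ilt_inner_radius
            outer = r >= a
            rp[outer] = np.sqrt(r[outer] ** 2 + ap**2 - a**2)
            # ILT: linear blend from an amplified lumen-border pulsation to
            # the incompressible wall-border motion; more compliant thrombus.
            ilt = (r >= al) & (r < a)
            u_border = s.ilt_compliance_ratio * s.pulsation * p
            u_wall = ap - a
            beta = (r[ilt] - al) / (a - al)
            rp[ilt] = r[ilt] + (1 - beta) * u_border + beta * u_wall
            inner = r < al
            rp[inner] = r[inner] * (1 + u_border / max(al, 1e-9))
        else:
            outside = r >= a
            rp[outside] = np.sqrt(r[outside] ** 2 + ap**2 - a**2)
            rp[~outside] = r[~outside] * (ap / a)
        return rp

    def _shift(self, t: float) -> np.ndarray:
        s = self.spec
        p = cardiac_waveform(t, s.period, s.systole_fraction)
        # anterior = toward the probes = decreasing depth z
        return np.array([0.0, -s.midpoint_shift_amplitude * p])

    def displace(self, points0: np.ndarray, t: float) -> np.ndarray:
        """Map material points (t=0 positions) to their position at time t."""
        s = self.spec
        c = np.asarray(s.center)
        d = np.atleast_2d(points0) - c
        r = np.hypot(d[:, 0], d[:, 1])
        rp = self._mapped_radius(r, t)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(r > 1e-12, rp / np.maximum(r, 1e-12), 1.0)
        return c + d * scale[:, None] + self._shift(t)

    def frame_at(self, t: float, duration: float | None = None) -> PhantomFrame:
        if duration is not None and not (0 <= t <= duration):
            raise ValueError(f"t={t} outside simulated duration [0, {duration}]")
        pos = self.displace(self.positions0, t)
        r = self.radii(self.positions0)
        rp = self._mapped_radius(r, t)
        with np.errstate(invalid="ignore", divide="ignore"):
            strain = np.where(r > 1e-12, (rp - r) / np.maximum(r, 1e-12), 0.0)
        return PhantomFrame(
            time=t,
            scatterer_positions=pos,
            scatterer_amplitudes=self.amplitudes,
            true_displacement=pos - self.positions0,
            true_strain_circ=strain,
        )


def cardiac_waveform(t: float, period: float = 1.0, systole_fraction: float = 0.3) -> float:
    """Normalized distension waveform in [0, 1].

    Raised-cosine upstroke over the systolic fraction of the cycle, then
    exponential decay back toward end-diastole; p(0) = 0 and p(period) is
    close to 0 so one period contains two end-diastoles.
    """
    tau = np.mod(t, period)
    ts = systole_fraction * period
    if np.isscalar(tau):
        tau = float(tau)
        if tau <= ts:
            return 0.5 * (1 - np.cos(np.pi * tau / ts))
        return float(np.exp(-4.0 * (tau - ts) / (period - ts)))
    tau = np.asarray(tau)
    up = 0.5 * (1 - np.cos(np.pi * np.minimum(tau, ts) / ts))
    down = np.exp(-4.0 * (tau - ts) / (period - ts))
    return np.where(tau <= ts, up, down)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build the scatterer cloud; raises on degenerate geometry."""
    return Phantom(spec)


def kinematics_at(phantom: Phantom, t: float, duration: float | None = None) -> PhantomFrame:
    return phantom.frame_at(t, duration)


def ground_truth_strain(phantom: Phantom, mesh_points: np.ndarray, t: float):
    """Analytic circumferential and radial strain at material mesh points.

    ``mesh_points`` are t=0 positions, any shape (..., 2).  Points outside
    the wall/ILT annulus are flagged invalid.  Returns (e_cc, e_rr, valid).
    """
    s = phantom.spec
    pts = np.asarray(mesh_points, dtype=float)
    shape = pts.shape[:-1]
    flat = pts.reshape(-1, 2)
    r = phantom.radii(flat)
    rp = phantom._mapped_radius(r, t)
    e_cc = (rp - r) / np.maximum(r, 1e-12)
    # radial strain dr'/dr - 1 by finite difference of the map (one-sided
    # next to the lumen border so the stencil stays in the annulus)
    h = 1e-4
    r_lo = np.maximum(r - h, s.inner_border_radius)
    e_rr = (phantom._mapped_radius(r + h, t) - phantom._mapped_radius(r_lo, t)) / (r + h - r_lo) - 1.0
    valid = (r >= s.inner_border_radius - 1e-9) & (r <= s.outer_radius + 1e-9)
    return e_cc.reshape(shape), e_rr.reshape(shape), valid.reshape(shape)
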