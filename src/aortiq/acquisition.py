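"""Bistatic channel-data simulation for two curved-array probes.

Two C5-2v-like convex arrays fire diverging waves in an interleaved
schedule; on every transmit both probes receive, giving the four signal
pathways T1R1, T1R2, T2R1, T2R2 per frame.  The scattering model is
linear single scattering: every receive element records the sum over
scatterers of a Gaussian-modulated cosine delayed by the transmit and
receive times of flight, with 1/r receive spreading and no multiple
scattering, attenuation or aberration.

Transmit diverging waves use a virtual point source behind the array:
for steering angle a the source sits one curvature radius behind the
curvature centre along the steered axis, and t = 0 is referenced to the
wavefront reaching the nearest array element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.signal import butter, filtfilt

__all__ = [
    "RigidTransform",
    "TransducerGeometry",
    "AcquisitionConfig",
    "ChannelData",
    "pose_facing",
    "diverging_wave_delays",
    "interleave_schedule",
    "simulate_channel_data",
    "iq_demodulate",
    "add_channel_noise",
]


@dataclass
class RigidTransform:
    """Local -> world map  w = R(rotation) @ l + translation.

    rotation is the world angle of the probe axis; the probe's local +z
    (into tissue) maps to (sin rotation, cos rotation).
    """

    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return np.array([[c, s], [-s, c]])

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts) @ self.matrix.T + np.asarray(self.translation)

    def apply_vec(self, vec: np.ndarray) -> np.ndarray:
        return np.asarray(vec) @ self.matrix.T


def pose_facing(target, distance: float, angle: float) -> RigidTransform:
    """Pose with the array face centre at ``distance`` from ``target``,
    viewing direction at world angle ``angle`` (0 = straight down +z)."""
    u = np.array([np.sin(angle), np.cos(angle)])
    return RigidTransform(rotation=angle, translation=tuple(np.asarray(target) - distance * u))


@dataclass
class TransducerGeometry:
    """Convex array geometry.  Defaults approximate a C5-2v abdominal
    probe (element count and pitch are configuration, not vendor data)."""

    n_elements: int = 128
    pitch: float = 0.508  # arc length on the array surface, mm
    curvature_radius: float = 49.57  # mm
    center_frequency: float = 3.7e6  # Hz
    pose: RigidTransform = field(default_factory=RigidTransform)

    def __post_init__(self) -> None:
        if self.n_elements < 2:
            raise ValueError("need at least 2 elements")
        if self.pitch <= 0 or self.curvature_radius <= 0:
            raise ValueError("pitch and curvature radius must be positive")

    @property
    def element_angles(self) -> np.ndarray:
        idx = np.arange(self.n_elements) - (self.n_elements - 1) / 2
        return idx * self.pitch / self.curvature_radius

    def element_positions(self) -> np.ndarray:
        """World positions of the element centres, (E, 2) mm."""
        g = self.element_angles
        local = np.column_stack(
            [
                self.curvature_radius * np.sin(g),
                self.curvature_radius * (np.cos(g) - 1.0),
            ]
        )
        return self.pose.apply(local)

    def curvature_center(self) -> np.ndarray:
        return self.pose.apply(np.array([0.0, -self.curvature_radius]))

    def virtual_source(self, angle: float, source_offset: float | None = None) -> np.ndarray:
        """Virtual source for a diverging wave steered by ``angle``: one
        curvature radius (configurable) behind the curvature centre along
        the steered axis."""
        off = self.curvature_radius if source_offset is None else source_offset
        local = np.array(
            [-off * np.sin(angle), -self.curvature_radius - off * np.cos(angle)]
        )
        return self.pose.apply(local)


@dataclass
class AcquisitionConfig:
    steering_angles: np.ndarray = field(
        default_factory=lambda: np.deg2rad(np.linspace(-12, 12, 15))
    )
    frame_rate: float = 130.0  # Hz per pathway / compounded image
    speed_of_sound: float = 1540.0  # m/s
    sampling_frequency: float = 4 * 3.7e6  # Hz
    pulse_cycles: int = 2
    fractional_bandwidth: float = 0.6
    inter_probe_angle: float = np.deg2rad(55.0)
    duration: float = 1.0  # s
    prf_limit: float = 12_000.0  # Hz
    noise_snr_db: float | None = 0.0

    def __post_init__(self) -> None:
        a = np.asarray(self.steering_angles, dtype=float)
        if not np.allclose(a + a[::-1], 0.0, atol=1e-9):
            raise ValueError("steering angles must be symmetric about 0")
        self.steering_angles = a

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration))

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def wavelength(self) -> float:
        """mm at the configured speed of sound and 3.7 MHz-class centre
        frequency of the arrays (set per-geometry; helper uses fs/4)."""
        return self.speed_of_sound / (self.sampling_frequency / 4) * 1e3


@dataclass
class ChannelData:
    """Per-pathway channel data: samples[frame, angle, element, sample]."""

    samples: np.ndarray
    tx_aperture: int
    rx_aperture: int
    t_start: float  # s, time of sample 0 (same for every angle)
    sampling_frequency: float
    angles: np.ndarray
    frame_times: np.ndarray
    center_frequency: float
    is_iq: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite channel samples")


def gauss_pulse_alpha(f0: float, bandwidth: float) -> float:
    """Envelope coefficient a in exp(-a t^2) for a Gaussian pulse with the
    given -6 dB fractional bandwidth."""
    return (np.pi * f0 * bandwidth) ** 2 / (4.0 * np.log(10 ** (6 / 20)))


def diverging_wave_delays(
    geom: TransducerGeometry, angle: float, points: np.ndarray, c: float = 1540.0
) -> np.ndarray:
    """Transmit delay (s) of the steered diverging wavefront at world
    ``points`` (mm), zero-referenced to the wave leaving the array."""
    src = geom.virtual_source(angle)
    el = geom.element_positions()
    offset = np.min(np.linalg.norm(el - src, axis=1))
    pts = np.atleast_2d(points)
    d = np.linalg.norm(pts - src, axis=1)
    return (d - offset) * 1e-3 / c


def interleave_schedule(cfg: AcquisitionConfig) -> list[dict]:
    """Alternating T1/T2 transmit events; each transducer completes its
    full steering set at the frame rate and both probes receive on every
    event."""
    n_ang = len(cfg.steering_angles)
    prf = cfg.frame_rate * 2 * n_ang
    if prf > cfg.prf_limit:
        raise ValueError(f"required PRF {prf:.0f} Hz exceeds limit {cfg.prf_limit:.0f} Hz")
    events = []
    dt = 1.0 / prf
    for f in range(cfg.n_frames):
        t0 = f / cfg.frame_rate
        k = 0
        for a in range(n_ang):
            for tx in (0, 1):
                events.append(
                    {
                        "time": t0 + k * dt,
                        "frame": f,
                        "tx": tx,
                        "angle_index": a,
                        "rx": (0, 1),
                    }
                )
                k += 1
    return events


@njit(cache=True, fastmath=True)
def _simulate_rx(
    out,  # (E, S) float64, accumulated in place
    scat,  # (N, 2) mm
    amps,  # (N,)
    el,  # (E, 2) mm
    src,  # (2,) mm
    src_offset_mm,  # scalar
    t_start,  # s
    fs,
    c_mm_s,  # speed of sound in mm/s
    f0,
    alpha,  # envelope coefficient, 1/s^2
    half_window,  # samples
):
    n_scat = scat.shape[0]
    n_el = el.shape[0]
    n_s = out.shape[1]
    two_pi_f0 = 2.0 * np.pi * f0
    for i in range(n_scat):
        a = amps[i]
        if a == 0.0:
            continue
        dx = scat[i, 0] - src[0]
        dz = scat[i, 1] - src[1]
        tau_tx = (np.sqrt(dx * dx + dz * dz) - src_offset_mm) / c_mm_s
        for e in range(n_el):
            rx = scat[i, 0] - el[e, 0]
            rz = scat[i, 1] - el[e, 1]
            r = np.sqrt(rx * rx + rz * rz)
            tau = tau_tx + r / c_mm_s
            amp = a / max(r, 1.0)
            k0 = (tau - t_start) * fs
            kc = int(np.floor(k0))
            lo = kc - half_window
            hi = kc + half_window + 1
            if hi <= 0 or lo >= n_s:
                continue
            if lo < 0:
                lo = 0
            if hi > n_s:
                hi = n_s
            for k in range(lo, hi):
                dt = k / fs + t_start - tau
                out[e, k] += amp * np.cos(two_pi_f0 * dt) * np.exp(-alpha * dt * dt)
    return out


def _sample_window(field_bbox, geoms, cfg: AcquisitionConfig) -> tuple[float, int]:
    """Common sample window (t_start, n_samples) covering every
    scatterer-element path for all probes and angles."""
    (x0, x1), (z0, z1) = field_bbox
    corners = np.array([[x0, z0], [x0, z1], [x1, z0], [x1, z1]])
    c_mm = cfg.speed_of_sound * 1e3
    tmin, tmax = np.inf, -np.inf
    for g in geoms:
        el = g.element_positions()
        for ang in cfg.steering_angles:
            src = g.virtual_source(ang)
            off = np.min(np.linalg.norm(el - src, axis=1))
            for p in corners:
                tau_tx = (np.linalg.norm(p - src) - off) / c_mm
                d = np.linalg.norm(el - p, axis=1) / c_mm
                tmin = min(tmin, tau_tx + d.min())
                tmax = max(tmax, tau_tx + d.max())
    alpha = gauss_pulse_alpha(g.center_frequency, cfg.fractional_bandwidth)
    t_pulse = np.sqrt(np.log(1e4) / alpha)
    t_start = tmin - 2 * t_pulse
    n = int(np.ceil((tmax + 2 * t_pulse - t_start) * cfg.sampling_frequency)) + 1
    return t_start, n


def simulate_channel_data(
    phantom,
    tx: TransducerGeometry,
    rx: TransducerGeometry,
    cfg: AcquisitionConfig,
    tx_id: int = 0,
    rx_id: int = 0,
    field_bbox=None,
    sample_window=None,
) -> ChannelData:
    """Single-scattering channel data for one tx/rx pathway.

    Scatterers are sampled frame-synchronously (one phantom state per
    frame, shared by all steering angles of that frame).
    """
    if field_bbox is None:
        s = phantom.spec
        cx, cz = s.center
        fx, fz = s.field_size
        field_bbox = ((cx - fx / 2, cx + fx / 2), (cz - fz / 2, cz + fz / 2))
    if sample_window is None:
        t_start, n_s = _sample_window(field_bbox, [tx, rx], cfg)
    else:
        t_start, n_s = sample_window
    c_mm = cfg.speed_of_sound * 1e3
    alpha = gauss_pulse_alpha(tx.center_frequency, cfg.fractional_bandwidth)
    t_pulse = np.sqrt(np.log(1e4) / alpha)
    half_window = int(np.ceil(t_pulse * cfg.sampling_frequency))
    el = rx.element_positions()
    times = cfg.frame_times()
    n_ang = len(cfg.steering_angles)
    out = np.zeros((len(times), n_ang, rx.n_elements, n_s))
    for f, t in enumerate(times):
        fr = phantom.frame_at(t)
        scat = np.ascontiguousarray(fr.scatterer_positions)
        amps = np.ascontiguousarray(fr.scatterer_amplitudes)
        for a, ang in enumerate(cfg.steering_angles):
            src = tx.virtual_source(ang)
            off = float(np.min(np.linalg.norm(tx.element_positions() - src, axis=1)))
            _simulate_rx(
                out[f, a],
                scat,
                amps,
                el,
                src,
                off,
                t_start,
                cfg.sampling_frequency,
                c_mm,
                tx.center_frequency,
                alpha,
                half_window,
            )
    return ChannelData(
        samples=out,
        tx_aperture=tx_id,
        rx_aperture=rx_id,
        t_start=t_start,
        sampling_frequency=cfg.sampling_frequency,
        angles=np.asarray(cfg.steering_angles),
        frame_times=times,
        center_frequency=tx.center_frequency,
    )


def add_channel_noise(data: ChannelData, snr_db: float, rng: np.random.Generator) -> ChannelData:
    """Additive white Gaussian channel noise at the given SNR relative to
    the RMS of the pathway's signal."""
    rms = float(np.sqrt(np.mean(data.samples**2)))
    if rms == 0:
        return data
    sigma = rms / 10 ** (snr_db / 20)
    data.samples = data.samples + rng.normal(0.0, sigma, data.samples.shape)
    return data


def iq_demodulate(data: ChannelData) -> ChannelData:
    """Complex baseband conversion: mix down at the centre frequency
    (absolute time reference) and low-pass with a zero-phase Butterworth."""
    if data.is_iq:
        return data
    fs, f0 = data.sampling_frequency, data.center_frequency
    n_s = data.samples.shape[-1]
    t = data.t_start + np.arange(n_s) / fs
    carrier = np.exp(-2j * np.pi * f0 * t)
    iq = data.samples * carrier
    b, a = butter(4, 0.3)  # cutoff 0.3 * Nyquist; passes the 60% band
    iq = filtfilt(b, a, iq, axis=-1) * 2.0
    return ChannelData(
        samples=iq.astype(np.complex64),
        tx_aperture=data.tx_aperture,
        rx_aperture=data.rx_aperture,
        t_start=data.t_start,
        sampling_frequency=fs,
        angles=data.angles,
        frame_times=data.frame_times,
        center_frequency=f0,
        is_iq=True,
    )
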