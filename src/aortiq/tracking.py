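"""Coarse-to-fine 2-D block matching on beamformed IQ frames.

Displacements between consecutive frames are estimated per pathway on
that pathway's sector grid with complex normalized cross-correlation
(NCC): a coarse kernel/search finds the integer-pixel lag, a fine kernel
refines it, the axial sub-pixel shift comes from the zero-phase crossing
of the complex correlation and the lateral sub-pixel shift from 3-point
parabolic interpolation of the correlation magnitude.  The whole search
is evaluated with box-filter sums so every pixel of the grid is
estimated at once, which is what makes the printed 11 x 11-pixel median
filter directly applicable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates, median_filter, uniform_filter
from scipy.signal import find_peaks

from .beamform import GridSpec, IQImage

__all__ = [
    "TrackingConfig",
    "DisplacementField",
    "block_match",
    "median_filter_disp",
    "sample_field",
    "track_mesh",
    "select_cardiac_frames",
]


@dataclass
class TrackingConfig:
    """Kernel / search / filter extents in mm (axial, lateral)."""

    coarse_kernel: tuple[float, float] = (2.6, 5.2)
    fine_kernel: tuple[float, float] = (0.8, 2.4)
    coarse_search: tuple[float, float] = (3.0, 5.7)
    fine_search: tuple[float, float] = (1.0, 2.85)
    median_filter_mm: tuple[float, float] = (0.6, 5.2)

    def __post_init__(self) -> None:
        for a, b in ((self.fine_kernel, self.coarse_kernel), (self.fine_search, self.coarse_search)):
            if a[0] > b[0] + 1e-9 or a[1] > b[1] + 1e-9:
                raise ValueError("fine extents must not exceed coarse extents")
        for k, s in ((self.coarse_kernel, self.coarse_search), (self.fine_kernel, self.fine_search)):
            if s[0] < k[0] or s[1] < k[1]:
                raise ValueError("search must be at least as large as the kernel")

    def px(self, mm_pair, ax_spacing: float, lat_spacing: float) -> tuple[int, int]:
        def odd(v):
            k = max(int(round(v)), 1)
            return k if k % 2 else k + 1

        return odd(mm_pair[0] / ax_spacing), odd(mm_pair[1] / lat_spacing)

    def lags(self, kernel_mm, search_mm, ax_spacing: float, lat_spacing: float) -> tuple[int, int]:
        la = max(int(np.ceil((search_mm[0] - kernel_mm[0]) / 2 / ax_spacing)), 1)
        ll = max(int(np.ceil((search_mm[1] - kernel_mm[1]) / 2 / lat_spacing)), 1)
        return la, ll


@dataclass
class DisplacementField:
    u_ax: np.ndarray  # mm on the grid
    u_lat: np.ndarray  # mm
    max_cc: np.ndarray  # [0, 1]
    grid: GridSpec
    pathway: str = ""
    pair_index: int = 0


def _shift2(img: np.ndarray, di: int, dj: int) -> np.ndarray:
    """Integer shift with zero fill (img[i, j] -> img[i - di, j - dj])."""
    out = np.zeros_like(img)
    H, W = img.shape
    si = slice(max(di, 0), H + min(di, 0))
    sj = slice(max(dj, 0), W + min(dj, 0))
    ti = slice(max(-di, 0), H + min(-di, 0))
    tj = slice(max(-dj, 0), W + min(-dj, 0))
    out[si, sj] = img[ti, tj]
    return out


def _box(img: np.ndarray, size) -> np.ndarray:
    if np.iscomplexobj(img):
        return uniform_filter(img.real, size, mode="constant") + 1j * uniform_filter(
            img.imag, size, mode="constant"
        )
    return uniform_filter(img, size, mode="constant")


def _ncc_stack(f1: np.ndarray, f2: np.ndarray, kernel_px, lags_ax, lags_lat) -> np.ndarray:
    """Complex NCC maps for every integer lag: shape (n_ax_lags, n_lat_lags, H, W)."""
    f1 = f1.astype(np.complex64, copy=False)
    f2 = f2.astype(np.complex64, copy=False)
    e1 = _box((f1.real**2 + f1.imag**2).astype(np.float32), kernel_px)
    out = np.empty((len(lags_ax), len(lags_lat)) + f1.shape, dtype=np.complex64)
    for ia, da in enumerate(lags_ax):
        for il, dl in enumerate(lags_lat):
            f2s = _shift2(f2, -da, -dl)  # sample f2 at (i + da, j + dl)
            num = _box(f1 * np.conj(f2s), kernel_px)
            e2 = _box((f2s.real**2 + f2s.imag**2).astype(np.float32), kernel_px)
            den = np.sqrt(np.maximum(e1 * e2, 0.0))
            out[ia, il] = num / np.maximum(den, 1e-30)
    return out


def block_match(f1: IQImage, f2: IQImage, cfg: TrackingConfig, pair_index: int = 0) -> DisplacementField:
    """Two-stage complex-NCC block matching between consecutive frames."""
    if f1.grid != f2.grid:
        raise ValueError("frames must share a grid")
    g = f1.grid
    ax_sp = g.axial_spacing
    lat_sp_rows = np.atleast_1d(g.lateral_spacing())
    lat_sp = float(np.median(lat_sp_rows))
    a, b = f1.values, f2.values
    ck = cfg.px(cfg.coarse_kernel, ax_sp, lat_sp)
    fk = cfg.px(cfg.fine_kernel, ax_sp, lat_sp)
    if ck[0] > a.shape[0] or ck[1] > a.shape[1]:
        raise ValueError("kernel exceeds image size")
    cla, cll = cfg.lags(cfg.coarse_kernel, cfg.coarse_search, ax_sp, lat_sp)
    fla, fll = cfg.lags(cfg.fine_kernel, cfg.fine_search, ax_sp, lat_sp)

    # stage 1: coarse integer lag, on a decimated pixel set (the integer
    # lag field is piecewise smooth; the fine stage re-estimates anyway)
    lags_a = np.arange(-cla, cla + 1)
    lags_l = np.arange(-cll, cll + 1)
    dec = (2, 1)
    ad, bd = a[:: dec[0], :: dec[1]], b[:: dec[0], :: dec[1]]
    ckd = (max(ck[0] // dec[0], 1), max(ck[1] // dec[1], 1))
    # decimated axial lags: search the same mm range on the coarse grid
    lags_ad = np.unique(lags_a // dec[0]) if dec[0] > 1 else lags_a
    rho_c = np.abs(_ncc_stack(ad, bd, ckd, lags_ad, lags_l))
    flat = rho_c.reshape(len(lags_ad) * len(lags_l), *ad.shape)
    am = flat.argmax(axis=0)
    c_ax_d = lags_ad[am // len(lags_l)] * dec[0]
    c_lat_d = lags_l[am % len(lags_l)]
    c_ax = np.repeat(c_ax_d, dec[0], axis=0)[: a.shape[0]]
    c_lat = np.repeat(c_lat_d, dec[0], axis=0)[: a.shape[0]]

    # stage 2: fine kernel over the lag range actually selected by the
    # coarse stage (expanded by the fine search), constrained per pixel
    fla_eff = fla + dec[0]  # absorb coarse decimation error
    lags_a2 = np.arange(
        max(c_ax.min() - fla_eff, -cla - fla_eff), min(c_ax.max() + fla_eff, cla + fla_eff) + 1
    )
    lags_l2 = np.arange(
        max(c_lat.min() - fll, -cll - fll), min(c_lat.max() + fll, cll + fll) + 1
    )
    fla = fla_eff
    rho_f = _ncc_stack(a, b, fk, lags_a2, lags_l2)
    mag = np.abs(rho_f)
    best = np.full(a.shape, -1.0)
    bi = np.zeros(a.shape, dtype=np.intp)
    bj = np.zeros(a.shape, dtype=np.intp)
    for ia, da in enumerate(lags_a2):
        ok_a = np.abs(da - c_ax) <= fla
        if not ok_a.any():
            continue
        for il, dl in enumerate(lags_l2):
            sel = ok_a & (np.abs(dl - c_lat) <= fll) & (mag[ia, il] > best)
            if sel.any():
                best[sel] = mag[ia, il][sel]
                bi[sel] = ia
                bj[sel] = il

    II, JJ = np.meshgrid(np.arange(a.shape[0]), np.arange(a.shape[1]), indexing="ij")
    peak = rho_f[bi, bj, II, JJ]
    lag_ax = lags_a2[bi].astype(float)
    lag_lat = lags_l2[bj].astype(float)
    max_cc = np.minimum(np.abs(peak), 1.0)
    exact = max_cc >= 1.0 - 1e-6  # perfect match: no refinement needed

    # axial sub-pixel: zero crossing of the correlation phase; the local
    # phase-per-lag slope is estimated from the neighbouring lags, which
    # self-calibrates the carrier of any pathway geometry
    bip = np.clip(bi + 1, 0, len(lags_a2) - 1)
    bim = np.clip(bi - 1, 0, len(lags_a2) - 1)
    # single-lag phase differences (the two-lag spread can sit exactly on
    # the +/-pi wrap for quarter-wave axial sampling)
    rp = rho_f[bip, bj, II, JJ]
    rm = rho_f[bim, bj, II, JJ]
    slope = 0.5 * (np.angle(rp * np.conj(peak)) + np.angle(peak * np.conj(rm)))
    phi = np.angle(peak)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_ax = np.where((np.abs(slope) > 1e-6) & ~exact, -phi / slope, 0.0)
    d_ax = np.clip(d_ax, -1.0, 1.0)

    # lateral sub-pixel: parabolic fit on |rho|
    bjp = np.clip(bj + 1, 0, len(lags_l2) - 1)
    bjm = np.clip(bj - 1, 0, len(lags_l2) - 1)
    m0 = max_cc
    mp = np.abs(rho_f[bi, bjp, II, JJ])
    mm = np.abs(rho_f[bi, bjm, II, JJ])
    den = mm - 2 * m0 + mp
    with np.errstate(invalid="ignore", divide="ignore"):
        d_lat = np.where((den < -1e-9) & ~exact, 0.5 * (mm - mp) / den, 0.0)
    d_lat = np.clip(d_lat, -0.5, 0.5)

    u_ax = (lag_ax + d_ax) * ax_sp
    lat_scale = lat_sp_rows[:, None] if g.kind == "sector" else lat_sp
    u_lat = (lag_lat + d_lat) * lat_scale
    # zero-variance kernels carry no information
    dead = max_cc == 0
    u_ax[dead] = 0.0
    u_lat[dead] = 0.0
    return DisplacementField(
        u_ax=u_ax, u_lat=u_lat, max_cc=max_cc, grid=g, pathway=f1.pathway, pair_index=pair_index
    )


def median_filter_disp(fld: DisplacementField, size_px=(11, 11)) -> DisplacementField:
    """Median filter on both displacement components; max_cc untouched."""
    return DisplacementField(
        u_ax=median_filter(fld.u_ax, size=size_px, mode="nearest"),
        u_lat=median_filter(fld.u_lat, size=size_px, mode="nearest"),
        max_cc=fld.max_cc,
        grid=fld.grid,
        pathway=fld.pathway,
        pair_index=fld.pair_index,
    )


def sample_field(grid: GridSpec, values: np.ndarray, points: np.ndarray, warn: bool = True) -> np.ndarray:
    """Bilinear sample of a grid field at world points (nearest-valid
    extrapolation outside the support, with a warning)."""
    idx = grid.index_coords(points)
    i = idx[..., 0]
    j = idx[..., 1]
    if warn and (
        np.any(i < -0.5)
        or np.any(i > values.shape[0] - 0.5)
        or np.any(j < -0.5)
        or np.any(j > values.shape[1] - 0.5)
    ):
        warnings.warn("points outside displacement support; nearest-valid extrapolation")
    coords = np.stack([i.ravel(), j.ravel()])
    out = map_coordinates(values, coords, order=1, mode="nearest")
    return out.reshape(np.asarray(points).shape[:-1])


def track_mesh(points0: np.ndarray, displacement_samplers) -> np.ndarray:
    """Accumulate frame-to-frame displacements through time.

    ``displacement_samplers`` is a sequence of callables, one per frame
    pair, mapping current world positions (..., 2) to displacement
    vectors (..., 2) in mm.  Returns coordinates with a leading frame
    axis of length ``len(samplers) + 1``.
    """
    coords = [np.asarray(points0, dtype=float)]
    for sampler in displacement_samplers:
        u = sampler(coords[-1])
        coords.append(coords[-1] + u)
    return np.stack(coords)


def select_cardiac_frames(
    radius_series: np.ndarray, prominence: float | None = None, detrend: bool = False
) -> tuple[int, int, int]:
    """(end-diastole 1, end-diastole 2, end-systole) from the mean inner
    radius waveform (the M-mode proxy for lumen diameter).

    ``prominence`` (fraction of the waveform range) suppresses spurious
    minima from tracking noise; ``detrend`` removes a linear trend (drift)
    before looking for the minima.
    """
    r = np.asarray(radius_series, dtype=float)
    if np.ptp(r) < 1e-12:
        raise ValueError("no cardiac cycle found (constant radius)")
    w = r.copy()
    if detrend:
        x = np.arange(len(w), dtype=float)
        w = w - np.polyval(np.polyfit(x, w, 1), x)
    # local minima, allowing the endpoints to act as end-diastoles
    pad = np.concatenate([[w[0] + np.ptp(w)], w, [w[-1] + np.ptp(w)]])
    kw = {"prominence": prominence * np.ptp(w)} if prominence else {}
    mins, _ = find_peaks(-pad, **kw)
    mins = mins - 1
    if len(mins) < 2:
        raise ValueError("no full cardiac cycle found")
    ed1, ed2 = int(mins[0]), int(mins[1])
    es = ed1 + int(np.argmax(w[ed1 : ed2 + 1]))
    return ed1, ed2, es
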