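import numpy as np
import pytest
from scipy.ndimage import fourier_shift, gaussian_filter

from aortiq.beamform import GridSpec, IQImage
from aortiq.tracking import (
    TrackingConfig,
    block_match,
    median_filter_disp,
    sample_field,
    select_cardiac_frames,
    track_mesh,
)


def make_grid(nr=260, ntheta=90):
    return GridSpec(
        kind="sector",
        apex=(0.0, -49.57),
        axis_angle=0.0,
        start_radius=80.0,
        dr=0.052,
        nr=nr,
        theta0=-0.23,
        dtheta=0.00512,
        ntheta=ntheta,
    )


def speckle_iq(grid, seed=0):
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(grid.shape) + 1j * rng.standard_normal(grid.shape)
    f = gaussian_filter(f.real, (2, 1)) + 1j * gaussian_filter(f.imag, (2, 1))
    carrier = np.exp(1j * 2 * np.pi * 0.25 * np.arange(grid.shape[0]))[:, None]
    return (f * carrier).astype(np.complex128)


@pytest.fixture(scope="module")
def frame_pair():
    grid = make_grid()
    v = speckle_iq(grid)
    return grid, v


def cfg():
    return TrackingConfig(coarse_search=(3.6, 6.5))


def test_identical_frames_zero_displacement_unit_cc(frame_pair):
    grid, v = frame_pair
    f = IQImage(values=v, grid=grid, pathway="t")
    fld = block_match(f, f, cfg())
    assert np.all(fld.u_ax == 0)
    assert np.all(fld.u_lat == 0)
    assert np.all(fld.max_cc >= 1 - 1e-6)


def test_integer_shift_recovered_exactly(frame_pair):
    grid, v = frame_pair
    f1 = IQImage(values=v, grid=grid, pathway="t")
    f2 = IQImage(values=np.roll(v, 6, axis=0), grid=grid, pathway="t")
    fld = block_match(f1, f2, cfg())
    interior = fld.u_ax[40:-40, 10:-10]
    assert np.allclose(interior, 6 * grid.dr)


def test_subpixel_shift_bias(frame_pair):
    grid, v = frame_pair
    v2 = np.fft.ifft2(fourier_shift(np.fft.fft2(v), (0.3, 0)))
    f1 = IQImage(values=v, grid=grid, pathway="t")
    f2 = IQImage(values=v2, grid=grid, pathway="t")
    fld = block_match(f1, f2, cfg())
    err_px = fld.u_ax[40:-40, 10:-10] / grid.dr - 0.3
    assert abs(np.median(err_px)) < 0.05


def test_subpixel_bias_at_20db_snr(frame_pair):
    grid, v = frame_pair
    rng = np.random.default_rng(9)
    v2 = np.fft.ifft2(fourier_shift(np.fft.fft2(v), (0.3, 0)))
    sig = np.sqrt(np.mean(np.abs(v) ** 2))
    amp = sig / 10 ** (20 / 20) / np.sqrt(2)

    def noisy(x):
        return x + amp * (rng.standard_normal(x.shape) + 1j * rng.standard_normal(x.shape))

    f1 = IQImage(values=noisy(v), grid=grid, pathway="t")
    f2 = IQImage(values=noisy(v2), grid=grid, pathway="t")
    fld = block_match(f1, f2, cfg())
    err_px = fld.u_ax[40:-40, 10:-10] / grid.dr - 0.3
    assert abs(np.median(err_px)) < 0.05


def test_max_cc_bounded(frame_pair):
    grid, v = frame_pair
    rng = np.random.default_rng(1)
    f1 = IQImage(values=v, grid=grid, pathway="t")
    f2 = IQImage(
        values=(rng.standard_normal(grid.shape) + 1j * rng.standard_normal(grid.shape)),
        grid=grid,
        pathway="t",
    )
    fld = block_match(f1, f2, cfg())
    assert fld.max_cc.max() <= 1.0
    assert fld.max_cc.min() >= 0.0


def test_flat_kernel_zero_cc(frame_pair):
    grid, _ = frame_pair
    z = np.zeros(grid.shape, complex)
    f = IQImage(values=z, grid=grid, pathway="t")
    fld = block_match(f, f, cfg())
    assert np.all(fld.u_ax == 0)
    assert np.all(fld.max_cc == 0)


def test_kernel_exceeding_image_rejected():
    grid = make_grid(nr=30, ntheta=8)
    v = speckle_iq(grid, 2)
    f = IQImage(values=v, grid=grid, pathway="t")
    with pytest.raises(ValueError):
        block_match(f, f, cfg())


def test_fine_extents_must_not_exceed_coarse():
    with pytest.raises(ValueError):
        TrackingConfig(fine_kernel=(3.0, 6.0))
    with pytest.raises(ValueError):
        TrackingConfig(coarse_search=(2.0, 5.7))


def test_median_filter_properties(frame_pair):
    grid, v = frame_pair
    from aortiq.tracking import DisplacementField

    const = np.full(grid.shape, 0.25)
    cc = np.ones(grid.shape)
    fld = DisplacementField(u_ax=const.copy(), u_lat=const.copy(), max_cc=cc, grid=grid)
    out = median_filter_disp(fld)
    assert np.array_equal(out.u_ax, const)
    # single-pixel outlier removed exactly
    spiked = const.copy()
    spiked[50, 40] = 5.0
    fld2 = DisplacementField(u_ax=spiked, u_lat=const.copy(), max_cc=cc, grid=grid)
    out2 = median_filter_disp(fld2)
    assert np.array_equal(out2.u_ax, const)
    assert np.array_equal(out2.max_cc, cc)  # untouched
    # idempotent on a constant-plus-step field
    step = np.where(np.arange(grid.shape[1])[None, :] > 40, 1.0, 0.0) + const
    fld3 = DisplacementField(u_ax=step, u_lat=const.copy(), max_cc=cc, grid=grid)
    once = median_filter_disp(fld3)
    twice = median_filter_disp(once)
    assert np.array_equal(once.u_ax, twice.u_ax)


def test_track_mesh_accumulation():
    pts = np.array([[[0.0, 45.0], [1.0, 45.0]]])
    zero = lambda p: np.zeros_like(p)
    coords = track_mesh(pts, [zero] * 5)
    assert np.allclose(coords, pts[None])
    step = lambda p: np.tile([0.0, 0.1], p.shape[:-1] + (1,))
    coords = track_mesh(pts, [step] * 10)
    assert np.allclose(coords[-1][..., 1] - pts[..., 1], 1.0, atol=1e-9)


def test_sample_field_bilinear_and_extrapolation(frame_pair):
    grid, _ = frame_pair
    vals = np.fromfunction(lambda i, j: i * 0.1 + j * 0.05, grid.shape)
    pts = grid.world_points()[10:12, 20:22]
    out = sample_field(grid, vals, pts, warn=False)
    assert np.allclose(out, vals[10:12, 20:22], atol=1e-9)
    with pytest.warns(UserWarning):
        sample_field(grid, vals, np.array([[0.0, 0.0]]))


def test_wall_tracks_better_than_lumen_on_phantom():
    """Speckle correlation confidence is higher in the echogenic wall
    than in the near-anechoic lumen."""
    from dataclasses import replace

    from aortiq.acquisition import add_channel_noise, iq_demodulate, simulate_channel_data
    from aortiq.beamform import das_reconstruct, make_sector_grids
    from aortiq.pipeline import _geometry, tiny_config
    from aortiq.phantom import make_phantom

    cfg = tiny_config(seed=4)
    cfg.acquisition = replace(cfg.acquisition, duration=2 / cfg.acquisition.frame_rate)
    phantom = make_phantom(cfg.phantom)
    g = _geometry(cfg, 0.0)
    cd = simulate_channel_data(phantom, g, g, cfg.acquisition)
    cd = add_channel_noise(cd, 0.0, np.random.default_rng(0))
    iq = iq_demodulate(cd)
    grid = make_sector_grids(g, g, cfg.phantom.center, cfg.phantom.outer_radius, cfg.wavelength)[0]
    f0 = das_reconstruct(iq, grid, g, g, cfg.acquisition, frame=0)
    f1 = das_reconstruct(iq, grid, g, g, cfg.acquisition, frame=1)
    fld = block_match(f0, f1, TrackingConfig(coarse_search=(3.6, 6.5)))
    rad = np.linalg.norm(grid.world_points() - np.asarray(cfg.phantom.center), axis=-1)
    wall = (rad >= cfg.phantom.lumen_radius + 0.3) & (rad <= cfg.phantom.outer_radius - 0.3)
    lumen = rad < cfg.phantom.lumen_radius - 1.0
    assert fld.max_cc[wall].mean() > fld.max_cc[lumen].mean()


def test_cardiac_frame_selection():
    t = np.linspace(0, 1, 40)
    r = 10 + np.sin(np.pi * t) ** 2
    ed1, ed2, es = select_cardiac_frames(r)
    assert (ed1, ed2) == (0, 39)
    assert es == pytest.approx(20, abs=1)
    with pytest.raises(ValueError):
        select_cardiac_frames(np.full(30, 10.0))
    # two cycles: successive minima, not first and third
    t2 = np.linspace(0, 2, 80, endpoint=False)
    r2 = 10 + np.sin(np.pi * t2) ** 2
    ed1, ed2, es = select_cardiac_frames(r2)
    assert ed1 == 0
    assert ed2 == pytest.approx(40, abs=1)
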