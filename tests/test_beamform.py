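import math

import numpy as np
import pytest

from aortiq.acquisition import (
    AcquisitionConfig,
    TransducerGeometry,
    add_channel_noise,
    iq_demodulate,
    pose_facing,
    simulate_channel_data,
)
from aortiq.beamform import (
    GridSpec,
    IQImage,
    bmode_render,
    cartesian_grid,
    compound_bistatic,
    das_reconstruct,
    envelope,
    localize_probe,
    make_sector_grids,
    virtual_probe,
)
from tests.conftest import PointCloud


def brute_force_das(data, grid, tx_geom, rx_geom, cfg, f_number=1.5):
    """Independent per-pixel delay-and-sum oracle (plain Python loops)."""
    c = cfg.speed_of_sound * 1e3
    f0 = data.center_frequency
    fs = data.sampling_frequency
    el = rx_geom.element_positions()
    rc = rx_geom.curvature_center()
    Rr = rx_geom.curvature_radius
    pts = grid.world_points()
    out = np.zeros(grid.shape, dtype=complex)
    for a, ang in enumerate(data.angles):
        src = tx_geom.virtual_source(ang)
        off = min(math.dist(e, src) for e in tx_geom.element_positions())
        for i in range(grid.shape[0]):
            for j in range(grid.shape[1]):
                x, z = pts[i, j]
                tau_tx = (math.dist((x, z), src) - off) / c
                rad = math.dist((x, z), rc)
                depth = rad - Rr
                if depth <= 0:
                    continue
                half_ap = depth / (2 * f_number)
                acc = 0.0j
                for e in range(len(el)):
                    r = math.dist((x, z), el[e])
                    cosd = ((el[e][0] - rc[0]) * (x - rc[0]) + (el[e][1] - rc[1]) * (z - rc[1])) / (
                        Rr * rad
                    )
                    arc = Rr * math.acos(max(-1.0, min(1.0, cosd)))
                    if arc >= half_ap:
                        continue
                    w = 0.5 + 0.5 * math.cos(math.pi * arc / half_ap)
                    tau = tau_tx + r / c
                    k = (tau - data.t_start) * fs
                    k0 = int(math.floor(k))
                    if k0 < 0 or k0 + 1 >= data.samples.shape[-1]:
                        continue
                    frac = k - k0
                    s = data.samples[0, a, e, k0] * (1 - frac) + data.samples[0, a, e, k0 + 1] * frac
                    acc += w * complex(s) * complex(math.cos(2 * math.pi * f0 * tau), math.sin(2 * math.pi * f0 * tau))
                out[i, j] += acc
    return out


def test_das_matches_brute_force_oracle(three_scatterers, small_probe, small_cfg):
    grid = cartesian_grid((0, 45), 6.0, 6.0, 0.5)
    img = das_reconstruct(three_scatterers, grid, small_probe, small_probe, small_cfg)
    oracle = brute_force_das(three_scatterers, grid, small_probe, small_probe, small_cfg)
    err = np.linalg.norm(img.values - oracle) / np.linalg.norm(oracle)
    assert err < 1e-8


def test_all_zero_channel_data_gives_zero_image(small_probe, small_cfg):
    cloud = PointCloud(np.empty((0, 2)), np.empty(0))
    iq = iq_demodulate(simulate_channel_data(cloud, small_probe, small_probe, small_cfg))
    grid = cartesian_grid((0, 45), 6.0, 6.0, 0.5)
    img = das_reconstruct(iq, grid, small_probe, small_probe, small_cfg)
    assert np.all(img.values == 0)


def test_per_angle_sum_equals_full_reconstruction(three_scatterers, small_probe, small_cfg):
    grid = cartesian_grid((0, 45), 6.0, 6.0, 0.5)
    full = das_reconstruct(three_scatterers, grid, small_probe, small_probe, small_cfg)
    parts = sum(
        das_reconstruct(
            three_scatterers, grid, small_probe, small_probe, small_cfg, angle_indices=[a]
        ).values
        for a in range(3)
    )
    assert np.linalg.norm(full.values - parts) <= 1e-10 * np.linalg.norm(full.values)


def test_point_scatterer_localized_within_half_wavelength(small_probe, small_cfg):
    lam = 1540 / 3.7e6 * 1e3
    cloud = PointCloud([[1.0, 44.0]], [1.0])
    iq = iq_demodulate(simulate_channel_data(cloud, small_probe, small_probe, small_cfg))
    grid = cartesian_grid((1, 44), 6.0, 6.0, lam / 4)
    img = das_reconstruct(iq, grid, small_probe, small_probe, small_cfg)
    env = envelope(img)
    ij = np.unravel_index(env.argmax(), env.shape)
    peak = grid.world_points()[ij]
    assert np.linalg.norm(peak - [1.0, 44.0]) <= lam / 2


def test_bistatic_lateral_resolution_not_worse(small_cfg):
    """Lateral -6 dB width of a point between the probes: the compound is
    at least as narrow as either single pathway."""
    lam = 1540 / 3.7e6 * 1e3
    half = np.deg2rad(30.0)
    g1 = TransducerGeometry(n_elements=24, pose=pose_facing((0, 45), 45, -half))
    g2 = TransducerGeometry(n_elements=24, pose=pose_facing((0, 45), 45, +half))
    cloud = PointCloud([[0.0, 45.0]], [1.0], field=(16.0, 16.0))
    grid = cartesian_grid((0, 45), 8.0, 8.0, lam / 4)
    imgs = {}
    for name, (tx, rx) in {"11": (g1, g1), "22": (g2, g2), "12": (g1, g2), "21": (g2, g1)}.items():
        iq = iq_demodulate(simulate_channel_data(cloud, tx, rx, small_cfg))
        imgs[name] = das_reconstruct(iq, grid, tx, rx, small_cfg)
    comp = compound_bistatic(imgs["11"], imgs["22"], imgs["12"], imgs["21"])

    def lat_width(img):
        env = envelope(img)
        i, j = np.unravel_index(env.argmax(), env.shape)
        row = env[i]
        return np.sum(row >= env[i, j] / 2) * grid.dx

    assert lat_width(comp) <= min(lat_width(imgs["11"]), lat_width(imgs["22"])) + grid.dx


def test_compound_constant_and_symmetry():
    grid = cartesian_grid((0, 45), 4.0, 4.0, 0.5)
    c = np.full(grid.shape, 2.0 - 1.0j)
    mk = lambda v: IQImage(values=v, grid=grid, pathway="p")
    out = compound_bistatic(mk(c), mk(c), mk(c), mk(c))
    assert np.allclose(out.values, 3 * c)
    # trans-probe swap leaves the result unchanged
    a, b = np.full(grid.shape, 1 + 1j), np.full(grid.shape, 2 - 3j)
    o1 = compound_bistatic(mk(c), mk(c), mk(a), mk(b))
    o2 = compound_bistatic(mk(c), mk(c), mk(b), mk(a))
    assert np.array_equal(o1.values, o2.values)
    # antisymmetric trans pair with zero single-probe images cancels
    z = np.zeros(grid.shape, complex)
    o3 = compound_bistatic(mk(z), mk(z), mk(a), mk(-a))
    assert np.all(o3.values == 0)


def test_compound_grid_mismatch_rejected():
    g1 = cartesian_grid((0, 45), 4.0, 4.0, 0.5)
    g2 = cartesian_grid((0, 45), 4.0, 4.0, 0.25)
    i1 = IQImage(values=np.zeros(g1.shape, complex), grid=g1, pathway="a")
    i2 = IQImage(values=np.zeros(g2.shape, complex), grid=g2, pathway="b")
    with pytest.raises(ValueError):
        compound_bistatic(i1, i1, i1, i2)


def test_sector_grids_geometry():
    lam = 1540 / 3.7e6 * 1e3
    center = np.array([0.0, 45.0])
    g1 = TransducerGeometry(n_elements=24, pose=pose_facing(center, 45, 0.0))
    # degenerate: identical probes -> virtual grid equals the single grids
    ga, gb, gv = make_sector_grids(g1, g1, center, 10.0, lam)
    assert np.allclose(ga.apex, gv.apex)
    assert ga.axis_angle == pytest.approx(gv.axis_angle)
    # 60 degree inter-probe angle -> virtual axis bisects (30 deg from each)
    h = np.deg2rad(30.0)
    p1 = TransducerGeometry(n_elements=24, pose=pose_facing(center, 45, -h))
    p2 = TransducerGeometry(n_elements=24, pose=pose_facing(center, 45, +h))
    _, _, gtv = make_sector_grids(p1, p2, center, 10.0, lam)
    assert gtv.axis_angle == pytest.approx(0.0, abs=1e-12)
    assert abs(gtv.axis_angle - p1.pose.rotation) == pytest.approx(h)
    # axial spacing is lambda/8
    assert gtv.dr == pytest.approx(lam / 8)
    assert gtv.dr == pytest.approx(0.052, abs=1e-3)


def test_virtual_probe_midpoint():
    center = np.array([0.0, 45.0])
    h = np.deg2rad(25.0)
    p1 = TransducerGeometry(n_elements=24, pose=pose_facing(center, 45, -h))
    p2 = TransducerGeometry(n_elements=24, pose=pose_facing(center, 45, +h))
    v = virtual_probe(p1, p2)
    assert np.allclose(v.curvature_center(), (p1.curvature_center() + p2.curvature_center()) / 2)
    assert v.pose.rotation == pytest.approx(0.0, abs=1e-12)


def test_bmode_rendering():
    grid = cartesian_grid((0, 45), 4.0, 4.0, 0.5)
    vals = np.full(grid.shape, 1e-6 + 0j)
    vals[4, 4] = 1.0
    vals[2, 2] = 10 ** (-55 / 20)  # exactly at the clip point
    img = IQImage(values=vals, grid=grid, pathway="p")
    out = bmode_render(img, dynamic_range_db=55, alpha=1.3)
    assert out[4, 4] == 255
    assert out[2, 2] == 0
    # alpha = 1 reduces to plain log compression
    lin = bmode_render(img, dynamic_range_db=55, alpha=1.0)
    db = 20 * np.log10(np.abs(vals) / np.abs(vals).max())
    expect = np.round(255 * np.clip((db + 55) / 55, 0, 1)).astype(np.uint8)
    assert np.array_equal(lin, expect)


def test_bmode_all_zero_warns():
    grid = cartesian_grid((0, 45), 4.0, 4.0, 0.5)
    img = IQImage(values=np.zeros(grid.shape, complex), grid=grid, pathway="p")
    with pytest.warns(UserWarning):
        out = bmode_render(img)
    assert np.all(out == 0)


def test_probe_localization_recovers_pose(small_cfg):
    rng = np.random.default_rng(3)
    n = 250
    pts = np.column_stack([rng.uniform(-8, 8, n), rng.uniform(38, 52, n)])
    cloud = PointCloud(pts, np.abs(rng.standard_normal(n)), field=(20.0, 18.0))
    half = np.deg2rad(22.0)
    g1 = TransducerGeometry(n_elements=24, pose=pose_facing((0, 45), 45, -half))
    true_pose = pose_facing((0, 45), 45, +half)
    g2_true = TransducerGeometry(n_elements=24, pose=true_pose)
    cfg = AcquisitionConfig(
        steering_angles=np.array([0.0]), frame_rate=20.0, duration=1 / 20.0, noise_snr_db=None
    )
    d12 = iq_demodulate(simulate_channel_data(cloud, g1, g2_true, cfg, 0, 1))
    d21 = iq_demodulate(simulate_channel_data(cloud, g2_true, g1, cfg, 1, 0))
    # search from a nominal pose off by 2 degrees / 1.5 mm
    from aortiq.acquisition import RigidTransform

    nominal = TransducerGeometry(
        n_elements=24,
        pose=RigidTransform(
            rotation=true_pose.rotation + np.deg2rad(2.0),
            translation=(true_pose.translation[0] + 1.5, true_pose.translation[1] - 1.0),
        ),
    )
    pose = localize_probe(
        d12, d21, g1, nominal, cfg, roi_center=(0, 45), roi_size=10.0,
        rot_range=np.deg2rad(3.0), trans_range=2.0, n_steps=5, n_levels=3,
    )
    assert pose.success
    assert abs(pose.rotation - true_pose.rotation) < np.deg2rad(0.5)
    assert np.hypot(
        pose.translation[0] - true_pose.translation[0],
        pose.translation[1] - true_pose.translation[1],
    ) < 0.5


def test_probe_localization_fails_on_noise(small_cfg):
    rng = np.random.default_rng(0)
    half = np.deg2rad(22.0)
    g1 = TransducerGeometry(n_elements=16, pose=pose_facing((0, 45), 45, -half))
    g2 = TransducerGeometry(n_elements=16, pose=pose_facing((0, 45), 45, +half))
    cfg = AcquisitionConfig(
        steering_angles=np.array([0.0]), frame_rate=20.0, duration=1 / 20.0, noise_snr_db=None
    )
    cloud = PointCloud(np.empty((0, 2)), np.empty(0))
    d12 = simulate_channel_data(cloud, g1, g2, cfg, 0, 1)
    d21 = simulate_channel_data(cloud, g2, g1, cfg, 1, 0)
    for d in (d12, d21):
        d.samples = rng.standard_normal(d.samples.shape)
    d12, d21 = iq_demodulate(d12), iq_demodulate(d21)
    pose = localize_probe(
        d12, d21, g1, g2, cfg, roi_center=(0, 45), roi_size=8.0,
        rot_range=np.deg2rad(2.0), trans_range=1.0, n_steps=3, n_levels=1, min_score=0.5,
    )
    assert not pose.success
    # fallback: nominal pose returned
    assert pose.rotation == pytest.approx(g2.pose.rotation)
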