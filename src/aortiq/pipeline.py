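"""End-to-end experiment: simulate -> beamform -> track -> fuse -> strain
-> metrics, for the single-aperture and bistatic dual-aperture arms.

The experiment mirrors a two-acquisition protocol: a conventional
anterior single-probe acquisition and a dual-probe acquisition with the
probes under an inter-probe angle, both imaging the same pulsating
vessel phantom.  Every stage is seeded and deterministic.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import container
from .acquisition import (
    AcquisitionConfig,
    TransducerGeometry,
    add_channel_noise,
    iq_demodulate,
    pose_facing,
    simulate_channel_data,
)
from .beamform import (
    bmode_render,
    cartesian_grid,
    compound_bistatic,
    das_reconstruct,
    envelope,
    make_sector_grids,
)
from .fusion_strain import (
    RegularizerConfig,
    bistatic_track,
    lsq_strain,
    single_aperture_track,
)
from .mesh import adaptive_strain_kernel, circle_contour, mesh_from_contours
from .metrics import gcnr, motion_drift, regional_gcnr, snre
from .phantom import PhantomSpec, make_phantom
from .tracking import TrackingConfig, block_match, median_filter_disp, select_cardiac_frames

__all__ = ["ExperimentConfig", "desk_config", "tiny_config", "run_experiment", "make_fixtures"]

PATHWAYS = ("T1R1", "T2R2", "T1R2", "T2R1")


@dataclass
class ExperimentConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    n_elements: int = 128
    pitch: float = 0.508
    curvature_radius: float = 49.57
    center_frequency: float = 3.7e6
    xi_star: float = 0.9
    arms: tuple = ("single", "bistatic")
    mesh_size: tuple = (5, 101)
    seed: int = 0

    @property
    def wavelength(self) -> float:
        return self.acquisition.speed_of_sound / self.center_frequency * 1e3


def desk_config(seed: int = 0) -> ExperimentConfig:
    """Desk-scale preset: a 48-element probe pair, 5 steering angles and a
    single cardiac cycle; minutes-scale on one core."""
    ph = PhantomSpec(
        lumen_radius=10.0,
        wall_thickness=2.0,
        center=(0.0, 45.0),
        field_size=(40.0, 40.0),
        scatterer_density=4.0,
        pulsation=0.19,
        midpoint_shift_amplitude=0.3,
        seed=seed,
    )
    acq = AcquisitionConfig(
        steering_angles=np.deg2rad(np.linspace(-12, 12, 5)),
        frame_rate=24.0,
        duration=1.0,
        inter_probe_angle=np.deg2rad(55.0),
        noise_snr_db=0.0,
    )
    trk = TrackingConfig(coarse_search=(3.6, 6.5), fine_search=(1.0, 2.85))
    return ExperimentConfig(phantom=ph, acquisition=acq, tracking=trk, n_elements=48, seed=seed)


def tiny_config(seed: int = 0) -> ExperimentConfig:
    """Smallest preset that still exercises every stage; used for the
    replicate studies and quick tests."""
    cfg = desk_config(seed)
    cfg.phantom = replace(
        cfg.phantom,
        lumen_radius=8.0,
        center=(0.0, 40.0),
        field_size=(34.0, 34.0),
        scatterer_density=3.0,
    )
    cfg.acquisition = replace(
        cfg.acquisition,
        steering_angles=np.deg2rad(np.linspace(-10, 10, 3)),
        frame_rate=14.0,
    )
    cfg.n_elements = 32
    return cfg


def _geometry(cfg: ExperimentConfig, angle: float) -> TransducerGeometry:
    center = np.asarray(cfg.phantom.center)
    return TransducerGeometry(
        n_elements=cfg.n_elements,
        pitch=cfg.pitch,
        curvature_radius=cfg.curvature_radius,
        center_frequency=cfg.center_frequency,
        pose=pose_facing(center, center[1], angle),
    )


def _make_mesh(cfg: ExperimentConfig):
    ph = cfg.phantom
    inner = circle_contour(ph.center, ph.inner_border_radius, n=360)
    if ph.ilt_present:
        outer = circle_contour(ph.center, ph.outer_radius, n=360)
        mesh = mesh_from_contours(inner, outer, size=(17, 151))
    else:
        mesh = mesh_from_contours(inner, ph.wall_thickness, size=cfg.mesh_size)
    adaptive_strain_kernel(mesh)
    return mesh


def _track_fields(images, trk: TrackingConfig, median_px=(11, 11)):
    fields = []
    for p in range(len(images) - 1):
        fld = block_match(images[p], images[p + 1], trk, pair_index=p)
        fields.append(median_filter_disp(fld, median_px))
    return fields


def _radius_series(coords, center):
    inner = coords[:, 0]  # (F, C, 2)
    c = coords.reshape(coords.shape[0], -1, 2).mean(axis=1)
    return np.linalg.norm(inner - c[:, None], axis=-1).mean(axis=1)


def _arm_metrics(coords, strain, mesh, frames):
    ed1, ed2, es = frames
    mid = mesh.middle_ring_index()
    md = motion_drift(coords[ed1, mid], coords[ed2, mid])
    e_mid = strain.circumferential[es, mid]
    return md, snre(e_mid), float(np.median(e_mid))


def run_experiment(cfg: ExperimentConfig, outdir: str | Path | None = None, verbose: bool = True) -> dict:
    """Run both arms and return the comparison report."""
    t_all = time.time()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    noise_seeds = rng.integers(0, 2**31 - 1, size=8)
    ph_spec = replace(cfg.phantom, seed=cfg.seed)
    phantom = make_phantom(ph_spec)
    acq = cfg.acquisition
    lam = cfg.wavelength
    center = np.asarray(ph_spec.center)
    outer_r = ph_spec.outer_radius

    half = acq.inter_probe_angle / 2
    g_single = _geometry(cfg, 0.0)
    g1 = _geometry(cfg, -half)
    g2 = _geometry(cfg, +half)

    def log(msg):
        if verbose:
            print(f"[aortiq +{time.time() - t_all:6.1f}s] {msg}", flush=True)

    # --- simulate ---------------------------------------------------------
    log("simulating channel data (single aperture)")
    cd_s = simulate_channel_data(phantom, g_single, g_single, acq, 0, 0)
    pathways = [(g1, g1, 0, 0), (g2, g2, 1, 1), (g1, g2, 0, 1), (g2, g1, 1, 0)]
    cds = []
    log("simulating channel data (bistatic, 4 pathways)")
    for k, (tx, rx, ti, ri) in enumerate(pathways):
        cd = simulate_channel_data(phantom, tx, rx, acq, ti, ri)
        cds.append(cd)
    if acq.noise_snr_db is not None:
        cd_s = add_channel_noise(cd_s, acq.noise_snr_db, np.random.default_rng(int(noise_seeds[0])))
        cds = [
            add_channel_noise(c, acq.noise_snr_db, np.random.default_rng(int(noise_seeds[1 + k])))
            for k, c in enumerate(cds)
        ]
    cd_s = iq_demodulate(cd_s)
    cds = [iq_demodulate(c) for c in cds]

    # --- beamform ---------------------------------------------------------
    log("beamforming sector grids")
    grid_s = make_sector_grids(g_single, g_single, center, outer_r, lam)[0]
    grid_11, grid_22, grid_tp = make_sector_grids(g1, g2, center, outer_r, lam)
    grids = [grid_11, grid_22, grid_tp, grid_tp]
    geoms = [(g1, g1), (g2, g2), (g1, g2), (g2, g1)]
    n_frames = acq.n_frames
    imgs_s = [
        das_reconstruct(cd_s, grid_s, g_single, g_single, acq, frame=f, pathway="single")
        for f in range(n_frames)
    ]
    imgs = []
    for k in range(4):
        log(f"beamforming pathway {PATHWAYS[k]}")
        imgs.append(
            [
                das_reconstruct(cds[k], grids[k], *geoms[k], acq, frame=f, pathway=PATHWAYS[k])
                for f in range(n_frames)
            ]
        )

    # Cartesian quarter-wave images at the reference frame for image quality
    log("beamforming Cartesian compounding grid")
    fov = min(ph_spec.field_size) * 0.95
    cgrid = cartesian_grid(center, fov, fov, lam / 4)
    cart_s = das_reconstruct(cd_s, cgrid, g_single, g_single, acq, frame=0, pathway="single")
    cart_p = [das_reconstruct(cds[k], cgrid, *geoms[k], acq, frame=0, pathway=PATHWAYS[k]) for k in range(4)]
    cart_b = compound_bistatic(*cart_p)

    # --- tracking ---------------------------------------------------------
    log("block matching (single)")
    flds_s = _track_fields(imgs_s, cfg.tracking)
    flds = []
    for k in range(4):
        log(f"block matching ({PATHWAYS[k]})")
        flds.append(_track_fields(imgs[k], cfg.tracking))
    pairs = [tuple(flds[k][p] for k in range(4)) for p in range(n_frames - 1)]

    # --- arms -------------------------------------------------------------
    log("tracking mesh / fusing / strain")
    mesh = _make_mesh(cfg)
    report = {"seed": cfg.seed, "arms": {}}
    # cardiac phase is a property of the acquisition, not of an arm's
    # tracking quality: select it once, from the least-drifting track
    frames_shared = None
    arm_order = sorted(cfg.arms, key=lambda a: a != "bistatic")
    for arm in arm_order:
        for reg_on in (False, True):
            regcfg = RegularizerConfig(xi_star=cfg.xi_star) if reg_on else None
            if arm == "bistatic":
                coords, _ = bistatic_track(mesh, pairs, grids, regularizer=regcfg)
            else:
                coords = single_aperture_track(mesh, flds_s, grid_s, regularizer=regcfg)
            radius = _radius_series(coords, center)
            if frames_shared is None:
                try:
                    frames_shared = select_cardiac_frames(radius, prominence=0.25)
                except ValueError:
                    frames_shared = (0, len(radius) - 1, int(np.argmax(radius)))
            frames_sel = frames_shared
            strain = lsq_strain(coords, mesh, reference_frame=frames_sel[0])
            md, sn, med = _arm_metrics(coords, strain, mesh, frames_sel)
            key = f"{arm}_reg" if reg_on else arm
            report["arms"][key] = {
                "md_mm": md,
                "snre_db": sn,
                "midwall_circ_strain_median": med,
                "frames": list(frames_sel),
            }
            if outdir is not None:
                od = Path(outdir)
                od.mkdir(parents=True, exist_ok=True)
                container.strain_to_csv(strain, od / f"strain_{key}.csv")

    # --- image quality ----------------------------------------------------
    log("image-quality metrics")
    pix = cgrid.world_points()
    rad = np.linalg.norm(pix - center, axis=-1)
    wall_mask = (rad >= ph_spec.lumen_radius) & (rad <= outer_r)
    lumen_mask = rad < ph_spec.lumen_radius
    q = {}
    for name, img in (("single", cart_s), ("bistatic", cart_b)):
        env = envelope(img)
        from .metrics import erode_lumen

        lum = erode_lumen(lumen_mask, 0.6, cgrid.dx)
        q[name] = {
            "gcnr_total": gcnr(env, wall_mask, lum),
            "gcnr_regional": regional_gcnr(env, wall_mask, lumen_mask, cgrid.dx),
        }
    report["image_quality"] = q

    # ground truth at end-systole for the bistatic frame selection
    from .phantom import ground_truth_strain

    es = report["arms"]["bistatic"]["frames"][2] if "bistatic" in report["arms"] else frames_sel[2]
    t_es = acq.frame_times()[es]
    e_cc_true, _, _ = ground_truth_strain(phantom, mesh.points, t_es)
    mid = mesh.middle_ring_index()
    report["ground_truth"] = {
        "midwall_circ_strain_median": float(np.median(e_cc_true[mid])),
        "lumen_border_circ_strain": float(
            ph_spec.pulsation * _wave(ph_spec, t_es) / ph_spec.lumen_radius
        ),
        "frame_time_es": float(t_es),
    }
    report["runtime_s"] = time.time() - t_all

    if outdir is not None:
        od = Path(outdir)
        od.mkdir(parents=True, exist_ok=True)
        from PIL import Image

        Image.fromarray(bmode_render(cart_s)).save(od / "bmode_single.png")
        Image.fromarray(bmode_render(cart_b)).save(od / "bmode_bistatic.png")
        container.mesh_to_csv(mesh, od / "mesh.csv")
        _write_metrics_csv(report, od / "metrics.csv")
        with open(od / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    log("done")
    return report


def _wave(spec: PhantomSpec, t: float) -> float:
    from .phantom import cardiac_waveform

    return float(cardiac_waveform(t, spec.period, spec.systole_fraction))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o).__name__)


def _write_metrics_csv(report: dict, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["arm", "md_mm", "snre_db", "midwall_circ_strain_median", "gcnr_total"]
            + [f"gcnr_r{i}" for i in range(1, 9)]
        )
        for key, vals in report["arms"].items():
            base = key.replace("_reg", "")
            iq = report["image_quality"].get(base, {})
            row = [
                key,
                f"{vals['md_mm']:.6f}",
                f"{vals['snre_db']:.4f}",
                f"{vals['midwall_circ_strain_median']:.6e}",
                f"{iq.get('gcnr_total', float('nan')):.6f}",
            ]
            row += [f"{v:.6f}" for v in iq.get("gcnr_regional", [float("nan")] * 8)]
            w.writerow(row)


def make_fixtures(size: str = "tiny", outdir: str | Path = "fixtures", seed: int = 0) -> dict:
    """Seeded fixture bundle: phantom + four-pathway channel data + digests."""
    import hashlib

    import h5py

    cfg = tiny_config(seed) if size == "tiny" else desk_config(seed)
    phantom = make_phantom(replace(cfg.phantom, seed=seed))
    half = cfg.acquisition.inter_probe_angle / 2
    g1, g2 = _geometry(cfg, -half), _geometry(cfg, +half)
    od = Path(outdir)
    od.mkdir(parents=True, exist_ok=True)
    digests = {}
    with h5py.File(od / f"fixture_{size}.h5", "w") as h5:
        for tx, rx, ti, ri in ((g1, g1, 0, 0), (g2, g2, 1, 1), (g1, g2, 0, 1), (g2, g1, 1, 0)):
            cd = simulate_channel_data(phantom, tx, rx, cfg.acquisition, ti, ri)
            container.save_channel_data(h5, cd)
            digests[f"T{ti + 1}R{ri + 1}"] = hashlib.sha256(
                np.ascontiguousarray(cd.samples).tobytes()
            ).hexdigest()
        grp = h5.create_group("phantom/frames/0")
        fr = phantom.frame_at(0.0)
        grp.create_dataset("positions", data=fr.scatterer_positions)
        grp.create_dataset("amplitudes", data=fr.scatterer_amplitudes)
    with open(od / f"digests_{size}.json", "w") as fh:
        json.dump(digests, fh, indent=2)
    return digests
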