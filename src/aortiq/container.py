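"""Hierarchical (HDF5) container for channel data, IQ frames and
displacement fields, plus CSV export of meshes and strain.

Layout:
    /channel/<TxRy>/samples            4-D [frame, angle, element, sample]
    /channel/<TxRy>/...                timing metadata
    /iq/<pathway>/frame<i>             complex images + grid attrs
    /disp/<pathway>/pair<i>/{u_ax,u_lat,max_cc}
    /phantom/frames/<i>                scatterer positions / amplitudes
Round-trips are bit exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .acquisition import ChannelData
from .beamform import GridSpec, IQImage

__all__ = [
    "save_channel_data",
    "load_channel_data",
    "save_iq_image",
    "load_iq_image",
    "save_displacement",
    "mesh_to_csv",
    "mesh_from_csv",
    "strain_to_csv",
]


def _pathway_name(tx: int, rx: int) -> str:
    return f"T{tx + 1}R{rx + 1}"


def save_channel_data(h5, data: ChannelData) -> None:
    g = h5.require_group(f"channel/{_pathway_name(data.tx_aperture, data.rx_aperture)}")
    for k in list(g.keys()):
        del g[k]
    g.create_dataset("samples", data=data.samples)
    g.create_dataset("angles", data=data.angles)
    g.create_dataset("frame_times", data=data.frame_times)
    g.attrs["t_start"] = data.t_start
    g.attrs["sampling_frequency"] = data.sampling_frequency
    g.attrs["center_frequency"] = data.center_frequency
    g.attrs["tx_aperture"] = data.tx_aperture
    g.attrs["rx_aperture"] = data.rx_aperture
    g.attrs["is_iq"] = data.is_iq


def load_channel_data(h5, tx: int, rx: int) -> ChannelData:
    g = h5[f"channel/{_pathway_name(tx, rx)}"]
    return ChannelData(
        samples=g["samples"][()],
        tx_aperture=int(g.attrs["tx_aperture"]),
        rx_aperture=int(g.attrs["rx_aperture"]),
        t_start=float(g.attrs["t_start"]),
        sampling_frequency=float(g.attrs["sampling_frequency"]),
        angles=g["angles"][()],
        frame_times=g["frame_times"][()],
        center_frequency=float(g.attrs["center_frequency"]),
        is_iq=bool(g.attrs["is_iq"]),
    )


_GRID_FIELDS = [
    "kind", "x0", "z0", "dx", "dz", "nx", "nz", "apex", "axis_angle",
    "start_radius", "dr", "nr", "theta0", "dtheta", "ntheta",
]


def save_iq_image(h5, img: IQImage) -> None:
    g = h5.require_group(f"iq/{img.pathway}")
    name = f"frame{img.frame_index}"
    if name in g:
        del g[name]
    d = g.create_dataset(name, data=img.values)
    for f in _GRID_FIELDS:
        v = getattr(img.grid, f)
        d.attrs[f"grid_{f}"] = v if f != "apex" else np.asarray(v)
    d.attrs["center_frequency"] = img.center_frequency


def load_iq_image(h5, pathway: str, frame: int) -> IQImage:
    d = h5[f"iq/{pathway}/frame{frame}"]
    kw = {}
    for f in _GRID_FIELDS:
        v = d.attrs[f"grid_{f}"]
        if f == "apex":
            v = tuple(np.asarray(v))
        elif f == "kind":
            v = str(v)
        elif f in ("nx", "nz", "nr", "ntheta"):
            v = int(v)
        else:
            v = float(v)
        kw[f] = v
    return IQImage(
        values=d[()],
        grid=GridSpec(**kw),
        pathway=pathway,
        frame_index=frame,
        center_frequency=float(d.attrs["center_frequency"]),
    )


def save_displacement(h5, fld) -> None:
    g = h5.require_group(f"disp/{fld.pathway}/pair{fld.pair_index}")
    for k in list(g.keys()):
        del g[k]
    g.create_dataset("u_ax", data=fld.u_ax)
    g.create_dataset("u_lat", data=fld.u_lat)
    g.create_dataset("max_cc", data=fld.max_cc)


def mesh_to_csv(mesh, path) -> None:
    R, C = mesh.shape
    ri, ci = np.meshgrid(np.arange(R), np.arange(C), indexing="ij")
    pd.DataFrame(
        {
            "x_mm": mesh.points[..., 0].ravel(),
            "y_mm": mesh.points[..., 1].ravel(),
            "radial_idx": ri.ravel(),
            "circ_idx": ci.ravel(),
        }
    ).to_csv(path, index=False)


def mesh_from_csv(path):
    from .mesh import VesselMesh, local_directions

    df = pd.read_csv(path)
    R = int(df.radial_idx.max()) + 1
    C = int(df.circ_idx.max()) + 1
    pts = np.zeros((R, C, 2))
    pts[df.radial_idx, df.circ_idx, 0] = df.x_mm
    pts[df.radial_idx, df.circ_idx, 1] = df.y_mm
    return local_directions(VesselMesh(points=pts))


def strain_to_csv(strain, path) -> None:
    F, R, C = strain.circumferential.shape
    fi, ri, ci = np.meshgrid(np.arange(F), np.arange(R), np.arange(C), indexing="ij")
    pd.DataFrame(
        {
            "frame": fi.ravel(),
            "radial_idx": ri.ravel(),
            "circ_idx": ci.ravel(),
            "e_rr": strain.radial.ravel(),
            "e_cc": strain.circumferential.ravel(),
            "e_p1": strain.principal.ravel(),
        }
    ).to_csv(path, index=False, float_format="%.6e")
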