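"""Shared fixtures: small simulated datasets and one tiny end-to-end run."""

from __future__ import annotations

import numpy as np
import pytest

from aortiq.acquisition import (
    AcquisitionConfig,
    TransducerGeometry,
    iq_demodulate,
    pose_facing,
    simulate_channel_data,
)


class PointCloud:
    """Minimal phantom stand-in: a static set of point scatterers."""

    def __init__(self, positions, amplitudes, center=(0.0, 45.0), field=(30.0, 30.0)):
        self.positions = np.atleast_2d(np.asarray(positions, dtype=float))
        self.amplitudes = np.asarray(amplitudes, dtype=float)

        class _Spec:
            pass

        self.spec = _Spec()
        self.spec.center = center
        self.spec.field_size = field

    def frame_at(self, t):
        class _F:
            pass

        f = _F()
        f.scatterer_positions = self.positions
        f.scatterer_amplitudes = self.amplitudes
        return f


@pytest.fixture(scope="session")
def small_cfg():
    return AcquisitionConfig(
        steering_angles=np.deg2rad(np.linspace(-8, 8, 3)),
        frame_rate=20.0,
        duration=1 / 20.0,  # single frame
        noise_snr_db=None,
    )


@pytest.fixture(scope="session")
def small_probe():
    return TransducerGeometry(n_elements=16, pose=pose_facing((0.0, 45.0), 45.0, 0.0))


@pytest.fixture(scope="session")
def three_scatterers(small_probe, small_cfg):
    cloud = PointCloud(
        [[0.0, 45.0], [-3.0, 42.0], [2.5, 47.5]], [1.0, 0.7, 1.3], field=(20.0, 20.0)
    )
    cd = simulate_channel_data(cloud, small_probe, small_probe, small_cfg)
    return iq_demodulate(cd)


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """One full tiny end-to-end experiment, shared across tests."""
    from aortiq.pipeline import run_experiment, tiny_config

    out = tmp_path_factory.mktemp("tiny_run")
    report = run_experiment(tiny_config(seed=1), outdir=out, verbose=False)
    return report, out
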