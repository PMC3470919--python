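"""Shared fixtures: small synthetic sessions sized for fast, exact checks."""

from __future__ import annotations

import numpy as np
import pytest

import mtldecode as m


def tiny_config(seed: int = 0, trials_per_condition: int = 6,
                hemispheres=("L",), hc: int = 80) -> m.ExperimentConfig:
    return m.ExperimentConfig(
        grid_shape=(14, 14, 14),
        roi_voxels={"HC": hc, "EC": 30, "PHG": 30},
        trials_per_condition=trials_per_condition,
        hemispheres=hemispheres,
        seed=seed,
    )


def tiny_geometry(mode: str = "attractor", amplitude: float = 2.0,
                  noise_sd: float = 0.5, **kw) -> dict:
    hc = m.GeometrySpec(mode=mode, cluster_radius_voxels=1, n_clusters=2,
                        amplitude=amplitude, noise_sd=noise_sd, **kw)
    small = m.GeometrySpec(mode=mode, cluster_radius_voxels=0, n_clusters=2,
                           amplitude=amplitude, noise_sd=noise_sd, **kw)
    return {"HC": hc, "EC": small, "PHG": small}


@pytest.fixture(scope="session")
def ball_mask() -> m.ROIMask:
    """A compact ~100-voxel blob for searchlight geometry tests."""
    shape = (11, 11, 11)
    center = np.array([5, 5, 5])
    g = np.indices(shape).reshape(3, -1).T
    d2 = ((g - center) ** 2).sum(axis=1)
    mask = np.zeros(shape, dtype=bool)
    mask[tuple(g[d2 <= 9].T)] = True  # radius-3 ball: 123 voxels
    return m.ROIMask("HC", "L", mask)


@pytest.fixture(scope="session")
def full_cube_mask() -> m.ROIMask:
    mask = np.zeros((9, 9, 9), dtype=bool)
    mask[:] = True
    return m.ROIMask("HC", "L", mask)


@pytest.fixture(scope="session")
def attractor_dataset() -> m.SyntheticDataset:
    cfg = tiny_config(seed=7, trials_per_condition=8)
    return m.simulate_dataset(cfg, geo=tiny_geometry("attractor"))


@pytest.fixture(scope="session")
def intermediate_dataset() -> m.SyntheticDataset:
    cfg = tiny_config(seed=8, trials_per_condition=8)
    return m.simulate_dataset(cfg, geo=tiny_geometry("intermediate"))
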