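"""Shared fixtures.

The expensive finite-element fixtures are session-scoped and shared across
test modules: a layered-sphere validation model (analytic oracles apply
there) and the default desk-scale study models.
"""

from __future__ import annotations

import numpy as np
import pytest

from megfem import (
    Dipole, ForwardModel, LabeledVoxelGrid, LayerRadii, PhantomConfig,
    SensorArrayConfig, Tissue, TissueTable, apply_node_shift,
    build_phantom, make_sensor_array, voxels_to_hexmesh,
)
from megfem.study import build_models, default_study_config


def make_homogeneous_sphere(radius: float = 8.0, voxel: float = 0.6,
                            label: Tissue = Tissue.GRAY_MATTER
                            ) -> LabeledVoxelGrid:
    n = int(np.ceil(2 * (radius + 2 * voxel) / voxel))
    origin = -(n - 1) / 2.0 * voxel * np.ones(3)
    grid = LabeledVoxelGrid((n, n, n), voxel, origin,
                            np.zeros((n, n, n), dtype=np.int16))
    centers = grid.voxel_centers()
    r = np.linalg.norm(centers, axis=-1)
    grid.labels[r <= radius] = int(label)
    return grid


#: shell radii of the scaled validation sphere (2/3 of the head phantom)
SPHERE_RADII = LayerRadii(scalp=10.0, skull_outer=9.33,
                          cancellous_outer=8.8, cancellous_inner=8.53,
                          skull_inner=8.0, white=6.67)


@pytest.fixture(scope="session")
def homogeneous_sphere_model() -> ForwardModel:
    """Small homogeneous sphere with the planar gradiometer array."""
    grid = make_homogeneous_sphere()
    mesh = apply_node_shift(voxels_to_hexmesh(grid, TissueTable()), 0.49,
                            grid)
    array = make_sensor_array(SensorArrayConfig(plane_z=8.0 + 4.0,
                                                spacing=5.0))
    return ForwardModel(mesh, array, grid=grid, model_id="homog-sphere")


@pytest.fixture(scope="session")
def layered_sphere_model() -> ForwardModel:
    """Layered sphere at 0.5 mm voxels (>= 26^3), for the field oracles."""
    cfg = PhantomConfig(shape="sphere", radii=SPHERE_RADII, voxel_size=0.5)
    grid = build_phantom(cfg)
    mesh = apply_node_shift(voxels_to_hexmesh(grid, TissueTable()), 0.49,
                            grid)
    array = make_sensor_array(
        SensorArrayConfig(plane_z=SPHERE_RADII.scalp + 4.0, spacing=5.0))
    return ForwardModel(mesh, array, grid=grid, model_id="layered-sphere")


@pytest.fixture(scope="session")
def sphere_tangential_dipole() -> Dipole:
    return Dipole((0.0, 0.0, SPHERE_RADII.skull_inner - 1.5),
                  (130.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def study_setup():
    """Default desk-scale study config and its models (built lazily)."""
    cfg = default_study_config(seed=1234)
    models = build_models(cfg)
    return cfg, models


@pytest.fixture(scope="session")
def recon_runs(study_setup):
    """Noiseless i-I, d-I and d-D reconstruction runs on the default study."""
    from megfem.study import run_reconstruction
    cfg, models = study_setup
    return {conf: run_reconstruction(cfg, models, conf)
            for conf in ("i-I", "d-I", "d-D")}


@pytest.fixture(scope="session")
def noisy_recon_runs(study_setup):
    """The three configurations refit on 40 dB SNR noisy measurements."""
    import dataclasses

    from megfem.study import run_reconstruction
    cfg, models = study_setup
    noisy_cfg = dataclasses.replace(cfg, snr_db=40.0)
    return {conf: run_reconstruction(noisy_cfg, models, conf)
            for conf in ("i-I", "d-I", "d-D")}
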