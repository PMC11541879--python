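"""Shared fixtures: coarse-grid phantoms sized for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

from organotomo import PhantomSpec, generate_organoid_phantom


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0


@pytest.fixture(scope="session")
def cyst_spec() -> PhantomSpec:
    """Enterocystic phantom on a coarse 1 x 1 x 2 µm grid."""
    return PhantomSpec(
        voxel_spacing_um=(1.0, 1.0, 2.0),
        volume_shape_vox=(80, 80, 40),
        outer_radius_um=30.0,
        shell_thickness_um=12.0,
        noise_sd=0.002,
        seed=1,
    )


@pytest.fixture(scope="session")
def cyst_phantom(cyst_spec):
    return generate_organoid_phantom(cyst_spec)


@pytest.fixture(scope="session")
def uniform_ball_spec() -> PhantomSpec:
    """Noise-free solid sphere of uniform density 0.1 g/mL, radius 12 µm."""
    return PhantomSpec(
        voxel_spacing_um=(0.5, 0.5, 1.0),
        volume_shape_vox=(64, 64, 32),
        outer_radius_um=12.0,
        shell_thickness_um=12.0,
        noise_sd=0.0,
        uniform_density=0.1,
        debris_count=0,
        seed=0,
    )


@pytest.fixture(scope="session")
def uniform_ball(uniform_ball_spec):
    return generate_organoid_phantom(uniform_ball_spec)


def livedead_subvolume_tables(n_seeds: int = 10, seed0: int = 0):
    """Subvolume density tables for live- and dead-dominant phantoms.

    One pair of large phantoms per seed (all-live and all-dead epithelium,
    emulating the live-cell-dominant and dead-cell-dominant regions a
    stained acquisition identifies), partitioned into the default
    50 x 50 x 10 µm cubes over the epithelial shell.
    """
    from organotomo import PhantomSpec, VolumeMask, partition_subvolumes

    tables = {"live": [], "dead": []}
    for i in range(n_seeds):
        for group, frac in (("live", 0.0), ("dead", 1.0)):
            spec = PhantomSpec(
                voxel_spacing_um=(1.0, 1.0, 2.0),
                volume_shape_vox=(170, 170, 90),
                outer_radius_um=70.0,
                shell_thickness_um=25.0,
                dead_fraction=frac,
                noise_sd=0.002,
                seed=seed0 + 7 * i + (0 if group == "live" else 1000),
            )
            tomo, truth = generate_organoid_phantom(spec)
            shell = VolumeMask(truth.organoid_mask & ~truth.lumen_mask)
            tab = partition_subvolumes(
                tomo, shell, group=group, truth_labels=truth.live_dead_labels
            )
            tab["seed_index"] = i
            tables[group].append(tab)
    return tables


@pytest.fixture(scope="session")
def livedead_tables():
    return livedead_subvolume_tables()
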