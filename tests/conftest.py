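"""Shared fixtures: small geometries, synthetic datasets, a smoke-trained model.

Everything is generated programmatically at test time; the expensive
reduced-scale training run is session-scoped so the training-behaviour and
separation-quality tests share one model.
"""

from __future__ import annotations

import numpy as np
import pytest

from diffsep import dataset as ds
from diffsep import gan
from diffsep.molecules import Molecule, random_molecule
from diffsep.scatter import PlaneDefinition, reciprocal_basis


@pytest.fixture(scope="session")
def cubic_recip():
    return reciprocal_basis(6.0, 6.0, 6.0)


@pytest.fixture(scope="session")
def hexagonal_recip():
    return reciprocal_basis(12.0, 12.0, 7.0, 90.0, 90.0, 120.0)


@pytest.fixture(scope="session")
def small_plane(cubic_recip):
    """Centred hk0 plane, 64 pixels, with exact Friedel partners."""
    return PlaneDefinition.axis_plane(
        cubic_recip, (0, 1), offset=0.0, grid_size=64, q_max=7.0
    )


@pytest.fixture(scope="session")
def offset_plane(cubic_recip):
    return PlaneDefinition.axis_plane(
        cubic_recip, (0, 1), offset=1.0, grid_size=64, q_max=7.0
    )


@pytest.fixture(scope="session")
def mol_pair():
    return random_molecule(11, (6, 10)), random_molecule(12, (6, 10))


@pytest.fixture(scope="session")
def vacancy():
    return Molecule.vacancy()


SMOKE_SEED = 2024


def _smoke_config() -> ds.DatasetConfig:
    return ds.DatasetConfig(
        mc_models_per_pair=4,
        mc_planes_per_model=6,
        sym_models_per_pair=4,
        sym_planes_per_model=4,
        grid_size=64,
        mc_dims=(12, 12, 12),
        vector_cutoff=3,
    )


@pytest.fixture(scope="session")
def smoke_dataset():
    """~200 training + held-out 64x64 samples from 6 synthetic molecule pairs."""
    pairs = [
        (random_molecule(2 * i + 101, (5, 20)), random_molecule(2 * i + 102, (5, 20)))
        for i in range(6)
    ]
    manifest, samples = ds.build_dataset(pairs, _smoke_config(), seed=SMOKE_SEED)
    train, holdout = samples[:200], samples[200:210]
    assert len(train) == 200 and len(holdout) >= 5
    return manifest, train, holdout


@pytest.fixture(scope="session")
def smoke_run(smoke_dataset):
    """Five epochs of reduced-scale training on 200 samples, fixed seed."""
    _, train, _ = smoke_dataset
    state = gan.init_train_state(
        seed=SMOKE_SEED,
        grid_size=64,
        gen_spec=gan.GeneratorSpec(grid_size=64, base_channels=12),
        disc_spec=gan.DiscriminatorSpec(base_channels=12),
    )
    logs = gan.train_epoch(state, train, epochs=5)
    return state, logs
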