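"""Shared desk-scale fixtures.

The tiny configuration keeps the full design structure (two tasks, nine
category x quality cells, two presentations, odd/even run
counterbalancing) at 4 images per cell and 9-trial blocks, so every
pipeline stage runs in seconds.
"""

import numpy as np
import pytest

import vqmvpa as v


def tiny_design_config(**overrides):
    base = dict(
        n_participants=2,
        n_runs=4,
        blocks_per_run=4,
        trials_per_block=9,
        block_total_s=50.0,  # 4 + 9 * 3.5 + 14.5 s of ISIs
        images_per_cell=4,
        seed=11,
    )
    base.update(overrides)
    return v.DesignConfig(**base)


def tiny_sim_params(**overrides):
    base = dict(
        voxels_per_unilateral_roi=30,
        n_reliable_voxels=15,
        seed=11,
    )
    base.update(overrides)
    return v.SimulationParams(**base)


@pytest.fixture(scope="session")
def tiny_design():
    return v.generate_design(tiny_design_config())


@pytest.fixture(scope="session")
def tiny_dataset(tiny_design):
    return v.simulate_betas(tiny_design, tiny_sim_params())


@pytest.fixture(scope="session")
def tiny_reps(tiny_dataset):
    return v.extract_representations(tiny_dataset, k=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
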