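"""Shared fixtures: a coarse synthetic study (population, shape model, trials,
trained surrogates) reused across the regression/validation/synthetic tests.

The coarse configuration (60-node loops, 12 capsule lines, ~160 trials) keeps
whole-pipeline tests fast while exercising every stage of the real pipeline.
"""

from __future__ import annotations

import numpy as np
import pytest

import capsulereg as cr


@pytest.fixture(scope="session")
def frame() -> cr.AnatomicFrame:
    return cr.AnatomicFrame()


@pytest.fixture(scope="session")
def coarse_mesh_config() -> cr.MeshConfig:
    return cr.MeshConfig(n_lines=12)


@pytest.fixture(scope="session")
def population_small():
    config = cr.PopulationConfig(n_subjects=80, n_nodes=60, seed=101)
    return cr.synthetic_attachment_population(config)


@pytest.fixture(scope="session")
def shape_model_small(population_small) -> cr.ShapeModel:
    return cr.fit_shape_model(population_small, n_modes=4)


@pytest.fixture(scope="session")
def small_dataset(shape_model_small, coarse_mesh_config):
    return cr.generate_trial_dataset(
        160, shape_model_small, mesh_config=coarse_mesh_config, seed=202
    )


@pytest.fixture(scope="session")
def split_small(small_dataset):
    """Deterministic 130/30 train/validation split of the complete trials."""
    complete = [r for r in small_dataset if r.ok]
    rng = np.random.default_rng(303)
    order = rng.permutation(len(complete))
    shuffled = [complete[i] for i in order]
    return shuffled[:130], shuffled[130:160]


@pytest.fixture(scope="session")
def set1_model(split_small) -> cr.RegressionModel:
    train, _ = split_small
    return cr.train_surrogate(train, cr.TRAINING_SETS[1])


@pytest.fixture(scope="session")
def set2_model(split_small) -> cr.RegressionModel:
    train, _ = split_small
    return cr.train_surrogate(train, cr.TRAINING_SETS[2])


@pytest.fixture(scope="session")
def multi_seed_loop(shape_model_small, coarse_mesh_config):
    """Five independent scaled-down calibration loops for ordering properties.

    For each seed: a 120-trial dataset, Set 1 surrogates at two nested
    training sizes validated on a fixed 20-trial holdout, and a Set 2
    (I-E-only) surrogate validated on the same holdout.
    """
    results = []
    for seed in range(5):
        records = cr.generate_trial_dataset(
            120, shape_model_small, mesh_config=coarse_mesh_config, seed=1000 + seed
        )
        complete = [r for r in records if r.ok]
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(complete))
        shuffled = [complete[i] for i in order]
        val = shuffled[-20:]
        pool = shuffled[:-20]
        small = cr.train_surrogate(pool[:60], cr.TRAINING_SETS[1])
        large = cr.train_surrogate(pool[:100], cr.TRAINING_SETS[1])
        ie_only = cr.train_surrogate(pool[:100], cr.TRAINING_SETS[2])
        results.append(
            {
                "seed": seed,
                "rmse_small": cr.closed_loop_validate(
                    small, val, shape_model_small, coarse_mesh_config
                ),
                "rmse_large": cr.closed_loop_validate(
                    large, val, shape_model_small, coarse_mesh_config
                ),
                "ie_only": cr.closed_loop_validate(
                    ie_only, val, shape_model_small, coarse_mesh_config
                ),
            }
        )
    return results
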