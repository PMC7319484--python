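"""Shared fixtures: small seeded synthetic worlds reused across tests."""

import numpy as np
import pandas as pd
import pytest

import traitscape as ts
from traitscape import learners as lrn


def make_world(seed, n_cols=20, n_rows=20, n_species=300, n_sites=150,
               species_per_site=15, specs=None, **assemble_kw):
    """One seeded synthetic world: (stack, pool, observations, truth)."""
    gs = ts.GridSpec(n_cols=n_cols, n_rows=n_rows)
    stack = ts.generate_env_grid(gs, 2.0, seed=seed)
    pool = ts.generate_species_pool(n_species, seed=seed + 1)
    obs, truth = ts.assemble_communities(
        stack, pool, specs or ts.default_response_specs(),
        n_sites=n_sites, species_per_site=species_per_site,
        seed=seed + 2, **assemble_kw,
    )
    return stack, pool, obs, truth


def features_of(stack, obs):
    """Run the data path (filter, clean, means, grid, link) on one world."""
    kept, _ = ts.apply_selection_criteria(obs)
    clean, _ = ts.clean_observations(kept)
    cm = ts.community_mean(clean)
    records = ts.grid_aggregate(cm, stack.grid)
    features, _ = ts.link_env(records, stack)
    return features


@pytest.fixture(scope="session")
def small_world():
    return make_world(seed=1000)


@pytest.fixture(scope="session")
def small_features(small_world):
    stack, _pool, obs, _truth = small_world
    return features_of(stack, obs)


@pytest.fixture(scope="session")
def height_fits(small_features):
    """Cross-validated fits of all four learners for one trait."""
    sub = small_features[small_features["trait"] == "height"].reset_index(drop=True)
    X = sub[list(ts.PREDICTORS)]
    y = sub["value"]
    fits = {
        kind: lrn.cross_validate(lrn.LearnerSpec(kind, seed=10 + i), X, y, seed=7)
        for i, kind in enumerate(lrn.LEARNER_KINDS)
    }
    return fits, X, y


@pytest.fixture(scope="session")
def height_ensemble(height_fits):
    fits, X, y = height_fits
    return ts.build_ensemble("height", fits), X, y


def tiny_config(root, name, seed=11):
    from traitscape import pipeline as pl
    return pl.RunConfig(
        out_dir=str(root / name),
        seed=seed,
        world=pl.WorldConfig(n_cols=12, n_rows=12, n_species=150,
                             n_sites=80, species_per_site=10),
        n_permutations=3,
        partial_grid_size=20,
    )


@pytest.fixture(scope="session")
def smoke_runs(tmp_path_factory):
    """Two full tiny-world runs from one master seed."""
    from traitscape import pipeline as pl
    root = tmp_path_factory.mktemp("runs")
    r1 = pl.run_full_pipeline(tiny_config(root, "a"))
    r2 = pl.run_full_pipeline(tiny_config(root, "b"))
    return r1, r2
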