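"""Shared fixtures: small host sets, the 1-random-effect toy, null generators."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import lingcod_burden as lb

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced synthetic study: 20 fish, 5 taxa, every cell represented."""
    cfg = lb.GeneratorConfig(
        n_regions=2,
        sites_per_region=2,
        fish_per_site=5,
        n_fish=20,
        n_taxa=5,
        cell_probabilities=(0.45, 0.2, 0.2, 0.15),
        exact_cells=True,
        seed=17,
    )
    return lb.generate_dataset(cfg)


@pytest.fixture(scope="session")
def fast_design():
    """No-random-effect design: quick refits for permutation machinery tests."""
    return lb.ModelDesign(nested_terms=(), taxon_structure="none")


@pytest.fixture(scope="session")
def toy_1re():
    """The shipped single-random-effect toy: 3 groups x 4 NB counts.

    Frozen recipe (generator seed 42) so the quadrature oracle and the
    Laplace implementation always see the same instance.
    """
    rng = np.random.default_rng(42)
    n_groups, per = 3, 4
    groups = np.repeat([f"g{i}" for i in range(n_groups)], per)
    beta0, sigma, theta = 1.8, 0.5, 5.0
    b_true = rng.normal(0, sigma, n_groups)
    mu = np.exp(beta0 + np.repeat(b_true, per))
    y = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)
    return {"y": y, "groups": groups, "n_groups": n_groups}


def make_null_config(seed: int) -> lb.GeneratorConfig:
    """Null generator for permutation calibration: no color effects at all,
    no random structure (so the refitted model is an ordinary NB regression),
    and exactly 4 blue males / 3 blue females per realization."""
    return lb.GeneratorConfig(
        n_regions=2,
        sites_per_region=2,
        fish_per_site=10,
        n_fish=40,
        n_taxa=3,
        cell_probabilities=(26 / 40, 4 / 40, 7 / 40, 3 / 40),
        exact_cells=True,
        beta_color_brown=0.0,
        beta_interaction=0.0,
        sd_region=0.0,
        sd_site=0.0,
        sd_fish=0.0,
        taxon_cov=np.zeros((4, 4)),
        theta=2.0,
        seed=seed,
    )


def make_hosts(rows) -> list:
    """Host records from compact tuples
    (fish_id, region, location, depth, sex, color, length, mass, liver)."""
    return [lb.HostRecord(*r) for r in rows]
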