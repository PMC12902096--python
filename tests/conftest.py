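"""Shared fixtures: seeded synthetic datasets reused across test modules."""

from __future__ import annotations

import pytest

from salinomics import synthetic as syn

#: root seed of the default study-scale fixtures
ROOT_SEED = 1


@pytest.fixture(scope="session")
def presence_default():
    """Default-scale presence-absence simulation (40 species, 2000 families)."""
    counts, meta, truth = syn.simulate_presence_absence(
        seed=syn.substream_seed(ROOT_SEED, "presence")
    )
    return counts, meta, truth


@pytest.fixture(scope="session")
def expression_default():
    """Default-scale expression simulation (300 metagenes, 3 planted modules)."""
    exprs, gmap, traits, truth = syn.simulate_expression(
        seed=syn.substream_seed(ROOT_SEED, "expression")
    )
    return exprs, gmap, traits, truth


@pytest.fixture(scope="session")
def metabolites_default():
    """Default-scale metabolite simulation (451 compounds, 150 planted DA)."""
    mets, truth = syn.simulate_metabolites(
        seed=syn.substream_seed(ROOT_SEED, "metabolites")
    )
    return mets, truth


@pytest.fixture(scope="session")
def presence_small():
    """Small presence-absence fixture for fast unit tests."""
    counts, meta, truth = syn.simulate_presence_absence(
        n_salt=8, n_fresh=8, n_families=300,
        n_planted_salt=5, n_planted_fresh=10, seed=4,
    )
    return counts, meta, truth
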