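"""Shared fixtures: cached simulated studies and derived matrices."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from corrbreak import genio, kinship, simdata

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_cache():
    """Memoised default-config studies, keyed by seed (shared across tests)."""
    cache: dict = {}

    def get(seed: int) -> simdata.SimulatedStudy:
        if seed not in cache:
            cache[seed] = simdata.generate_study(simdata.SimConfig(seed=seed))
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def qc_cache(study_cache):
    """Memoised MAF-filtered, mean-imputed genotypes per seed."""
    cache: dict = {}

    def get(seed: int) -> genio.GenotypeMatrix:
        if seed not in cache:
            g, _ = genio.maf_filter(study_cache(seed).genotypes, 0.01)
            cache[seed] = genio.mean_impute(g)
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def study(study_cache):
    return study_cache(1)


@pytest.fixture(scope="session")
def qc_genotypes(qc_cache):
    return qc_cache(1)


def cohort_g(g: genio.GenotypeMatrix) -> kinship.RelationshipMatrix:
    """VanRaden G on the markers still polymorphic within this cohort."""
    poly, _ = genio.maf_filter(g, 0.0)
    return kinship.vanraden_g(poly)


@pytest.fixture(scope="session")
def pop1_training(qc_cache, study_cache):
    """(G matrix, labels, families) for the seed-1 training population."""
    g = qc_cache(1)
    st = study_cache(1)
    pop1 = [i for i, p in zip(g.individual_ids, g.population) if p != "POP2GF"]
    G1 = cohort_g(g.subset_individuals(pop1))
    return G1, st.breaker_labels.loc[pop1], st.families


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
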