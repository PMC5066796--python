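"""Shared fixtures: small synthetic genomes generated once per session."""
from __future__ import annotations

import numpy as np
import pytest

from legfam import (
    SyntheticConfig,
    generate_genomes,
    scan_proteins,
)
from legfam.domains import builtin_profile


@pytest.fixture(scope="session")
def ap2_profile():
    return builtin_profile("AP2")


@pytest.fixture(scope="session")
def small_fixture():
    """Two species x 50 genes, noise-free, with planted duplications and
    orthologs in every downstream-relevant category."""
    config = SyntheticConfig(
        species_count=2,
        genes_per_species=50,
        planted_tandem_pairs=2,
        planted_segmental_pairs=4,
        planted_ortholog_fraction=1.0,
        noise_mutation_rate=0.0,
        seed=42,
    )
    return generate_genomes(config)


@pytest.fixture(scope="session")
def small_hits(small_fixture):
    return scan_proteins(small_fixture.all_proteins())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
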