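"""Shared fixtures: a seeded reference panel and a small planted genome.

All fixtures are deterministic; nothing is read from disk."""

import pytest

from ltrkit import PlantSpec, generate_genome, generate_panel


@pytest.fixture(scope="session")
def panel():
    return generate_panel(seed=11)


@pytest.fixture(scope="session")
def planted():
    """A 150 kb scaffold carrying 10 planted elements (2 BEL, 3 copia,
    2 DIRS, 3 gypsy) at 2% divergence, with its truth manifest."""
    spec = PlantSpec(
        counts={"BEL": 2, "copia": 3, "DIRS": 2, "gypsy": 3}, divergence=0.02
    )
    pan = generate_panel(seed=11)
    genomes, manifest = generate_genome(
        spec, pan, background_length=150_000, seed=7
    )
    return genomes, manifest, pan
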