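"""Shared fixtures: small synthetic populations, encoders, and probe geometry."""

import numpy as np
import pytest

import spikesight as ss


@pytest.fixture(scope="session")
def separable_population():
    """Separable 4-type population, 20 units per type (session-cached)."""
    return ss.synth_population(n_per_type=20, separation_level="separable", seed=0)


@pytest.fixture(scope="session")
def mock_encoder():
    return ss.load_encoder({"backend": "mock_projection", "dim": 64, "seed": 0})


@pytest.fixture(scope="session")
def population_embeddings(separable_population, mock_encoder):
    from spikesight.fewshot import embed_records

    return embed_records(separable_population, mock_encoder)


@pytest.fixture(scope="session")
def example_record():
    return ss.synth_neuron(ss.DEFAULT_ARCHETYPES["Pyramidal"], duration=60.0, seed=3)


@pytest.fixture()
def linear_probe():
    n = 8
    return ss.ProbeGeometry(
        channel_ids=tuple(range(n)),
        positions=np.column_stack([np.zeros(n), np.arange(n) * 20.0]),
    )
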