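from __future__ import annotations

import pytest

from ighclone import SimulationConfig, generate_synthetic_germline, simulate_sample
from ighclone.germline import GeneSegment, GermlineSet, parse_segment_name


def make_segment(label: str, sequence: str) -> GeneSegment:
    return GeneSegment(name=parse_segment_name(label), sequence=sequence)


@pytest.fixture
def toy_germline() -> GermlineSet:
    """Tiny hand-built germline for junction arithmetic tests."""
    return GermlineSet.from_segments(
        [
            make_segment("IGHV1-1*01", "ACGTACGT"),
            make_segment("IGHD1-1*01", "TTTT"),
            make_segment("IGHJ1*01", "CCCCCC"),
        ]
    )


@pytest.fixture(scope="session")
def synthetic_germline() -> "GermlineSet":
    return generate_synthetic_germline(8, 4, 4, divergence=0.015, seed=7)


@pytest.fixture(scope="session")
def small_sample(synthetic_germline):
    """A 600-pair error-free monoclonal sample used by several test modules."""
    return simulate_sample(
        synthetic_germline,
        n_pairs=600,
        main_fraction=0.7,
        n_background=10,
        seed=5,
        config=SimulationConfig(substitution_error_rate=0.0),
    )


@pytest.fixture(scope="session")
def noisy_sample(synthetic_germline):
    """Same design with sequencing errors injected."""
    return simulate_sample(
        synthetic_germline,
        n_pairs=600,
        main_fraction=0.7,
        n_background=10,
        seed=6,
        config=SimulationConfig(substitution_error_rate=0.005),
    )
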