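import numpy as np
import pytest

from mitonuclear import popgen_sim as ps


@pytest.fixture(scope="session")
def tiny_map() -> ps.GeneticMap:
    """4 chromosomes x 25 evenly spaced markers over 250 kb each."""
    return ps.GeneticMap.yeast_like(
        n_chromosomes=4, markers_per_chromosome=25, chromosome_length_bp=250_000
    )


@pytest.fixture(scope="session")
def small_panel(tiny_map) -> ps.FounderPanel:
    return ps.simulate_founders(10, 2, tiny_map, F=0.2, seed=11)


@pytest.fixture(scope="session")
def small_collection(small_panel) -> ps.RecombinantCollection:
    """60 strains x 3 mitotypes from a 3-round intercross of 10 founders."""
    rc1 = ps.advanced_intercross(
        small_panel, rounds=3, progeny_per_round=300, sample_size=60, seed=12
    )
    return ps.replicate_with_mitotypes(rc1, ["RC1", "RC2", "RC3"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
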