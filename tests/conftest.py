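import pytest

from genecontent import ProteomeSimConfig, simulate_proteomes


@pytest.fixture(scope="session")
def planted_proteomes():
    """Three proteomes with known family structure at identity 0.9:
    5 core families, 3 A&B-only, 2 B&C-only, and per-genome unique genes."""
    cfg = ProteomeSimConfig(
        n_genomes=3,
        n_core_families=5,
        n_pairwise_families={"A-B": 3, "B-C": 2},
        n_unique={"A": 2, "B": 1, "C": 3},
        protein_length=120,
        within_family_identity=0.9,
        seed=7,
    )
    return simulate_proteomes(cfg)
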