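import pytest

from allokit.simulate import SimulationConfig, simulate_all

# a small three-group design reused by tests that do not need all 22 tissues
SMALL_TISSUES = (
    ("leaf", "vegetative"),
    ("root", "vegetative"),
    ("flower", "reproductive"),
    ("peg", "reproductive"),
    ("seed_early", "seed"),
    ("seed_late", "seed"),
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11,
        n_chroms=2,
        chrom_len=40_000,
        n_pairs=10,
        tissues=SMALL_TISSUES,
        n_exon_skip=5,
        n_alt_donor=5,
        n_alt_acceptor=5,
        n_decoy_junctions=6,
        n_lncrna=(
            ("intergenic", 4),
            ("intronic", 2),
            ("exonic", 4),
            ("pri_miRNA", 2),
        ),
    )


@pytest.fixture(scope="session")
def dataset(small_config):
    return simulate_all(small_config)
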