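import numpy as np
import pytest

from isoreads.simulate import (
    GeneSimSpec,
    SimulationConfig,
    build_genome,
    ptt_gene,
    simulate_reads,
    two_first_exon_gene,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def ap_gene():
    """Minus-strand alternative-promoter gene template."""
    return two_first_exon_gene()


@pytest.fixture(scope="session")
def ptt_model():
    """Plus-strand premature-termination gene template."""
    return ptt_gene()


def make_ptt_readthrough_config(prob: float, n_reads: int, seed: int,
                                donor: str = "donor_e4") -> SimulationConfig:
    """Single-group config in which every read crosses the named donor."""
    model = ptt_gene()
    spec = GeneSimSpec(
        model=model,
        mixture={"G": {"B_FULL": 1.0}},
        readthrough={donor: {"G": prob}},
        termination={"donor_e4": 4700, "donor_e6": 6700},
    )
    cells = max(1, n_reads // 500)
    return SimulationConfig(
        genes=[spec],
        groups={"G": cells},
        reads_per_cell=n_reads // cells,
        seed=seed,
    )


def make_first_exon_config(tr_weight: float, n_cells: int, reads_per_cell: int,
                           seed: int, group: str = "G") -> SimulationConfig:
    model = two_first_exon_gene()
    spec = GeneSimSpec(
        model=model,
        mixture={group: {"TR": tr_weight, "FL": 1.0 - tr_weight}},
    )
    return SimulationConfig(
        genes=[spec],
        groups={group: n_cells},
        reads_per_cell=reads_per_cell,
        seed=seed,
    )


def make_altsplice_config(fraction: float, n_reads: int, seed: int) -> SimulationConfig:
    model = two_first_exon_gene()
    spec = GeneSimSpec(
        model=model,
        mixture={"G": {"FL": 1.0 - fraction, "FL_DEX2": fraction}},
    )
    cells = max(1, n_reads // 500)
    return SimulationConfig(
        genes=[spec],
        groups={"G": cells},
        reads_per_cell=n_reads // cells,
        seed=seed,
    )


@pytest.fixture(scope="session")
def demo_dataset(tmp_path_factory):
    """Small simulated dataset shared across I/O and pipeline tests."""
    from isoreads.simulate import demo_config

    cfg = demo_config(seed=11)
    genome = build_genome(cfg)
    reads = simulate_reads(cfg, genome)
    return cfg, genome, reads
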