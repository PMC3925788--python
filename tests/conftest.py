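import numpy as np
import pytest

from mitomosaic import CircularGenome, SimulationConfig, generate_master_circle


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_genome(n: int, seed: int, circular: bool = True) -> CircularGenome:
    r = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in r.integers(0, 4, size=n))
    return CircularGenome(id=f"rand{seed}", sequence=seq, is_circular=circular)


@pytest.fixture
def small_sim():
    """A small genome with one exact inverted repeat and a few genes."""
    cfg = SimulationConfig(
        genome_length=6000,
        repeat_spec=((150, "inverted", 0),),
        n_genes=3,
        gene_length_range=(300, 450),
        rng_seed=42,
    )
    genome, truth = generate_master_circle(cfg)
    return cfg, genome, truth
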