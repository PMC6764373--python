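import numpy as np
import pytest

import mitokit as mk


@pytest.fixture(scope="session")
def default_config() -> mk.SimulationConfig:
    return mk.SimulationConfig()


@pytest.fixture(scope="session")
def genome(default_config):
    """The default synthetic mitogenome (seed 42): chromosomes,
    annotations, ground truth."""
    return mk.generate_mitogenome(default_config)


@pytest.fixture(scope="session")
def transcripts(genome, default_config):
    """Truth transcript alignments; updates junction supports in truth."""
    chroms, annotations, truth = genome
    spliced, polya, refs = mk.simulate_transcript_alignments(
        chroms, annotations, truth, default_config)
    return spliced, polya, refs, truth


@pytest.fixture(scope="session")
def long_reads(genome, default_config):
    chroms, _, _ = genome
    cfg = mk.SimulationConfig(seed=default_config.seed, coverage=10)
    return mk.simulate_genomic_reads(chroms, cfg, long_reads=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.45) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
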