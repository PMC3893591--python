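import numpy as np
import pandas as pd
import pytest

from cisnet.genome import GenomeDefinition
from cisnet.insertions import SITE_COLUMNS, InsertionDataset
from cisnet.simulate import simulate_expression


@pytest.fixture(scope="session")
def toy_genome():
    return GenomeDefinition({"chr1": 10_000_000, "chr2": 5_000_000})


def make_dataset(genome, rows):
    """rows: (sample, chrom, pos, strand, reads) tuples."""
    return InsertionDataset(pd.DataFrame(rows, columns=SITE_COLUMNS), genome)


@pytest.fixture(scope="session")
def planted_study():
    """200-sample expression study with a planted 7-gene signed metagene."""
    study, graph, truth = simulate_expression(300, 200, metagene_effect=2.0,
                                              noise_sd=1.0, seed=42)
    return study, graph, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
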