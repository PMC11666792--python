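import numpy as np
import pytest

from oxidoscape.genome import Genome
from oxidoscape.synthetic import (
    SyntheticConfig,
    make_annotation_fixtures,
    make_reference,
    plant_events,
)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=101, contig_lengths={"chrS1": 500_000}, n_events=5_000)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return make_reference(small_config)


@pytest.fixture(scope="session")
def small_tracks(small_config, small_genome):
    return make_annotation_fixtures(small_config, small_genome)


@pytest.fixture(scope="session")
def small_truth(small_config, small_genome, small_tracks):
    return plant_events(small_config, small_genome, small_tracks)


@pytest.fixture()
def toy_genome():
    """A tiny deterministic reference for hand-checked examples."""
    rng = np.random.default_rng(7)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
    # plant specific bases used by the lesion examples
    seq = seq[:100] + "G" + seq[101:249] + "C" + seq[250:]
    return Genome({"chrT": seq})


def as_events(df):
    """Materialize truth-table rows as simple event objects."""
    return list(df.itertuples(index=False))
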