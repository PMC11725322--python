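import numpy as np
import pytest

from metaspot.synthdata import SimConfig, simulate
from metaspot.workflow import build_metaspots


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic Visium dataset: 3639-spot hex lattice, 7 band
    domains, negative-binomial counts."""
    return simulate(SimConfig())


@pytest.fixture(scope="session")
def default_run(default_fixture):
    """Full walktrap pipeline on the default fixture at γ = 4."""
    return build_metaspots(default_fixture, gamma=4)


@pytest.fixture
def small_sm():
    """A quick 100-gene × 300-spot hex fixture with 3 domains."""
    return simulate(SimConfig(n_spots=300, n_genes=100, n_domains=3, seed=5))


def modal_label_projection(partition, labels):
    """Per-spot labels after replacing each spot's label by its metaspot's
    modal label (ties to the lexicographically first winner)."""
    labels = np.asarray(labels, dtype=object).astype(str)
    out = np.empty(len(labels), dtype=object)
    for members in partition.members():
        cats, counts = np.unique(labels[members], return_counts=True)
        out[members] = cats[counts.argmax()]
    return out
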