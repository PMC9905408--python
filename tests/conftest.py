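import numpy as np
import pytest

from scarst import geometry, preprocess, synthetic


@pytest.fixture(scope="session")
def lattice_10x10():
    return synthetic.build_lattice(10, 10)


@pytest.fixture(scope="session")
def lattice_30x30():
    return synthetic.build_lattice(30, 30)


@pytest.fixture(scope="session")
def graph_30x30(lattice_30x30):
    return geometry.neighbor_graph(lattice_30x30)


@pytest.fixture(scope="session")
def scene14(lattice_30x30):
    """Intermediate-stage scene: fibrotic core, microglial and astrocytic rings."""
    return synthetic.make_scene(lattice_30x30, 14, seed=2)


@pytest.fixture(scope="session")
def counts14(scene14):
    return synthetic.sample_counts(
        scene14,
        synthetic.default_programs(),
        synthetic.default_interactions(),
        n_genes=300,
        seed=2,
    )


@pytest.fixture(scope="session")
def norm14(counts14):
    return preprocess.log_normalize(counts14)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
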