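import numpy as np
import pytest

from allohe import simulate as sim
from allohe.layout import Chromosome, GenomeLayout, make_windows


@pytest.fixture(scope="session")
def small_config():
    """One 1-Mb chromosome per subgenome with a single planted HE; LTR
    positions compressed to fit. Small enough for subsecond mapping."""
    spec = sim.default_ltr_spec()
    for e in spec:
        e["position"] //= 4
    return sim.SimConfig(
        seed=7,
        n_chromosomes=1,
        chromosome_length=1_000_000,
        he_segments=[("a", 0, 250_000, 500_000)],
        coverage=8.0,
        ltr_spec=spec,
    )


@pytest.fixture(scope="session")
def small_universe(small_config):
    anc_a, anc_f = sim.simulate_ancestors(small_config)
    hybrid, truth = sim.simulate_hybrid(anc_a, anc_f, small_config)
    return small_config, anc_a, anc_f, hybrid, truth


@pytest.fixture
def hybrid_layout():
    return GenomeLayout(
        "hybrid",
        (
            Chromosome("chr1_a", 1_000_000, "a"),
            Chromosome("chr1_f", 1_000_000, "f"),
        ),
    )


@pytest.fixture
def grid_250k(hybrid_layout):
    return make_windows(hybrid_layout, 250_000)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
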