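import numpy as np
import pandas as pd
import pytest

from epiloci.overlap import incidence_to_matrix
from epiloci.synth import SynthConfig, gen_scenario


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """A scaled-down scenario for fast end-to-end tests."""
    return SynthConfig(
        seed=7, n_markers=4000, n_planted_loci=12, n_celltypes=8,
        n_genes=400, n_samples=120,
    )


@pytest.fixture(scope="session")
def small_scenario(small_cfg):
    return gen_scenario(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def random_overlap_matrix(rng, n_markers: int, cell_types, rate: float = 0.3):
    """Bernoulli incidence wrapped as an OverlapMatrix."""
    inc = pd.DataFrame(
        rng.random((n_markers, len(cell_types))) < rate,
        index=pd.Index([f"m{i}" for i in range(n_markers)], name="id"),
        columns=list(cell_types),
    )
    return incidence_to_matrix(inc)
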