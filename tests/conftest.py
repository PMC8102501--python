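import numpy as np
import pytest

import tasvkit as tk
from tasvkit.genome import SimulationConfig
from tasvkit.io import PipelineConfig


@pytest.fixture(scope="session")
def library():
    return tk.default_library()


@pytest.fixture(scope="session")
def small_sim():
    """A 30-event simulation on a 600 kb contig, all six mechanisms represented."""
    cfg = SimulationConfig(n_contigs=1, contig_length=600_000, n_classical=10,
                           n_ncai=5, n_solitary_ltr=2, n_herv_internal_del=1,
                           n_nahr=6, n_nhej=6)
    return tk.simulate(cfg, seed=7)


@pytest.fixture(scope="session")
def small_run(small_sim, library):
    result = tk.run_calls(small_sim.reference.contigs, small_sim.donor, library,
                          PipelineConfig())
    return small_sim, result


@pytest.fixture(scope="session")
def full_sim():
    """The default 200-event study-condition simulation (~3 Mb)."""
    return tk.simulate(SimulationConfig(), seed=11)


@pytest.fixture(scope="session")
def full_run(full_sim, library):
    result = tk.run_calls(full_sim.reference.contigs, full_sim.donor, library,
                          PipelineConfig())
    return full_sim, result


@pytest.fixture()
def rng():
    return np.random.default_rng(20210408)
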