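import numpy as np
import pytest

import aggscan as ag
from aggscan.simulate import ScreenSimConfig, simulate_screen


@pytest.fixture(scope="session")
def asyn():
    return ag.asyn_reference()


@pytest.fixture(scope="session")
def asyn_db(asyn):
    return ag.enumerate_nns(asyn)


@pytest.fixture(scope="session")
def toy_cds():
    # Met-Ala-Lys-Gly-Glu, third-base A/T codons
    return ag.CodingSequence("toy", "ATG" "GCT" "AAA" "GGT" "GAA")


@pytest.fixture(scope="session")
def toy_db(toy_cds):
    return ag.enumerate_nns(toy_cds, (2, 5))


@pytest.fixture(scope="session")
def small_screen(tmp_path_factory):
    """A reduced-depth simulated screen shared by fast tests."""
    cfg = ScreenSimConfig(n_cells=60_000, reads_per_pool=60_000, seed=11)
    out = tmp_path_factory.mktemp("small_screen")
    sim = simulate_screen(cfg, out)
    counts = {
        pool: ag.count_fastq(path, sim.db, pool)
        for pool, path in sim.fastq_paths.items()
    }
    return sim, counts
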