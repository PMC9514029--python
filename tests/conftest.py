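import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from ervscreen import synthetic_data as sd
from ervscreen.pipeline import PipelineConfig, ScreenInputs, run_screen


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic two-species fixture (seed 1), shared."""
    inputs, pair = ScreenInputs.from_simulation(sd.SimConfig(seed=1))
    return inputs, pair


@pytest.fixture(scope="session")
def screen_report(default_fixture):
    """One full screen run on the default fixture, shared across tests."""
    inputs, pair = default_fixture
    return run_screen(inputs, PipelineConfig(seed=1))


def simulate_codon_pair(seed: int, n_codons: int, ds: float, omega: float, kappa: float):
    """Two coding sequences diverged from a random ancestor (pairwise dS = ds)."""
    rng = np.random.default_rng(seed)
    pep = sd.random_peptide(rng, n_codons)
    anc = sd.random_coding(rng, pep)
    a = sd.evolve_coding(rng, anc, ds / 2.0, omega, kappa)
    b = sd.evolve_coding(rng, anc, ds / 2.0, omega, kappa)
    return a, b
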