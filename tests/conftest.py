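import numpy as np
import pytest

from mhnipt import SynthPanelSpec, generate_panel


@pytest.fixture(scope="session")
def synth_panel():
    """Default synthetic reference panel: 20 loci, 4 populations of 50."""
    return generate_panel(SynthPanelSpec(), seed=1)


@pytest.fixture(scope="session")
def small_panel():
    """Small single-population panel for fast statistical tests."""
    spec = SynthPanelSpec(
        n_loci=4, haplotypes_per_locus=4, populations=(("POP1", 40),)
    )
    return generate_panel(spec, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
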