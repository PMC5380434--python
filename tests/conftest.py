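import numpy as np
import pytest

from cdzminer.profilehmm import Msa, build_profile
from cdzminer.synthgen import SynthParams, generate


@pytest.fixture(scope="session")
def small_synth():
    """Two synthetic genomes with planted clusters, decoys and truth."""
    return generate(SynthParams(seed=7, n_genomes=2))


@pytest.fixture(scope="session")
def toy_msa():
    return Msa(
        names=["a", "b", "c", "d"],
        rows=["GAVIGAVIG", "GAVLGAIIG", "GVVIGAVIG", "GA-IGAVIG"],
    )


@pytest.fixture(scope="session")
def toy_hmm(toy_msa):
    return build_profile(toy_msa)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
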