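import numpy as np
import pytest

import polytrait as pt

# Reference parameter set used throughout: s=0.1, N=2e4, n=200, mu=1e-5,
# gamma_bar=0.01, z0=0.2 (human-polygenic-adaptation scale).
REF = dict(s=0.1, N=20000, n=200, mu=1e-5, gamma_bar=0.01, z0=0.2)


@pytest.fixture(scope="session")
def ref_arch() -> pt.TraitArchitecture:
    return pt.sample_architecture(REF["n"], REF["gamma_bar"], REF["mu"], seed=1)


@pytest.fixture(scope="session")
def ref_regime() -> pt.SelectionRegime:
    return pt.SelectionRegime(s=REF["s"], optimum_before=REF["z0"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
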