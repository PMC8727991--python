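import numpy as np
import pytest

from mamutspec.simulate import GenomeSpec, build_reference


@pytest.fixture(scope="session")
def toy_reference():
    """Small two-chromosome genome (autosome + X) with genes, planted
    repeats, domains, chromatin and A/T clusters."""
    spec = GenomeSpec(chromosomes=(("I", 80_000), ("X", 50_000)))
    return build_reference(spec, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
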