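import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def event_spec():
    """Plus-strand two-donor event with the spacing used throughout the tests."""
    from altdonor import SpliceSiteSpec

    return SpliceSiteSpec(chrom="chr1", strand="+", sds1=100, sds2=112, sas=500, gene_id="G")
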