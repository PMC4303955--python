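import pytest
from hypothesis import settings

from mirffl import Mechanism, ParameterSet, Topology, default_parameters

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")

ALL_VARIANTS = [(mech, topo) for mech in Mechanism for topo in Topology]


@pytest.fixture
def params() -> ParameterSet:
    return default_parameters()
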