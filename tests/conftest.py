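import pytest

from redoxkin.competition import bottleneck_example_system


@pytest.fixture(scope="session")
def bottleneck_system():
    """The bundled production/GPx/GSH/PTP1B competition system."""
    return bottleneck_example_system()
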