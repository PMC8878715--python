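import pytest

from bcell_repseq import PipelineConfig, generate_germline_reference


@pytest.fixture(scope="session")
def ref():
    """Small germline reference shared by alignment/annotation tests."""
    return generate_germline_reference(6, 4, 3, seed=7)


@pytest.fixture()
def config():
    return PipelineConfig()
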