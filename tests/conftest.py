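import pytest
from hypothesis import settings

from pahrisk.config import default_config

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture()
def demo_config(tmp_path):
    """Shipped demo configuration writing into a temp directory."""
    return default_config(seed=1234, outdir=str(tmp_path / "out"))
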