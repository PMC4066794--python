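import pytest

from ssedrive import DriveParams


@pytest.fixture
def talelat_params() -> DriveParams:
    """TALEN-line point estimates from the homing assay counts."""
    return DriveParams(c=0.702, h=0.698, phi=0.40)


@pytest.fixture
def zfn_params() -> DriveParams:
    """ZFN-line point estimates from the homing assay counts."""
    return DriveParams(c=0.861, h=0.395, phi=0.75)
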