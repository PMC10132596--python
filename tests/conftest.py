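import pytest

from bsfsort import reference_dataset


@pytest.fixture(scope="session")
def ref_system():
    return reference_dataset("boundaries")


@pytest.fixture(scope="session")
def ref_thresholds():
    return reference_dataset("thresholds")


@pytest.fixture(scope="session")
def calibration_set():
    return reference_dataset("calibration_set")


@pytest.fixture(scope="session")
def validation_set():
    return reference_dataset("validation_set")
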