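import pytest

from pepsim.fingerprints import FingerprintParams


@pytest.fixture(scope="session")
def small_params() -> FingerprintParams:
    """Short signatures keep unit tests fast; estimator accuracy is
    checked separately at length 2048."""
    return FingerprintParams(signature_length=128, seed=7)


@pytest.fixture(scope="session")
def oracle_params() -> FingerprintParams:
    """Signature length used wherever estimates are compared with the
    exact-Jaccard oracle."""
    return FingerprintParams(signature_length=2048, seed=7)
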