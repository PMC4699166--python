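import pytest

from genoshare.primitives import ClearBackend, SecureBackend
from genoshare.sharing import MpcContext


@pytest.fixture
def secure_be():
    """Factory for secure backends sized to a requested operand bitlength."""
    def make(ell_max: int = 32, seed: int = 1234, kappa: int = 40):
        return SecureBackend(MpcContext.for_bitlength(ell_max, kappa=kappa,
                                                      seed=seed))
    return make


@pytest.fixture
def clear_be():
    def make(ell_max: int = 32, seed: int = 1234, kappa: int = 40):
        return ClearBackend(MpcContext.for_bitlength(ell_max, kappa=kappa,
                                                     seed=seed))
    return make


@pytest.fixture(params=["secure", "cleartext"])
def any_be(request, secure_be, clear_be):
    """Run a test over both backends."""
    return secure_be if request.param == "secure" else clear_be
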