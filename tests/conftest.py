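import numpy as np
import pytest

from tenttail import simulate
from tenttail.tailcall import CallStatus, RejectReason, TailCall


@pytest.fixture
def substrate():
    return simulate.default_substrate("A")


@pytest.fixture
def adapter():
    return simulate.default_adapter()


@pytest.fixture
def tail_model():
    return simulate.default_tail_model()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_calls(tails, n_untailed=0, n_rejected=0):
    """Build a TailCall list from bare tail strings (test scaffolding)."""
    calls = [
        TailCall(f"t{i}", CallStatus.TAILED, None, "AAAA" + t, 4, t)
        for i, t in enumerate(tails)
    ]
    calls += [
        TailCall(f"u{i}", CallStatus.UNTAILED, None, "AAAA", 4, "")
        for i in range(n_untailed)
    ]
    calls += [
        TailCall(f"r{i}", CallStatus.REJECTED, RejectReason.PREFIX_MISSING)
        for i in range(n_rejected)
    ]
    return calls
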