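import numpy as np
import pytest

from armitsim import ProtocolConfig, default_stages
from armitsim.task import OMISSION


class ScriptedAgent:
    """Agent that always picks the (smallest) rewarded hole; no learning."""

    def act(self, cfg, rng):
        return min(cfg.rewarded), 2.0


class OmittingAgent:
    """Agent that never responds."""

    def act(self, cfg, rng):
        return OMISSION, None


class UniformLitAgent:
    """Uniform choice over the lit holes; optional fixed latency."""

    def __init__(self, latency=1.5):
        self.latency = latency

    def act(self, cfg, rng):
        return int(rng.choice(sorted(cfg.lit))), self.latency


@pytest.fixture
def protocol():
    return ProtocolConfig()


@pytest.fixture
def stages():
    return default_stages()


@pytest.fixture
def always_correct():
    return ScriptedAgent()


@pytest.fixture
def always_omit():
    return OmittingAgent()


@pytest.fixture
def uniform_lit():
    return UniformLitAgent()
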