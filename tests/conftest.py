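import pytest

from apecomm import (
    DEFAULT_REGISTRY,
    CueParameters,
    default_parameters,
)


@pytest.fixture
def registry():
    return DEFAULT_REGISTRY


@pytest.fixture
def params():
    """Reference cue weights for the default registry."""
    return default_parameters()


@pytest.fixture
def neutral_params(registry):
    """Fully uninformative weights: every cue at 0.5."""
    return CueParameters(
        **{
            comp: {label: 0.5 for label in registry.labels(comp)}
            for comp in ("gesture", "facial", "context", "dominance")
        }
    )


def random_cue_parameters(rng, registry, low=0.02, high=0.98):
    """Random parameter draw with weights bounded away from 0 and 1."""
    return CueParameters(
        **{
            comp: {
                label: float(rng.uniform(low, high))
                for label in registry.labels(comp)
            }
            for comp in ("gesture", "facial", "context", "dominance")
        }
    )
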