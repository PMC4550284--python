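import pytest

from replidyn import ModelParams


@pytest.fixture
def basic_params() -> ModelParams:
    """A well-behaved full-communication parameter set."""
    return ModelParams(b=0.1, r=0.2, power_new=0.8, alpha_new=0.05)


@pytest.fixture
def suppressed_novel_negatives() -> ModelParams:
    """Low base rate, novel negatives never communicated, replications fully
    communicated — the regime where replication purifies the tally-1 mixture."""
    return ModelParams(b=0.001, r=0.2, power_new=0.8, alpha_new=0.05, c_new_neg=0.0)
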