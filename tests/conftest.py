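import pytest

from seqtrial import (
    DesignInput,
    LookSchedule,
    SpendingSpec,
    compute_boundaries,
    group_sequential_sample_size,
)

THREE_LOOKS = LookSchedule([1 / 3, 2 / 3, 1.0])


@pytest.fixture(scope="session")
def three_looks():
    return THREE_LOOKS


@pytest.fixture(scope="session")
def alpha_spec():
    return SpendingSpec(0.05, 3.0)


@pytest.fixture(scope="session")
def boundaries_90(three_looks, alpha_spec):
    """The 3-look, one-sided alpha 0.05, 90%-power, rho=3 design."""
    return compute_boundaries(three_looks, alpha_spec, SpendingSpec(0.10, 3.0))


@pytest.fixture(scope="session")
def boundaries_80(three_looks, alpha_spec):
    return compute_boundaries(three_looks, alpha_spec, SpendingSpec(0.20, 3.0))


@pytest.fixture(scope="session")
def intermediate_11(three_looks):
    """Recommended intermediate-risk design: 40%->60%, 90% power, 1:1."""
    return group_sequential_sample_size(
        DesignInput(0.40, 0.60, schedule=three_looks)
    )


@pytest.fixture(scope="session")
def intermediate_12(three_looks):
    return group_sequential_sample_size(
        DesignInput(0.40, 0.60, allocation=(1, 2), schedule=three_looks)
    )
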