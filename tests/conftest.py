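import pytest

from soiol import OutcomeRecord, load_table


@pytest.fixture(scope="session")
def group_a():
    return load_table("group_a")


@pytest.fixture(scope="session")
def group_b():
    return load_table("group_b")


@pytest.fixture(scope="session")
def group_a_outcomes(group_a):
    return [OutcomeRecord.from_biometry(r) for r in group_a]


@pytest.fixture(scope="session")
def group_b_outcomes(group_b):
    return [OutcomeRecord.from_biometry(r) for r in group_b]
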