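import pytest

import ecdeval as e


@pytest.fixture(scope="session")
def ledger_lines():
    return e.gen_cost_ledger()


@pytest.fixture(scope="session")
def breakdowns(ledger_lines):
    return {arm: e.aggregate(ledger_lines, arm, 400) for arm in ("group_only", "mixed")}


@pytest.fixture(scope="session")
def impacts():
    return e.gen_impacts()


@pytest.fixture(scope="session")
def assumptions():
    return e.benchmark_assumptions()


@pytest.fixture(scope="session")
def syn_config():
    return e.SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def lifetable(syn_config):
    return e.gen_lifetable(syn_config)


@pytest.fixture(scope="session")
def profile(syn_config, lifetable):
    return e.gen_wage_profile(syn_config, lifetable=lifetable)


@pytest.fixture(scope="session")
def returns():
    return e.ReturnsModel()


@pytest.fixture(scope="session")
def benchmark_inputs(breakdowns, profile, lifetable, returns, assumptions):
    return e.BenchmarkInputs(
        breakdowns=breakdowns,
        cognition_effects={"group_only": 0.52, "mixed": 0.34},
        profile=profile,
        lifetable=lifetable,
        returns=returns,
        assumptions=assumptions,
    )
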