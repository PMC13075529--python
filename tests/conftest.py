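import pytest

from aacea import load_model_config, make_life_table, run_base_case


@pytest.fixture(scope="session")
def base_params_frozen():
    """Packaged base case with the synthetic Japanese-like life table.

    Session-scoped and shared; tests must not mutate it (use ``params``).
    """
    p = load_model_config()
    p.life_table = make_life_table()
    return p


@pytest.fixture
def params(base_params_frozen):
    """Mutable per-test copy of the base case."""
    return base_params_frozen.copy()


@pytest.fixture(scope="session")
def base_result(base_params_frozen):
    """Societal base-case comparison, computed once."""
    return run_base_case(base_params_frozen)
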