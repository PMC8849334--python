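import numpy as np
import pytest
from hypothesis import settings

import fibronet as fn
from fibronet.engine import SolverConfig, compile_model

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_model():
    return fn.make_demo_network()


@pytest.fixture(scope="session")
def demo_compiled(demo_model):
    return compile_model(demo_model)


@pytest.fixture(scope="session")
def chain3():
    """Input -> N1 -> N2 chain with closed-form steady states."""
    return fn.make_fixture(fn.FixtureSpec("chain", n_nodes=3, n_inputs=1))


@pytest.fixture(scope="session")
def random_cyclic7():
    return fn.make_fixture(
        fn.FixtureSpec(
            "random_with_cycles",
            n_nodes=7,
            n_inputs=2,
            inhibitor_fraction=0.3,
            and_gate_fraction=0.3,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def solver_config():
    return SolverConfig()
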