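import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import deamfoot as df

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def specs():
    return df.default_enzyme_specs()


@pytest.fixture(scope="session")
def genome100k():
    return df.simulate_genome(100_000, seed=1002)


@pytest.fixture(scope="session")
def genome50k():
    return df.simulate_genome(50_000, seed=1003)


@pytest.fixture(scope="session")
def t_minus1_contexts():
    """200 windows with T fixed at -1, C at 0, uniform elsewhere."""
    spec = df.MotifSpec.from_pattern("Tfixed", {-1: ("T", 1.0)})
    return df.simulate_context_set(spec, 200, seed=7)


@pytest.fixture(scope="session")
def t_minus1_wm(t_minus1_contexts):
    return df.build_weight_matrix(df.count_contexts(t_minus1_contexts), label="Tfixed")


@pytest.fixture(scope="session")
def a3a_wm(specs):
    ctx = df.simulate_context_set(specs["APOBEC3A"], 1000, seed=11)
    return df.build_weight_matrix(df.count_contexts(ctx), label="APOBEC3A")


@pytest.fixture(scope="session")
def aid_wm(specs):
    ctx = df.simulate_context_set(specs["AID"], 1000, seed=12)
    return df.build_weight_matrix(df.count_contexts(ctx), label="AID")


@pytest.fixture(scope="session")
def a3g_wm(specs):
    ctx = df.simulate_context_set(specs["APOBEC3G"], 1000, seed=13)
    return df.build_weight_matrix(df.count_contexts(ctx), label="APOBEC3G")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
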