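from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table2():
    from brcascreen.datasets import candidate_summary_table

    return candidate_summary_table()


@pytest.fixture(scope="session")
def table1():
    from brcascreen.datasets import gnomad_eas_plp_table

    return gnomad_eas_plp_table()


@pytest.fixture(scope="session")
def table2_frame():
    from brcascreen.datasets import candidate_summary_frame

    return candidate_summary_frame()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A scaled-down synthetic bundle shared across tests (deterministic)."""
    from brcascreen.simulate import default_config, generate

    outdir = tmp_path_factory.mktemp("bundle")
    config = default_config(seed=42, n_participants=3000)
    return config, generate(config, outdir)
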