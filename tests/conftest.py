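import os

# single-threaded BLAS: reduction order then never depends on machine load,
# keeping optimizer trajectories (and thus fitted parameters) reproducible
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def standard_runs():
    """One deterministic full-permutation run per experiment."""
    from temporal_channels import standard_run

    return {e: standard_run(e) for e in (1, 2, 3)}


@pytest.fixture(scope="session")
def standard_steps(standard_runs):
    from temporal_channels import render_step_function

    return {e: render_step_function(r) for e, r in standard_runs.items()}


@pytest.fixture(scope="session")
def ventral_params():
    """Generating parameters of the ventral-like preset."""
    from temporal_channels.synthetic import ventral_like

    return ventral_like().params


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
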