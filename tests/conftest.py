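import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from brachydose import (TG43ParameterSet, build_scoring_grid, builtin_source,
                        load_fixtures)
from brachydose.gfit import eval_model

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def source_12():
    return builtin_source("1_2")


@pytest.fixture(scope="session")
def source_3():
    return builtin_source("3")


@pytest.fixture(scope="session")
def synthetic_params():
    """A smooth, fully populated TG-43 parameter set for round-trip oracles.

    g(r) from the polynomial-times-exponential model, F a smooth anisotropy
    dip toward the poles, phi_an left empty (derived in tests).
    """
    g_r = np.array([0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0,
                    4.0, 5.0, 6.0, 7.0, 8.0, 10.0])
    coef = np.array([-0.02, 0.1, 0.9, -0.1, 0.004, 0.15])
    g = eval_model(coef, g_r) / eval_model(coef, 1.0)
    F_theta = np.arange(5.0, 176.0, 10.0)  # keeps clear of the axis
    F_r = g_r
    tt, rr = np.meshgrid(np.radians(F_theta), F_r, indexing="ij")
    F = 1.0 - 0.08 * np.cos(tt) ** 2 * np.exp(-rr / 5.0)
    F[F_theta == 95.0, :] = F[F_theta == 95.0, :]  # no-op; grid has no 90 row yet
    # insert an exact theta = 90 row (F = 1)
    F_theta = np.sort(np.append(F_theta, 90.0))
    j = np.where(F_theta == 90.0)[0][0]
    F = np.insert(F, j, 1.0, axis=0)
    return TG43ParameterSet(
        channel="1_2", code_label="synthetic", L=0.1,
        dose_rate_constant=1.115,
        g_r=g_r, g=g, F_r=F_r, F_theta=F_theta, F=F,
        sk_per_bq=2.985e-7,
    )
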