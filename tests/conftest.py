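import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from endoscore import (SimulationParams, build_reference_model, score_cohort,
                       simulate_reference_cohort)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return SimulationParams(seed=11)


@pytest.fixture(scope="session")
def reference_cohort(params):
    return simulate_reference_cohort(params, 2000)


@pytest.fixture(scope="session")
def model(reference_cohort):
    return build_reference_model(reference_cohort)


@pytest.fixture(scope="session")
def scores(reference_cohort, model):
    scored, skip_log = score_cohort(reference_cohort, model)
    assert not skip_log
    return scored


def true_percentile(cohort, params, ratio):
    """Oracle: percentile from the generating distribution itself.

    The generator defines each ratio as an exact monotone transform of its
    latent normal trait, so evaluating the *true* per-day CDF at the ratio
    recovers the latent uniform exactly.
    """
    from endoscore.calibrate import compute_ratios

    ratios = compute_ratios(cohort)[ratio].to_numpy()
    days = cohort["lh_day"].to_numpy()
    u = np.empty(len(cohort))
    for day, spec in params.ratio_specs.items():
        mask = days == day
        if mask.any():
            u[mask] = spec[ratio].frozen().cdf(ratios[mask])
    return 100.0 * u
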