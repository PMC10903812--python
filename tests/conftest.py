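import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from cmrsurv.pipeline import SplitSpec, evaluate_report, run_two_stage_training
from cmrsurv.simulate import SimParams, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny default-signal cohort for structural tests."""
    params = SimParams(n=12, seed=3)
    return params, generate_cohort(params)


@pytest.fixture(scope="session")
def e2e_run():
    """One full two-stage training run on a strong-signal miniature cohort.

    Session-scoped: the same trained model and report back every
    end-to-end assertion (learning curves, report fields, discrimination,
    stratification) so the 30-epoch optimization runs once.
    """
    params = SimParams.strong_signal(n=60, seed=7)
    bundles, covariates, followup, truth = generate_cohort(params)
    result = run_two_stage_training(
        bundles, covariates, followup, SplitSpec(seed=7), seed=7)
    report = evaluate_report(result, bundles, covariates, followup)
    return {"params": params, "bundles": bundles, "covariates": covariates,
            "followup": followup, "truth": truth, "result": result,
            "report": report}
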